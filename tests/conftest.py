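import numpy as np
import pandas as pd
import pytest

from mirlink import synth
from mirlink.targets import compute_score


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated study shared by read-only tests."""
    cfg = synth.SimulationConfig(
        n_mirna=8, n_mrna=60, n_control=10, n_case=10,
        n_true_pairs=15, beta=1.0, noise_sd=0.5, seed=11,
    )
    return synth.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_dataset(small_sim):
    return small_sim[0]


def make_combined(pairs, **overrides):
    """Build a minimal combined interaction table for the given pairs.

    ``pairs`` is a list of (miRNA, mRNA) or dicts overriding any column.
    """
    rows = []
    for i, p in enumerate(pairs):
        row = {
            "miRNA": None, "mRNA": None,
            "cor": -0.5, "pval": 0.001 * (i + 1), "adj.pval": 0.002 * (i + 1),
            "logratio.miRNA": 1.0, "logratio.mRNA": -1.0,
            "meanExp.miRNA": 8.0, "meanExp.mRNA": 8.0,
            "dat.db1": 1, "dat.sum": 1,
        }
        if isinstance(p, dict):
            row.update(p)
        else:
            row["miRNA"], row["mRNA"] = p
        row.update(overrides)
        row["score"] = compute_score(row["logratio.miRNA"], row["logratio.mRNA"])
        rows.append(row)
    cols = ["miRNA", "mRNA", "cor", "pval", "adj.pval",
            "logratio.miRNA", "logratio.mRNA", "meanExp.miRNA", "meanExp.mRNA",
            "dat.db1", "dat.sum", "score"]
    return pd.DataFrame(rows, columns=cols)


def brute_force_bh(p):
    """Textbook Benjamini-Hochberg step-up with cumulative-minimum enforcement."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        running_min = min(running_min, p[i] * m / (rank_from_top + 1))
        adj[i] = running_min
    return np.minimum(adj, 1.0)
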