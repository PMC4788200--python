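"""Synthetic paired-expression data with known ground truth.

The generator emulates the statistical structure the pipeline assumes:
two sample groups, log2-scale Gaussian expression, a planted set of
negative miRNA -> mRNA regulations, and partly overlapping
target-prediction databases that contain the true pairs with imperfect
sensitivity plus uniformly drawn decoys.  Every stage of the pipeline is
therefore testable without external downloads, and recovery tests can
compare against the exact planted truth.

Model
-----
miRNA values are Normal(8, 1) per sample on the log2 scale; a fraction
``de_fraction`` of miRNAs is shifted by +/- ``de_shift`` in the case
group.  Each planted pair assigns one regulator miRNA to a distinct
target mRNA:

    target = baseline + beta * 8 - beta * miRNA + Normal(0, noise_sd)

so the within-group population correlation of a planted pair is the
closed form ``expected_rho(beta, noise_sd)``.  Non-target mRNAs are
independent Normal(baseline, 1), with their own differentially expressed
fraction.  Databases include each true pair with probability
``db_sensitivity`` and add ``db_decoy_rate * n_true_pairs`` decoy pairs
drawn uniformly (without replacement) from the non-true pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import (
    DataError,
    ExpressionDataset,
    ExpressionMatrix,
    PhenotypeTable,
    LOG2,
    RAW_COUNTS,
)
from .targets import TargetDB

CONTROL, CASE = "control", "case"


@dataclass
class SimulationConfig:
    n_mirna: int = 50
    n_mrna: int = 500
    n_control: int = 20
    n_case: int = 20
    n_true_pairs: int = 50
    beta: float = 0.75          # regulation strength (target log2 units per miRNA log2 unit)
    noise_sd: float = 1.0       # residual sd of target mRNAs
    de_fraction: float = 0.2    # fraction of features shifted between groups
    de_shift: float = 1.0       # log2 shift applied to cases
    db_sensitivity: float = 0.9  # P(true pair listed) per database
    db_decoy_rate: float = 5.0   # decoys per true pair, per database
    n_databases: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_true_pairs > self.n_mrna:
            raise DataError(
                "n_true_pairs must be <= n_mrna (each target mRNA has one regulator)"
            )
        if self.n_true_pairs > self.n_mirna * self.n_mrna:
            raise DataError("more true pairs than possible pairs")
        if not (0 <= self.db_sensitivity <= 1):
            raise DataError("db_sensitivity must lie in [0, 1]")
        if not (0 <= self.de_fraction <= 1):
            raise DataError("de_fraction must lie in [0, 1]")
        if self.noise_sd < 0 or self.db_decoy_rate < 0:
            raise DataError("noise_sd and db_decoy_rate must be >= 0")
        if min(self.n_mirna, self.n_mrna, self.n_true_pairs) < 1:
            raise DataError("dimensions must be >= 1")
        if self.n_control < 2 or self.n_case < 2:
            raise DataError("need >= 2 samples per group")


@dataclass
class GroundTruth:
    true_pairs: frozenset       # (miRNA id, mRNA id)
    de_mirnas: frozenset
    de_mrnas: frozenset         # non-target mRNAs that were explicitly shifted
    db_contents: dict = field(default_factory=dict)  # name -> frozenset of pairs


def expected_rho(beta: float, noise_sd: float, mirna_sd: float = 1.0) -> float:
    """Within-group population correlation of a planted pair.

    With target = const - beta * m + eps, eps ~ N(0, noise_sd^2) and
    m ~ N(mu, mirna_sd^2):  rho = -beta * s / sqrt(beta^2 s^2 + noise^2).
    """
    denom = np.sqrt(beta * beta * mirna_sd * mirna_sd + noise_sd * noise_sd)
    if denom == 0:
        raise DataError("beta and noise_sd cannot both be 0")
    return float(-beta * mirna_sd / denom)


def _ids(prefix: str, n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"{prefix}-{i:0{width}d}" for i in range(1, n + 1)]


def simulate_dataset(cfg: SimulationConfig, true_pairs=None):
    """Generate (ExpressionDataset, GroundTruth, [TargetDB]) from a config.

    Fully reproducible from ``cfg.seed``.  ``true_pairs`` optionally fixes
    the planted regulations as (miRNA id, mRNA id) tuples — each target
    mRNA at most once — overriding the random draw; useful for planting a
    shared interaction core across several simulated datasets.
    """
    rng = np.random.default_rng(cfg.seed)
    mir_ids = _ids("mir", cfg.n_mirna)
    mrna_ids = _ids("gene", cfg.n_mrna)
    n_samples = cfg.n_control + cfg.n_case
    samples = [f"ctrl-{i:03d}" for i in range(1, cfg.n_control + 1)] + [
        f"case-{i:03d}" for i in range(1, cfg.n_case + 1)
    ]
    case_mask = np.zeros(n_samples, dtype=bool)
    case_mask[cfg.n_control:] = True

    # miRNA expression
    M = rng.normal(8.0, 1.0, size=(cfg.n_mirna, n_samples))
    n_de_mir = round(cfg.de_fraction * cfg.n_mirna)
    de_mir_idx = rng.choice(cfg.n_mirna, size=n_de_mir, replace=False)
    de_mir_sign = rng.choice([-1.0, 1.0], size=n_de_mir)
    for idx, sgn in zip(de_mir_idx, de_mir_sign):
        M[idx, case_mask] += sgn * cfg.de_shift

    # planted regulations: distinct target mRNAs, one regulator each
    if true_pairs is None:
        target_idx = rng.choice(cfg.n_mrna, size=cfg.n_true_pairs, replace=False)
        regulator_idx = rng.integers(0, cfg.n_mirna, size=cfg.n_true_pairs)
    else:
        true_pairs = list(true_pairs)
        if len(true_pairs) != cfg.n_true_pairs:
            raise DataError(
                f"cfg.n_true_pairs={cfg.n_true_pairs} but {len(true_pairs)} "
                "true_pairs supplied"
            )
        mir_pos = {m: i for i, m in enumerate(mir_ids)}
        mrna_pos = {g: i for i, g in enumerate(mrna_ids)}
        bad = [p for p in true_pairs if p[0] not in mir_pos or p[1] not in mrna_pos]
        if bad:
            raise DataError(f"true_pairs outside the simulated id space: {bad[:5]}")
        targets_seen = [b for _, b in true_pairs]
        if len(set(targets_seen)) != len(targets_seen):
            raise DataError("true_pairs must give each target mRNA one regulator")
        regulator_idx = np.array([mir_pos[a] for a, _ in true_pairs])
        target_idx = np.array([mrna_pos[b] for _, b in true_pairs])
    true_pairs = frozenset(
        (mir_ids[r], mrna_ids[t]) for r, t in zip(regulator_idx, target_idx)
    )

    baseline = rng.normal(8.0, 1.0, size=cfg.n_mrna)
    G = baseline[:, None] + rng.normal(0.0, 1.0, size=(cfg.n_mrna, n_samples))
    # independent DE among non-target mRNAs
    non_targets = np.setdiff1d(np.arange(cfg.n_mrna), target_idx)
    n_de_mrna = round(cfg.de_fraction * len(non_targets))
    de_mrna_idx = rng.choice(non_targets, size=n_de_mrna, replace=False)
    de_mrna_sign = rng.choice([-1.0, 1.0], size=n_de_mrna)
    for idx, sgn in zip(de_mrna_idx, de_mrna_sign):
        G[idx, case_mask] += sgn * cfg.de_shift
    # overwrite targets with the regulation model
    noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_true_pairs, n_samples))
    G[target_idx] = (
        baseline[target_idx][:, None]
        + cfg.beta * 8.0
        - cfg.beta * M[regulator_idx]
        + noise
    )

    pheno = PhenotypeTable(
        pd.Series(np.where(case_mask, CASE, CONTROL), index=samples),
        (CONTROL, CASE),
    )
    ds = ExpressionDataset(
        ExpressionMatrix(pd.DataFrame(M, index=mir_ids, columns=samples), LOG2),
        ExpressionMatrix(pd.DataFrame(G, index=mrna_ids, columns=samples), LOG2),
        pheno,
    )

    # databases: true pairs at db_sensitivity + uniform decoys from non-true pairs
    dbs = []
    db_contents = {}
    true_linear = {r * cfg.n_mrna + t for r, t in zip(regulator_idx, target_idx)}
    n_decoys = round(cfg.db_decoy_rate * cfg.n_true_pairs)
    n_possible = cfg.n_mirna * cfg.n_mrna
    if n_decoys > n_possible - len(true_linear):
        raise DataError("db_decoy_rate asks for more decoys than available non-true pairs")
    true_list = sorted(true_linear)
    for d in range(cfg.n_databases):
        listed = [
            lin for lin in true_list if rng.random() < cfg.db_sensitivity
        ]
        decoys: set = set()
        while len(decoys) < n_decoys:
            draw = rng.integers(0, n_possible, size=n_decoys - len(decoys))
            decoys.update(int(x) for x in draw if x not in true_linear)
        pairs = frozenset(
            (mir_ids[lin // cfg.n_mrna], mrna_ids[lin % cfg.n_mrna])
            for lin in list(listed) + sorted(decoys)
        )
        name = f"synthdb{d + 1}"
        dbs.append(TargetDB(name, pairs))
        db_contents[name] = pairs

    truth = GroundTruth(
        true_pairs=true_pairs,
        de_mirnas=frozenset(mir_ids[i] for i in de_mir_idx),
        de_mrnas=frozenset(mrna_ids[i] for i in de_mrna_idx),
        db_contents=db_contents,
    )
    return ds, truth, dbs


def simulate_counts(
    n_features: int, n_samples: int, seed: int = 0,
    mean_log: float = 3.0, sd_log: float = 1.5,
) -> ExpressionMatrix:
    """Poisson-lognormal raw-count matrix, for exercising the median filter."""
    rng = np.random.default_rng(seed)
    lam = np.exp(rng.normal(mean_log, sd_log, size=n_features))
    counts = rng.poisson(lam[:, None], size=(n_features, n_samples))
    ids = _ids("feat", n_features)
    cols = [f"s{i:03d}" for i in range(1, n_samples + 1)]
    return ExpressionMatrix(
        pd.DataFrame(counts.astype(float), index=ids, columns=cols), RAW_COUNTS
    )


def simulate_gene_sets(
    gene_ids,
    n_sets: int = 20,
    set_size: tuple[int, int] = (10, 50),
    seed: int = 0,
) -> dict:
    """Random gene sets over the given ids, GMT-writable via write_gmt."""
    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    lo, hi = set_size
    if hi > len(gene_ids):
        raise DataError("set_size upper bound exceeds number of genes")
    sets = {}
    for i in range(1, n_sets + 1):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(gene_ids, size=size, replace=False))
        sets[f"SET{i:04d}"] = (f"synthetic gene set {i}", members)
    return sets
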