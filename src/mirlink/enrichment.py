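"""Over-representation analysis of target sets against gene-set collections.

Given the mRNAs targeted by a miRNA (or any target list) and a GMT
collection of GO/KEGG-style gene sets, each set is tested for
over-representation with the hypergeometric upper tail

    p = P[X >= k],  X ~ Hypergeom(N = |universe|, K = |set ∩ universe|,
                                  n = |targets|)

followed by Benjamini-Hochberg adjustment across the tested sets.  The
universe defaults to the expressed mRNAs of the dataset, so enrichment is
judged against what could have been detected, not the whole genome.  Only
over-representation is tested (one-sided); no GO-graph conditioning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

from .core_data import DataError
from .diffexp import adjust_pvalues

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Gene sets restricted to a universe of testable gene ids."""

    sets: dict          # set_id -> (description, frozenset of members in universe)
    universe: frozenset

    def __post_init__(self):
        if not self.universe:
            raise DataError("empty universe")
        empty = [k for k, (_, members) in self.sets.items() if not members]
        for k in empty:
            del self.sets[k]
        if empty:
            logger.info("dropped %d gene sets empty after universe restriction", len(empty))

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path, universe=None) -> GeneSetCollection:
    """Read a GMT file: tab-separated ``set_id<TAB>description<TAB>members...``.

    Duplicate members within a line are collapsed.  When ``universe`` is
    None it defaults to the union of all members.
    """
    sets = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"GMT line {ln} has fewer than 3 fields")
            set_id, desc = parts[0], parts[1]
            members = frozenset(g for g in parts[2:] if g)
            if set_id in sets:
                raise DataError(f"duplicate gene-set id {set_id!r}")
            sets[set_id] = (desc, members)
    if universe is None:
        universe = frozenset().union(*(m for _, m in sets.values())) if sets else frozenset()
    else:
        universe = frozenset(universe)
        sets = {
            k: (desc, members & universe) for k, (desc, members) in sets.items()
        }
    return GeneSetCollection(sets, universe)


def write_gmt(sets: dict, path: str | Path) -> None:
    """Write ``{set_id: (description, members)}`` in GMT dialect."""
    with open(path, "w") as fh:
        for set_id in sorted(sets):
            desc, members = sets[set_id]
            fh.write("\t".join([set_id, desc, *sorted(members)]) + "\n")


def enrich(targets, gsc: GeneSetCollection, min_set: int = 5) -> pd.DataFrame:
    """Hypergeometric over-representation of ``targets`` in each gene set.

    Targets outside the universe are dropped with a warning.  Sets with
    fewer than ``min_set`` members (after universe restriction) are
    skipped.  Output is sorted by adjusted p, then raw p, then set id.
    """
    targets = set(targets)
    outside = targets - gsc.universe
    if outside:
        logger.warning("dropping %d target ids outside the universe", len(outside))
    targets &= gsc.universe
    if not targets:
        raise DataError("no targets remain inside the universe")
    N = len(gsc.universe)
    n = len(targets)
    rows = []
    for set_id in sorted(gsc.sets):
        desc, members = gsc.sets[set_id]
        K = len(members)
        if K < min_set:
            continue
        k = len(targets & members)
        # upper tail P[X >= k]
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "set_id": set_id,
                "description": desc,
                "overlap": k,
                "set_size": K,
                "pval": min(p, 1.0),
                "genes": ";".join(sorted(targets & members)),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["set_id", "description", "overlap", "set_size", "pval", "adj.pval", "genes"]
        )
    out = pd.DataFrame(rows)
    out["adj.pval"] = adjust_pvalues(out["pval"].to_numpy(), "BH")
    out = out.loc[:, ["set_id", "description", "overlap", "set_size", "pval", "adj.pval", "genes"]]
    return out.sort_values(["adj.pval", "pval", "set_id"], kind="mergesort").reset_index(drop=True)
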