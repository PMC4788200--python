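"""Intersection of significant negative correlations with prediction databases.

A (miRNA, mRNA) pair becomes a candidate interaction only when it is both
significantly negatively correlated in the dataset *and* listed in at
least ``min_dat_sum`` sequence-based target-prediction databases:

    H0: rho >= 0  or  not predicted        H1: rho < 0  and  predicted

The combined table carries, per pair: the correlation test results, the
differential-expression annotations of both partners, one 0/1 flag per
database, their sum (``dat.sum``) and an interaction score

    score = -2 * (logratio_miRNA * logratio_mRNA)

which is positive when the two fold-changes oppose each other (the
pattern expected of genuine repression) and grows with joint deregulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import DataError

logger = logging.getLogger(__name__)

# Exact column layout of the combined interaction table (before the
# per-database flag columns, which are inserted in load order).
_LEAD_COLUMNS = [
    "miRNA", "mRNA", "cor", "pval", "adj.pval",
    "logratio.miRNA", "logratio.mRNA", "meanExp.miRNA", "meanExp.mRNA",
]


@dataclass(frozen=True)
class TargetDB:
    """A named set of predicted (miRNA, mRNA) pairs."""

    name: str
    pairs: frozenset

    def __post_init__(self):
        if not self.name:
            raise DataError("target database needs a non-empty name")

    def __len__(self) -> int:
        return len(self.pairs)

    def restrict(self, mirnas, mrnas) -> "TargetDB":
        """Keep only pairs whose both features belong to the given sets."""
        mirnas, mrnas = set(mirnas), set(mrnas)
        kept = frozenset((a, b) for a, b in self.pairs if a in mirnas and b in mrnas)
        return TargetDB(self.name, kept)


def load_target_db(path: str | Path, name: str | None = None, sep: str | None = None) -> TargetDB:
    """Parse a two-column miRNA/mRNA pair list; duplicates are collapsed."""
    from .core_data import _sniff_sep

    path = Path(path)
    if name is None:
        name = path.stem
    sep = _sniff_sep(path, sep)
    try:
        df = pd.read_csv(path, sep=sep, header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise DataError(f"empty target database file {path}") from None
    # tolerate a header line naming the columns
    if len(df) and str(df.iloc[0, 0]).lower() in ("mirna", "mir"):
        df = df.iloc[1:]
    if df.shape[1] < 2:
        raise DataError(f"target database {path} needs >= 2 columns")
    if len(df) == 0:
        raise DataError(f"empty target database file {path}")
    raw = list(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    pairs = frozenset(raw)
    n_dup = len(raw) - len(pairs)
    if n_dup:
        logger.info("collapsed %d duplicate pairs in database %s", n_dup, name)
    return TargetDB(name, pairs)


def write_target_db(db: TargetDB, path: str | Path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        for a, b in sorted(db.pairs):
            fh.write(f"{a}{sep}{b}\n")


def union_pairs(dbs) -> frozenset:
    out = set()
    for db in dbs:
        out |= db.pairs
    return frozenset(out)


def compute_score(logratio_mirna, logratio_mrna):
    """Interaction score: -2 * (logratio_miRNA * logratio_mRNA).

    Positive when fold-changes oppose (miRNA up & target down, or vice
    versa); negative when they agree.  Works elementwise on arrays.
    """
    return -2.0 * (np.asarray(logratio_mirna, dtype=float)
                   * np.asarray(logratio_mrna, dtype=float))


def intersect_with_targets(
    sig: pd.DataFrame,
    de_mirna: pd.DataFrame,
    de_mrna: pd.DataFrame,
    dbs,
    min_dat_sum: int = 1,
) -> pd.DataFrame:
    """Build the combined interaction table from significant pairs + databases.

    ``sig`` must already be restricted to significantly negative pairs.
    Rows are kept when the pair appears in at least ``min_dat_sum``
    databases; differential-expression columns are joined by feature id
    and are required (a missing feature is an error, because the score
    needs both log-ratios).  Flag columns follow database load order.
    """
    if min_dat_sum < 0:
        raise DataError("min_dat_sum must be >= 0")
    dbs = list(dbs)
    names = [db.name for db in dbs]
    if len(set(names)) != len(names):
        raise DataError(f"duplicate database names: {names}")

    base = sig.loc[:, ["miRNA", "mRNA", "cor", "pval", "adj.pval"]].copy()
    pair_keys = list(zip(base["miRNA"], base["mRNA"]))
    flags = {}
    for db in dbs:
        flags[f"dat.{db.name}"] = np.fromiter(
            ((a, b) in db.pairs for a, b in pair_keys), dtype=int, count=len(pair_keys)
        )
    flag_df = pd.DataFrame(flags, index=base.index, dtype=int)
    dat_sum = flag_df.sum(axis=1).astype(int) if len(dbs) else pd.Series(0, index=base.index)
    keep = dat_sum >= min_dat_sum
    base = base.loc[keep]
    flag_df = flag_df.loc[keep]
    dat_sum = dat_sum.loc[keep]

    de_mir = de_mirna.set_index("feature")
    de_m = de_mrna.set_index("feature")
    missing_mir = sorted(set(base["miRNA"]) - set(de_mir.index.astype(str)))
    missing_mrna = sorted(set(base["mRNA"]) - set(de_m.index.astype(str)))
    if missing_mir or missing_mrna:
        raise DataError(
            "features missing from differential-expression tables: "
            f"miRNAs {missing_mir[:10]}, mRNAs {missing_mrna[:10]}"
        )
    out = base.reset_index(drop=True)
    flag_df = flag_df.reset_index(drop=True)
    out["logratio.miRNA"] = de_mir["logratio"].reindex(out["miRNA"]).to_numpy()
    out["logratio.mRNA"] = de_m["logratio"].reindex(out["mRNA"]).to_numpy()
    out["meanExp.miRNA"] = de_mir["meanExp"].reindex(out["miRNA"]).to_numpy()
    out["meanExp.mRNA"] = de_m["meanExp"].reindex(out["mRNA"]).to_numpy()
    for col in flag_df.columns:
        out[col] = flag_df[col].to_numpy()
    out["dat.sum"] = dat_sum.to_numpy() if len(out) else np.array([], dtype=int)
    out["score"] = compute_score(out["logratio.miRNA"], out["logratio.mRNA"])
    ordered = _LEAD_COLUMNS + [f"dat.{n}" for n in names] + ["dat.sum", "score"]
    return out.loc[:, ordered]


def mirna_fp_ratio(predicted: frozenset | set, combined: pd.DataFrame) -> pd.DataFrame:
    """Per-miRNA false-positive ratio of database predictions.

    ``predicted`` is the union of database pairs already restricted to
    features expressed in the dataset; ``combined`` holds the pairs that
    survived the negative-correlation + database filter.  For each miRNA
    with at least one predicted expressed target:

        fp_percent = 100 * (1 - n_confirmed / n_predicted)

    i.e. the share of its predictions *not* supported by negative
    correlation in this dataset.
    """
    n_pred: dict[str, int] = {}
    for a, _ in predicted:
        n_pred[a] = n_pred.get(a, 0) + 1
    confirmed_pairs = set(zip(combined["miRNA"], combined["mRNA"]))
    n_conf: dict[str, int] = {}
    for a, b in confirmed_pairs:
        n_conf[a] = n_conf.get(a, 0) + 1
    rows = []
    for mir in sorted(n_pred):
        npred = n_pred[mir]
        nconf = n_conf.get(mir, 0)
        rows.append(
            {
                "miRNA": mir,
                "n_predicted": npred,
                "n_confirmed": nconf,
                "fp_percent": 100.0 * (1.0 - nconf / npred),
            }
        )
    return pd.DataFrame(rows, columns=["miRNA", "n_predicted", "n_confirmed", "fp_percent"])


PIE_CATEGORIES = ["0", "1", "2", "3", "4", "5", ">5"]


@dataclass
class CountSummaries:
    """Descriptive target-count tables derived from the combined table."""

    targets_per_mirna: pd.DataFrame     # miRNA, n_targets; sorted descending
    mirnas_per_mrna_pie: dict           # category -> count, sums to expressed_mrnas
    cumulative_coverage: pd.DataFrame   # miRNA, n_targets, cumulative_fraction
    mirnas_per_mrna: pd.DataFrame       # mRNA, n_mirnas; sorted descending


def count_summaries(combined: pd.DataFrame, expressed_mrnas: int) -> CountSummaries:
    """Targets-per-miRNA table, miRNAs-per-mRNA pie and cumulative coverage.

    The pie partitions all ``expressed_mrnas`` into categories by how many
    miRNAs target them (0, 1, ..., 5, >5).  The coverage curve walks the
    miRNAs in decreasing target-count order and reports the fraction of
    expressed mRNAs covered by the union of the first k target sets.
    """
    pairs = combined.loc[:, ["miRNA", "mRNA"]].drop_duplicates()
    n_targeted = pairs["mRNA"].nunique()
    if expressed_mrnas < n_targeted:
        raise DataError(
            f"expressed_mrnas={expressed_mrnas} smaller than "
            f"{n_targeted} distinct targeted mRNAs"
        )
    per_mir = (
        pairs.groupby("miRNA").size().rename("n_targets").reset_index()
        .sort_values(["n_targets", "miRNA"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    per_mrna = (
        pairs.groupby("mRNA").size().rename("n_mirnas").reset_index()
        .sort_values(["n_mirnas", "mRNA"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    pie = {c: 0 for c in PIE_CATEGORIES}
    pie["0"] = expressed_mrnas - n_targeted
    for n in per_mrna["n_mirnas"]:
        pie[str(n) if n <= 5 else ">5"] += 1
    targets_by_mir = {m: set(g["mRNA"]) for m, g in pairs.groupby("miRNA")}
    covered: set = set()
    rows = []
    for _, row in per_mir.iterrows():
        covered |= targets_by_mir[row["miRNA"]]
        rows.append(
            {
                "miRNA": row["miRNA"],
                "n_targets": int(row["n_targets"]),
                "cumulative_fraction": len(covered) / expressed_mrnas,
            }
        )
    coverage = pd.DataFrame(rows, columns=["miRNA", "n_targets", "cumulative_fraction"])
    return CountSummaries(per_mir, pie, coverage, per_mrna)


def top_interactions(combined: pd.DataFrame, n: int, sort_key: str = "adj.pval") -> pd.DataFrame:
    """First ``n`` interactions under a deterministic ordering.

    Sorted ascending by ``sort_key`` with ties broken by (pval, miRNA,
    mRNA) lexicographically, so the result never depends on input row
    order.
    """
    if n < 1:
        raise DataError("n must be >= 1")
    if sort_key not in combined.columns:
        raise DataError(f"unknown sort key {sort_key!r}")
    keys = [sort_key] + [k for k in ("pval", "miRNA", "mRNA") if k != sort_key]
    return (
        combined.sort_values(keys, kind="mergesort")
        .head(n)
        .reset_index(drop=True)
    )


def write_combined(table: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    table.to_csv(path, sep=sep, index=False)


def read_combined(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in _LEAD_COLUMNS + ["dat.sum", "score"] if c not in df.columns]
    if missing:
        raise DataError(f"combined table missing columns: {missing}")
    df["miRNA"] = df["miRNA"].astype(str)
    df["mRNA"] = df["mRNA"].astype(str)
    return df
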