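"""Cross-dataset integration of interactomes.

Once several datasets (e.g. different cancers) each have a combined
interaction table, this module answers the comparative questions: which
interactions are shared (Venn cells over datasets), which are specific
to one dataset, how specific each miRNA's targetome is, and what the
dominant cross-dataset correlation patterns are (k-means over per-pair
correlation profiles, then hierarchical clustering / PCA of the datasets
based on the cluster centres).

A pair only enters the cross-dataset correlation matrix when it is
*measured* everywhere (both features pass the expression filter in every
dataset) and significant+predicted in at least one.  "Specific to D"
additionally requires measurability outside D: a pair that could not
even be tested elsewhere is excluded (with a logged count) rather than
called specific.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans

from .core_data import DataError

logger = logging.getLogger(__name__)


@dataclass
class DatasetResult:
    """One dataset's interactome plus the context needed for comparison."""

    label: str
    combined: pd.DataFrame              # significant + predicted pairs (S1 schema)
    expressed_mirnas: frozenset
    expressed_mrnas: frozenset
    corr: pd.DataFrame | None = None    # full all-pairs correlation table

    @property
    def pairs(self) -> frozenset:
        return frozenset(zip(self.combined["miRNA"], self.combined["mRNA"]))

    def measurable(self, pair) -> bool:
        return pair[0] in self.expressed_mirnas and pair[1] in self.expressed_mrnas


@dataclass
class VennResult:
    """Exact-membership Venn cells over the datasets' interaction sets."""

    cells: dict        # frozenset(labels) -> frozenset of pairs
    labels: list

    @property
    def counts(self) -> dict:
        return {k: len(v) for k, v in self.cells.items()}

    @property
    def union_size(self) -> int:
        return sum(len(v) for v in self.cells.values())

    def in_all(self) -> frozenset:
        return self.cells.get(frozenset(self.labels), frozenset())


def shared_interactions(results) -> VennResult:
    """Partition the union of interactions by exactly which datasets hold them."""
    results = list(results)
    if len(results) < 2:
        raise DataError("need >= 2 datasets for a shared-interaction analysis")
    labels = [r.label for r in results]
    if len(set(labels)) != len(labels):
        raise DataError(f"duplicate dataset labels: {labels}")
    pair_sets = {r.label: r.pairs for r in results}
    union = frozenset().union(*pair_sets.values())
    cells: dict = {}
    for pair in union:
        key = frozenset(l for l in labels if pair in pair_sets[l])
        cells.setdefault(key, set()).add(pair)
    return VennResult({k: frozenset(v) for k, v in cells.items()}, labels)


def specific_interactions(results, focal: str) -> pd.DataFrame:
    """Interactions found in the focal dataset and in no other.

    A pair must be measurable (both features expressed) in every other
    dataset to qualify; pairs untestable elsewhere are excluded with a
    logged count, since their absence elsewhere is not evidence of
    specificity.
    """
    results = list(results)
    by_label = {r.label: r for r in results}
    if focal not in by_label:
        raise DataError(f"focal dataset {focal!r} not among {sorted(by_label)}")
    others = [r for r in results if r.label != focal]
    focal_res = by_label[focal]
    other_pairs = frozenset().union(*(r.pairs for r in others)) if others else frozenset()
    keep = []
    n_unmeasurable = 0
    for idx, row in focal_res.combined.iterrows():
        pair = (row["miRNA"], row["mRNA"])
        if pair in other_pairs:
            continue
        if all(r.measurable(pair) for r in others):
            keep.append(idx)
        else:
            n_unmeasurable += 1
    if n_unmeasurable:
        logger.info(
            "%d focal pairs excluded from specificity (unmeasurable in some dataset)",
            n_unmeasurable,
        )
    return focal_res.combined.loc[keep].reset_index(drop=True)


def specificity_scatter(results, focal: str) -> pd.DataFrame:
    """Per-miRNA total vs focal-specific target counts (plus mean expression).

    A ratio of 1 flags miRNAs whose whole targetome is specific to the
    focal dataset.
    """
    by_label = {r.label: r for r in results}
    if focal not in by_label:
        raise DataError(f"focal dataset {focal!r} not among {sorted(by_label)}")
    focal_res = by_label[focal]
    spec = specific_interactions(results, focal)
    total = focal_res.combined.groupby("miRNA")["mRNA"].nunique()
    specific = spec.groupby("miRNA")["mRNA"].nunique() if len(spec) else pd.Series(dtype=int)
    mean_exp = focal_res.combined.groupby("miRNA")["meanExp.miRNA"].first()
    out = pd.DataFrame(
        {
            "miRNA": total.index,
            "n_total_targets": total.to_numpy(),
            "n_specific_targets": specific.reindex(total.index).fillna(0).astype(int).to_numpy(),
            "mean_expression": mean_exp.reindex(total.index).to_numpy(),
        }
    ).reset_index(drop=True)
    return out.sort_values("miRNA", kind="mergesort").reset_index(drop=True)


@dataclass
class MultiDatasetPairMatrix:
    """Per-pair correlation profiles across datasets.

    ``cor``: rows = (miRNA, mRNA) pairs measured in all datasets and
    significant+predicted in at least one; columns = dataset labels;
    cells = the pair's correlation in that dataset.  ``flags`` marks, per
    dataset, whether the pair is in that dataset's interactome.
    """

    cor: pd.DataFrame
    flags: pd.DataFrame

    def __post_init__(self):
        if self.cor.isna().to_numpy().any():
            raise DataError("pair matrix has missing cells")
        if not self.cor.index.equals(self.flags.index):
            raise DataError("cor and flags must share the same pair index")


def build_pair_matrix(results) -> MultiDatasetPairMatrix:
    """Assemble the cross-dataset correlation matrix.

    Every dataset must carry its full correlation table (``corr``).
    """
    results = list(results)
    if len(results) < 2:
        raise DataError("need >= 2 datasets")
    for r in results:
        if r.corr is None:
            raise DataError(f"dataset {r.label!r} lacks a full correlation table")
    union = frozenset().union(*(r.pairs for r in results))
    measured = [
        p for p in union if all(r.measurable(p) for r in results)
    ]
    n_dropped = len(union) - len(measured)
    if n_dropped:
        logger.info("%d pairs dropped: not measured in every dataset", n_dropped)
    if not measured:
        raise DataError("no pair is measured in every dataset")
    measured = sorted(measured)
    index = pd.MultiIndex.from_tuples(measured, names=["miRNA", "mRNA"])
    cor = {}
    flags = {}
    for r in results:
        lookup = r.corr.set_index(["miRNA", "mRNA"])["cor"]
        cor[r.label] = lookup.reindex(index).to_numpy()
        flags[r.label] = np.fromiter((p in r.pairs for p in measured), dtype=bool,
                                     count=len(measured))
    return MultiDatasetPairMatrix(
        pd.DataFrame(cor, index=index), pd.DataFrame(flags, index=index)
    )


@dataclass
class PairClustering:
    assignments: pd.Series   # pair -> cluster id (0-based)
    centers: pd.DataFrame    # cluster x dataset mean correlation
    inertia: float


def cluster_pairs(
    m: MultiDatasetPairMatrix, k: int = 4, n_init: int = 10, seed: int = 0
) -> PairClustering:
    """Lloyd k-means (k-means++ seeding, ``n_init`` restarts) on pair profiles.

    Centres are reported as the mean correlation profile of each cluster.
    """
    X = m.cor.to_numpy()
    if k > X.shape[0]:
        raise DataError(f"k={k} exceeds number of pairs {X.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(X)
    assignments = pd.Series(labels, index=m.cor.index, name="cluster")
    centers = pd.DataFrame(
        [X[labels == c].mean(axis=0) for c in range(k)],
        columns=m.cor.columns,
        index=pd.RangeIndex(k, name="cluster"),
    )
    return PairClustering(assignments, centers, float(km.inertia_))


@dataclass
class DatasetClustering:
    linkage: np.ndarray        # scipy linkage matrix (average linkage)
    labels: list
    pca_coords: pd.DataFrame   # dataset x (PC1, PC2)
    explained_variance: np.ndarray  # eigenvalues of the correlation matrix


def cluster_datasets(centers: pd.DataFrame) -> DatasetClustering:
    """Relate datasets through their cluster-centre profiles.

    Average-linkage hierarchical clustering on Euclidean distances
    between dataset columns, and PCA of the datasets computed from the
    correlation matrix of their profiles (standardized variables), so the
    component variances sum to the number of datasets.
    """
    labels = list(centers.columns)
    if len(labels) < 3:
        raise DataError("need >= 3 datasets for a meaningful tree")
    X = centers.to_numpy()  # clusters x datasets
    Z = hierarchy.linkage(X.T, method="average", metric="euclidean")
    corr = np.corrcoef(X.T)
    w, v = np.linalg.eigh(corr)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    # sign convention: largest-magnitude loading positive
    for j in range(v.shape[1]):
        i = np.argmax(np.abs(v[:, j]))
        if v[i, j] < 0:
            v[:, j] = -v[:, j]
    coords = v[:, :2] * np.sqrt(np.maximum(w[:2], 0.0))
    pca = pd.DataFrame(coords, index=labels, columns=["PC1", "PC2"])
    return DatasetClustering(Z, labels, pca, w)


def write_venn(venn: VennResult, path, sep: str = "\t") -> None:
    rows = []
    for key in sorted(venn.cells, key=lambda k: (len(k), sorted(k))):
        rows.append({"datasets": "+".join(sorted(key)), "n_pairs": len(venn.cells[key])})
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
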