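import itertools

import numpy as np
import pandas as pd
import pytest

from mirlink.core_data import DataError
from mirlink.multiset import (
    DatasetResult,
    MultiDatasetPairMatrix,
    build_pair_matrix,
    cluster_datasets,
    cluster_pairs,
    shared_interactions,
    specific_interactions,
    specificity_scatter,
)
from conftest import make_combined

ALL_MIRNAS = frozenset({f"m{i}" for i in range(6)})
ALL_MRNAS = frozenset({f"g{i}" for i in range(10)})


def _result(label, pairs, mirnas=ALL_MIRNAS, mrnas=ALL_MRNAS, corr=None):
    return DatasetResult(
        label=label, combined=make_combined(pairs),
        expressed_mirnas=frozenset(mirnas), expressed_mrnas=frozenset(mrnas),
        corr=corr,
    )


class TestSharedInteractions:
    def test_identical_tables_all_shared(self):
        pairs = [("m1", "g1"), ("m2", "g2")]
        venn = shared_interactions([_result("A", pairs), _result("B", pairs)])
        assert venn.counts == {frozenset({"A", "B"}): 2}
        assert venn.in_all() == frozenset({("m1", "g1"), ("m2", "g2")})

    def test_toy_three_dataset_cells(self):
        a = [("m1", "g1"), ("m2", "g2"), ("m3", "g3")]
        b = [("m1", "g1"), ("m2", "g2"), ("m4", "g4")]
        c = [("m1", "g1"), ("m5", "g5")]
        venn = shared_interactions([_result("A", a), _result("B", b), _result("C", c)])
        assert venn.counts[frozenset({"A", "B", "C"})] == 1
        assert venn.counts[frozenset({"A", "B"})] == 1
        assert venn.counts[frozenset({"A"})] == 1
        assert venn.counts[frozenset({"B"})] == 1
        assert venn.counts[frozenset({"C"})] == 1

    def test_cells_partition_union(self):
        rng = np.random.default_rng(31)
        datasets = []
        all_pairs = [(f"m{i}", f"g{j}") for i in range(6) for j in range(10)]
        for label in "ABCD":
            chosen = [all_pairs[k] for k in rng.choice(len(all_pairs), 20, replace=False)]
            datasets.append(_result(label, chosen))
        venn = shared_interactions(datasets)
        cells = list(venn.cells.values())
        for x, y in itertools.combinations(cells, 2):
            assert not (x & y)
        union = frozenset().union(*(d.pairs for d in datasets))
        assert venn.union_size == len(union)
        # per-dataset accounting: |pairs of D| = sum of cells containing D
        for d in datasets:
            total = sum(len(v) for k, v in venn.cells.items() if d.label in k)
            assert total == len(d.pairs)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(DataError):
            shared_interactions([_result("A", [("m1", "g1")])])


class TestSpecificInteractions:
    def test_pair_significant_everywhere_excluded(self):
        pairs = [("m1", "g1")]
        out = specific_interactions([_result("A", pairs), _result("B", pairs)], "A")
        assert len(out) == 0

    def test_focal_only_pair_included(self):
        out = specific_interactions(
            [_result("A", [("m1", "g1")]), _result("B", [("m2", "g2")])], "A"
        )
        assert list(zip(out["miRNA"], out["mRNA"])) == [("m1", "g1")]

    def test_unmeasurable_elsewhere_excluded(self, caplog):
        # g9 not expressed in B, so (m1, g9) cannot be called A-specific
        b = _result("B", [("m2", "g2")], mrnas=ALL_MRNAS - {"g9"})
        with caplog.at_level("INFO"):
            out = specific_interactions(
                [_result("A", [("m1", "g9"), ("m1", "g1")]), b], "A"
            )
        assert list(zip(out["miRNA"], out["mRNA"])) == [("m1", "g1")]

    def test_matches_brute_force_difference(self):
        rng = np.random.default_rng(32)
        all_pairs = [(f"m{i}", f"g{j}") for i in range(6) for j in range(10)]
        sets = {
            label: {all_pairs[k] for k in rng.choice(len(all_pairs), 15, replace=False)}
            for label in "ABC"
        }
        results = [_result(label, sorted(s)) for label, s in sets.items()]
        out = specific_interactions(results, "B")
        expected = sets["B"] - sets["A"] - sets["C"]
        assert set(zip(out["miRNA"], out["mRNA"])) == expected

    def test_unknown_focal(self):
        with pytest.raises(DataError):
            specific_interactions([_result("A", []), _result("B", [])], "Z")


class TestSpecificityScatter:
    def test_identical_tables_no_specific(self):
        pairs = [("m1", "g1"), ("m1", "g2"), ("m2", "g3")]
        out = specificity_scatter([_result("A", pairs), _result("B", pairs)], "A")
        assert (out["n_specific_targets"] == 0).all()

    def test_toy_counts(self):
        a = [("m1", "g1"), ("m1", "g2"), ("m2", "g3")]
        b = [("m1", "g1")]
        out = specificity_scatter([_result("A", a), _result("B", b)], "A").set_index("miRNA")
        assert out.loc["m1", "n_total_targets"] == 2
        assert out.loc["m1", "n_specific_targets"] == 1
        assert out.loc["m2", "n_specific_targets"] == 1

    def test_specific_bounded_by_total(self):
        rng = np.random.default_rng(33)
        all_pairs = [(f"m{i}", f"g{j}") for i in range(6) for j in range(10)]
        results = [
            _result(label,
                    [all_pairs[k] for k in rng.choice(len(all_pairs), 25, replace=False)])
            for label in "AB"
        ]
        out = specificity_scatter(results, "A")
        assert (out["n_specific_targets"] <= out["n_total_targets"]).all()


def _pair_matrix(values, labels=("A", "B", "C")):
    values = np.asarray(values, dtype=float)
    idx = pd.MultiIndex.from_tuples(
        [(f"m{i}", f"g{i}") for i in range(values.shape[0])], names=["miRNA", "mRNA"]
    )
    cor = pd.DataFrame(values, index=idx, columns=list(labels))
    flags = pd.DataFrame(True, index=idx, columns=list(labels))
    return MultiDatasetPairMatrix(cor, flags)


class TestBuildPairMatrix:
    def test_requires_measurement_everywhere(self):
        def corr_for(pairs):
            return pd.DataFrame(
                {"miRNA": [a for a, _ in pairs], "mRNA": [b for _, b in pairs],
                 "cor": [-0.4] * len(pairs), "pval": [0.01] * len(pairs),
                 "adj.pval": [0.02] * len(pairs)}
            )
        universe = [("m1", "g1"), ("m1", "g2"), ("m2", "g1"), ("m2", "g2")]
        a = _result("A", [("m1", "g1"), ("m1", "g2")], corr=corr_for(universe))
        # g2 unexpressed in B -> (m1, g2) must drop out
        b = _result("B", [("m1", "g1")], mrnas=ALL_MRNAS - {"g2"},
                    corr=corr_for([p for p in universe if p[1] != "g2"]))
        m = build_pair_matrix([a, b])
        assert set(m.cor.index) == {("m1", "g1")}
        assert not m.cor.isna().to_numpy().any()


class TestClusterPairs:
    def test_k1_center_is_column_mean(self):
        rng = np.random.default_rng(34)
        m = _pair_matrix(rng.normal(0, 0.3, size=(12, 3)))
        out = cluster_pairs(m, k=1, seed=0)
        assert np.allclose(out.centers.iloc[0], m.cor.mean(axis=0))

    def test_two_blobs_recovered_matches_exhaustive_search(self):
        pts = np.array([[-0.8, -0.7], [-0.75, -0.8], [-0.7, -0.75],
                        [0.5, 0.6], [0.55, 0.5], [0.6, 0.55]])
        m = _pair_matrix(pts, labels=("A", "B"))
        out = cluster_pairs(m, k=2, seed=0)
        labels = out.assignments.to_numpy()
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]
        # exhaustive minimum-SSE bipartition agrees
        best_sse, best_split = np.inf, None
        for mask_bits in range(1, 2 ** 6 - 1):
            mask = np.array([(mask_bits >> i) & 1 for i in range(6)], dtype=bool)
            if mask.sum() in (0, 6):
                continue
            sse = sum(
                ((pts[g] - pts[g].mean(axis=0)) ** 2).sum()
                for g in (mask, ~mask) if g.sum()
            )
            if sse < best_sse - 1e-12:
                best_sse, best_split = sse, mask
        assert set(map(tuple, [np.nonzero(best_split)[0], np.nonzero(~best_split)[0]])) == \
               set(map(tuple, [np.nonzero(labels == labels[0])[0],
                               np.nonzero(labels != labels[0])[0]]))
        assert out.inertia == pytest.approx(best_sse)

    def test_sse_non_increasing_in_k(self):
        rng = np.random.default_rng(35)
        m = _pair_matrix(rng.normal(0, 0.4, size=(40, 3)))
        sses = [cluster_pairs(m, k=k, seed=0).inertia for k in (1, 2, 3, 4)]
        assert all(a >= b - 1e-9 for a, b in zip(sses, sses[1:]))

    def test_seed_reproducible_and_stable_across_seeds(self):
        rng = np.random.default_rng(36)
        base = np.vstack([rng.normal(c, 0.05, size=(15, 3))
                          for c in (-0.6, -0.1, 0.4, 0.7)])
        m = _pair_matrix(base)
        a = cluster_pairs(m, k=4, n_init=10, seed=7)
        b = cluster_pairs(m, k=4, n_init=10, seed=7)
        assert a.assignments.equals(b.assignments)
        sses = [cluster_pairs(m, k=4, n_init=10, seed=s).inertia for s in range(5)]
        assert (max(sses) - min(sses)) / max(min(sses), 1e-12) < 0.01

    def test_k_exceeding_rows_rejected(self):
        m = _pair_matrix(np.zeros((3, 3)))
        with pytest.raises(DataError):
            cluster_pairs(m, k=4)


class TestClusterDatasets:
    def test_identical_columns_merge_at_zero(self):
        centers = pd.DataFrame(
            {"A": [0.1, -0.5, 0.3], "B": [0.1, -0.5, 0.3], "C": [0.9, 0.8, -0.2]}
        )
        out = cluster_datasets(centers)
        first_merge = out.linkage[0]
        assert first_merge[2] == pytest.approx(0.0)
        assert {int(first_merge[0]), int(first_merge[1])} == {0, 1}

    def test_planted_topology_recovered(self):
        rng = np.random.default_rng(37)
        base1 = rng.normal(0, 1, 6)
        base2 = rng.normal(0, 1, 6)
        centers = pd.DataFrame(
            {
                "A": base1 + rng.normal(0, 0.01, 6),
                "B": base1 + rng.normal(0, 0.01, 6),
                "C": base2 + rng.normal(0, 0.01, 6),
                "D": base2 + rng.normal(0, 0.01, 6),
            }
        )
        out = cluster_datasets(centers)
        # the first two merges must pair (A,B) and (C,D)
        merged = [
            {int(out.linkage[i][0]), int(out.linkage[i][1])} for i in range(2)
        ]
        assert {0, 1} in merged and {2, 3} in merged

    def test_correlation_pca_variances_sum_to_dimension(self):
        rng = np.random.default_rng(38)
        centers = pd.DataFrame(rng.normal(0, 1, size=(5, 4)), columns=list("ABCD"))
        out = cluster_datasets(centers)
        assert out.explained_variance.sum() == pytest.approx(4.0)
        assert out.pca_coords.shape == (4, 2)

    def test_fewer_than_three_rejected(self):
        centers = pd.DataFrame({"A": [0.1, 0.2], "B": [0.3, 0.4]})
        with pytest.raises(DataError):
            cluster_datasets(centers)
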