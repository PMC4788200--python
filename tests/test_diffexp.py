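import itertools
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mirlink import core_data, diffexp
from mirlink.core_data import DataError, ExpressionMatrix, PhenotypeTable


def _dataset(values, n_ctrl, ids=None):
    values = np.asarray(values, dtype=float)
    samples = [f"s{j}" for j in range(values.shape[1])]
    labels = ["ctl"] * n_ctrl + ["dis"] * (len(samples) - n_ctrl)
    m = ExpressionMatrix(
        pd.DataFrame(values, index=ids or [f"f{i}" for i in range(values.shape[0])],
                     columns=samples),
        core_data.LOG2,
    )
    return m, PhenotypeTable(pd.Series(labels, index=samples), ("ctl", "dis"))


class TestTTest:
    def test_identical_groups_null(self):
        m, pheno = _dataset([[1, 2, 3, 1, 2, 3]], 3)
        out = diffexp.diffexp_ttest(m, pheno)
        assert out["logratio"].iloc[0] == 0
        assert out["pval"].iloc[0] == 1

    def test_shift_gives_logratio(self):
        rng = np.random.default_rng(0)
        base = np.array([1.0, 1.0, 1.0, 3.0, 3.0, 3.0]) + rng.normal(0, 1e-6, 6)
        m, pheno = _dataset([base], 3)
        out = diffexp.diffexp_ttest(m, pheno)
        assert out["logratio"].iloc[0] == pytest.approx(2.0, abs=1e-4)
        assert out["meanExp"].iloc[0] == pytest.approx(2.0, abs=1e-4)

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(42)
        vals = rng.normal(0, 1, size=(1, 16))
        m, pheno = _dataset(vals, 8)
        p_t = diffexp.diffexp_ttest(m, pheno)["pval"].iloc[0]
        x = vals[0]
        obs = abs(stats.ttest_ind(x[8:], x[:8]).statistic)
        n_perm = 10_000
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(16)
            t = stats.ttest_ind(x[perm[8:]], x[perm[:8]]).statistic
            count += abs(t) >= obs
        p_perm = (count + 1) / (n_perm + 1)
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p_t - p_perm) < 3 * se + 1e-12

    def test_zero_variance_policy(self):
        m, pheno = _dataset([[1, 1, 1, 1, 1, 1], [1, 1, 1, 2, 2, 2]], 3)
        out = diffexp.diffexp_ttest(m, pheno)
        assert out["pval"].iloc[0] == 1.0          # equal constant groups
        assert out["pval"].iloc[1] < 1e-300        # separated constant groups


class TestWilcoxon:
    def test_identical_groups(self):
        m, pheno = _dataset([[5, 6, 7, 5, 6, 7]], 3)
        assert diffexp.diffexp_wilcoxon(m, pheno)["pval"].iloc[0] == 1

    def test_all_tied(self):
        m, pheno = _dataset([[2, 2, 2, 2, 2, 2]], 3)
        assert diffexp.diffexp_wilcoxon(m, pheno)["pval"].iloc[0] == 1

    def test_exact_enumeration_3v3(self):
        """p equals exhaustive enumeration of the 20 group assignments."""
        x = np.array([1.3, 0.2, 2.7, 0.9, 1.8, 0.1])
        m, pheno = _dataset([x], 3)
        p_impl = diffexp.diffexp_wilcoxon(m, pheno)["pval"].iloc[0]
        ranks = stats.rankdata(x)

        def u_stat(case_idx):
            r_case = ranks[list(case_idx)].sum()
            return r_case - 3 * 4 / 2  # U of the case group

        obs = u_stat([3, 4, 5])
        us = [u_stat(c) for c in itertools.combinations(range(6), 3)]
        lo = sum(u <= obs for u in us) / len(us)
        hi = sum(u >= obs for u in us) / len(us)
        p_exact = min(1.0, 2 * min(lo, hi))
        assert p_impl == pytest.approx(p_exact, abs=1e-12)

    def test_strict_separation_minimal_p(self):
        m, pheno = _dataset([[1, 2, 3, 10, 11, 12]], 3)
        # most extreme of the C(6,3)=20 assignments, two-sided
        assert diffexp.diffexp_wilcoxon(m, pheno)["pval"].iloc[0] == pytest.approx(0.1)


class TestModeratedT:
    def test_prior_df_zero_is_ordinary_t(self):
        rng = np.random.default_rng(1)
        m, pheno = _dataset(rng.normal(8, 1, size=(40, 10)), 5)
        mod = diffexp.diffexp_modt(m, pheno, prior_df=0.0)
        ordinary = diffexp.diffexp_ttest(m, pheno, equal_var=True)
        assert np.allclose(mod["pval"], ordinary["pval"], atol=1e-6)

    def test_equal_variance_preserves_ranking(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 1, size=(300, 12))
        vals[:50, 6:] += rng.uniform(0.5, 2.0, size=(50, 1))
        m, pheno = _dataset(vals, 6)
        mod = diffexp.diffexp_modt(m, pheno)
        ordinary = diffexp.diffexp_ttest(m, pheno)
        rho = stats.spearmanr(mod["pval"], ordinary["pval"]).statistic
        assert rho > 0.95

    def test_trend_needs_enough_features(self):
        rng = np.random.default_rng(3)
        m, pheno = _dataset(rng.normal(8, 1, size=(5, 8)), 4)
        with pytest.raises(DataError):
            diffexp.diffexp_modt(m, pheno, trend=True)

    def test_power_gain_at_matched_type_i(self):
        """Moderation should not lose power vs the ordinary t at matched
        empirical type-I error (3v3 design, 500 features, 50 shifted)."""
        rng = np.random.default_rng(7)
        vals = rng.normal(0, 1, size=(500, 6)) * rng.uniform(0.5, 2, size=(500, 1))
        shifted = np.arange(50)
        vals[shifted, 3:] += 2.0
        m, pheno = _dataset(vals, 3)
        mod = diffexp.diffexp_modt(m, pheno)["pval"].to_numpy()
        ordinary = diffexp.diffexp_ttest(m, pheno)["pval"].to_numpy()
        null_mask = np.ones(500, dtype=bool)
        null_mask[shifted] = False
        q = 0.05
        thr_mod = np.quantile(mod[null_mask], q)
        thr_ord = np.quantile(ordinary[null_mask], q)
        power_mod = (mod[shifted] < thr_mod).mean()
        power_ord = (ordinary[shifted] < thr_ord).mean()
        assert power_mod >= power_ord

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_matches_limma_reference(self, tmp_path):
        """Independent cross-check of the empirical-Bayes machinery against
        the reference R implementation on a tiny fixture."""
        rng = np.random.default_rng(9)
        vals = rng.normal(8, 1, size=(60, 8)) * rng.uniform(0.7, 1.5, size=(60, 1))
        vals[:10, 4:] += 1.5
        m, pheno = _dataset(vals, 4)
        mine = diffexp.diffexp_modt(m, pheno)
        expr_path = tmp_path / "expr.tsv"
        m.values.to_csv(expr_path, sep="\t")
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.delim("{expr_path}", row.names=1))
            group <- factor(c(rep("ctl",4), rep("dis",4)), levels=c("ctl","dis"))
            design <- model.matrix(~group)
            fit <- eBayes(lmFit(x, design), trend=FALSE)
            out <- data.frame(p=fit$p.value[,2], d0=fit$df.prior)
            write.table(out, "{tmp_path}/limma.tsv", sep="\\t", quote=FALSE)
        """)
        (tmp_path / "run.R").write_text(script)
        subprocess.run(["Rscript", str(tmp_path / "run.R")], check=True,
                       capture_output=True, timeout=300)
        ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t")
        assert np.max(np.abs(mine["pval"].to_numpy() - ref["p"].to_numpy())) < 1e-6
        assert mine.attrs["prior_df"] == pytest.approx(ref["d0"].iloc[0], rel=1e-3)


class TestRankProd:
    def test_consistently_top_ranked_feature_is_smallest(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 1, size=(30, 8))
        vals[0, 4:] -= 50.0  # most down-regulated in every pairwise comparison
        m, pheno = _dataset(vals, 4)
        out = diffexp.diffexp_rankprod(m, pheno, n_perm=100, seed=0)
        assert out["rank_product_down"].idxmin() == 0
        assert out["rank_product_down"].iloc[0] == pytest.approx(1.0)

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(5)
        m, pheno = _dataset(rng.normal(0, 1, size=(1000, 8)), 4)
        out = diffexp.diffexp_rankprod(m, pheno, n_perm=150, seed=1)
        ks = stats.kstest(out["pval"], "uniform")
        assert ks.pvalue > 0.01

    def test_monte_carlo_stability_under_more_permutations(self):
        rng = np.random.default_rng(6)
        m, pheno = _dataset(rng.normal(0, 1, size=(200, 8)), 4)
        p1 = diffexp.diffexp_rankprod(m, pheno, n_perm=400, seed=2)["pval"].to_numpy()
        p2 = diffexp.diffexp_rankprod(m, pheno, n_perm=800, seed=3)["pval"].to_numpy()
        se = np.sqrt(np.maximum(p1 * (1 - p1), 0.25 / 200) / 400)
        assert (np.abs(p1 - p2) <= 3 * se + 0.01).mean() > 0.95

    def test_rejects_too_few_permutations(self):
        rng = np.random.default_rng(8)
        m, pheno = _dataset(rng.normal(0, 1, size=(10, 8)), 4)
        with pytest.raises(DataError):
            diffexp.diffexp_rankprod(m, pheno, n_perm=50)


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        for method in ("BH", "bonferroni"):
            assert diffexp.adjust_pvalues([0.03], method)[0] == pytest.approx(0.03)

    def test_bh_hand_example(self):
        # step-up: min over i>=k of p_i * m / i, all collapse to 0.04
        out = diffexp.adjust_pvalues([0.01, 0.02, 0.03, 0.04], "BH")
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_bonferroni_dominates_bh(self, pvals):
        bh = diffexp.adjust_pvalues(pvals, "BH")
        bonf = diffexp.adjust_pvalues(pvals, "bonferroni")
        assert np.all(bonf >= bh - 1e-12)
        assert np.all(bh <= 1.0) and np.all(bonf <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            diffexp.adjust_pvalues([0.5, 1.5])


class TestImportExport:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(10)
        m, pheno = _dataset(rng.normal(8, 1, size=(12, 8)), 4)
        table = diffexp.diffexp_ttest(m, pheno)
        path = tmp_path / "de.tsv"
        diffexp.write_diffexp(table, path)
        back = diffexp.import_diffexp(path)
        for col in ("logratio", "meanExp", "pval", "adj.pval"):
            assert np.allclose(back[col], table[col], atol=1e-9)

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "de.tsv"
        path.write_text("feature\tlogratio\tmeanExp\tpval\nf1\t1.0\t8.0\t0.1\n")
        with pytest.raises(DataError, match="adj.pval"):
            diffexp.import_diffexp(path)

    def test_extra_columns_preserved(self, tmp_path):
        path = tmp_path / "de.tsv"
        path.write_text(
            "feature\tlogratio\tmeanExp\tpval\tadj.pval\tnote\nf1\t1.0\t8.0\t0.1\t0.2\thello\n"
        )
        back = diffexp.import_diffexp(path)
        assert "note" in back.columns


class TestInvariances:
    @pytest.mark.parametrize("method", ["ttest", "wilcoxon", "modt"])
    def test_sample_order_invariance(self, method):
        rng = np.random.default_rng(12)
        vals = rng.normal(8, 1, size=(15, 10))
        m, pheno = _dataset(vals, 5)
        fn = getattr(diffexp, f"diffexp_{method}")
        base = fn(m, pheno)
        perm = rng.permutation(10)
        m2 = ExpressionMatrix(m.values.iloc[:, perm], core_data.LOG2)
        permuted = fn(m2, pheno.subset(m2.sample_ids))
        for col in ("logratio", "pval", "adj.pval"):
            assert np.array_equal(base[col].to_numpy(), permuted[col].to_numpy())

    @pytest.mark.parametrize("method", ["ttest", "wilcoxon", "modt"])
    def test_label_swap_negates_logratio(self, method):
        rng = np.random.default_rng(13)
        vals = rng.normal(8, 1, size=(15, 10))
        m, pheno = _dataset(vals, 5)
        swapped = PhenotypeTable(pheno.assignments, ("dis", "ctl"))
        fn = getattr(diffexp, f"diffexp_{method}")
        a, b = fn(m, pheno), fn(m, swapped)
        assert np.allclose(a["logratio"], -b["logratio"], atol=1e-12)
        assert np.allclose(a["pval"], b["pval"], atol=1e-9)
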