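"""Two-group differential expression.

Every downstream stage consumes exactly four per-feature quantities:
``logratio`` (log2 case-minus-control mean difference), ``meanExp``
(grand mean on the log2 scale), ``pval`` and ``adj.pval``.  Four test
families are provided: Student/Welch t, Wilcoxon rank-sum, a moderated t
with empirical-Bayes variance shrinkage (optionally with a mean-variance
trend), and a permutation-based rank product.  Differential expression is
an annotation, not a filter: the pipeline never drops features by DE.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess
from statsmodels.stats.multitest import multipletests

from .core_data import DataError, ExpressionMatrix, PhenotypeTable

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["feature", "logratio", "meanExp", "pval", "adj.pval"]

_TINY_P = float(np.nextafter(0.0, 1.0))


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment (Benjamini-Hochberg step-up or Bonferroni).

    Output order matches input order; values are capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    key = {"BH": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise DataError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]


def _split_groups(m: ExpressionMatrix, pheno: PhenotypeTable):
    samples = m.sample_ids
    pheno = pheno.subset(samples)
    # canonical (sorted) order inside each group: results do not depend on
    # the column order of the input matrix, bit for bit
    ctrl = sorted(s for s in samples if pheno.assignments[s] == pheno.control_label)
    case = sorted(s for s in samples if pheno.assignments[s] == pheno.case_label)
    if len(ctrl) < 2 or len(case) < 2:
        raise DataError("need >= 2 samples per group for differential expression")
    x = m.values.loc[:, case].to_numpy()
    y = m.values.loc[:, ctrl].to_numpy()
    return x, y  # case, control


def _assemble(
    m: ExpressionMatrix,
    logratio: np.ndarray,
    pval: np.ndarray,
    method: str,
    adjust: str,
) -> pd.DataFrame:
    pval = np.clip(pval, _TINY_P, 1.0)
    out = pd.DataFrame(
        {
            "feature": m.feature_ids,
            "logratio": logratio,
            "meanExp": m.values.mean(axis=1).to_numpy(),
            "pval": pval,
            "adj.pval": adjust_pvalues(pval, adjust),
        }
    )
    out.attrs["method"] = method
    return out


def diffexp_ttest(
    m: ExpressionMatrix,
    pheno: PhenotypeTable,
    equal_var: bool = True,
    adjust: str = "BH",
) -> pd.DataFrame:
    """Two-sample t test per feature (two-sided).

    Features with zero variance in both groups get p = 1 when the group
    means agree and the smallest positive p otherwise, with a logged note.
    """
    x, y = _split_groups(m, pheno)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(x, y, axis=1, equal_var=equal_var)
        pval = np.asarray(res.pvalue, dtype=float)
    logratio = x.mean(axis=1) - y.mean(axis=1)
    degenerate = (x.var(axis=1) == 0) & (y.var(axis=1) == 0)
    if degenerate.any():
        logger.info("%d features with zero variance in both groups", int(degenerate.sum()))
        pval[degenerate & (logratio == 0)] = 1.0
        pval[degenerate & (logratio != 0)] = _TINY_P
    pval[~np.isfinite(pval)] = 1.0
    return _assemble(m, logratio, pval, "ttest", adjust)


def diffexp_wilcoxon(
    m: ExpressionMatrix, pheno: PhenotypeTable, adjust: str = "BH"
) -> pd.DataFrame:
    """Wilcoxon rank-sum (Mann-Whitney) test per feature, two-sided.

    Exact null distribution for small tie-free samples, tie-corrected
    normal approximation otherwise.  Effect summaries (logratio, meanExp)
    stay mean-based even for this rank test.
    """
    x, y = _split_groups(m, pheno)
    pval = np.empty(x.shape[0])
    for i in range(x.shape[0]):
        if np.ptp(np.concatenate([x[i], y[i]])) == 0:
            pval[i] = 1.0
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.mannwhitneyu(x[i], y[i], alternative="two-sided", method="auto")
        pval[i] = 1.0 if not np.isfinite(res.pvalue) else res.pvalue
    logratio = x.mean(axis=1) - y.mean(axis=1)
    return _assemble(m, logratio, pval, "wilcoxon", adjust)


def _trigamma_inverse(y: float) -> float:
    # Newton iteration for trigamma^{-1}; monotone decreasing target.
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
        x = max(x, 1e-8)
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: float, covariate: np.ndarray | None,
                        lowess_frac: float):
    """Empirical-Bayes scaled inverse-chi-square prior for gene variances.

    Returns (d0, s0sq) where s0sq is scalar (no trend) or per-feature
    (trend: smooth function of mean expression).  Method-of-moments fit on
    log variances, as is standard for moderated-t shrinkage.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        raise DataError("too few positive-variance features to fit a variance prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    if covariate is None:
        emean = e.mean()
        ehat_all = np.full(s2.shape, emean)
        resid = e - emean
    else:
        cov_ok = covariate[ok]
        fit = _lowess(e, cov_ok, frac=lowess_frac, return_sorted=True)
        ehat_ok = np.interp(cov_ok, fit[:, 0], fit[:, 1])
        ehat_all = np.interp(covariate, fit[:, 0], fit[:, 1])
        resid = e - ehat_ok
    evar = resid.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(float(evar))
        s0sq = np.exp(ehat_all + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0sq = np.exp(ehat_all)
    return d0, s0sq


def diffexp_modt(
    m: ExpressionMatrix,
    pheno: PhenotypeTable,
    trend: bool = False,
    lowess_frac: float = 0.5,
    prior_df: float | None = None,
    adjust: str = "BH",
) -> pd.DataFrame:
    """Moderated t test with empirical-Bayes variance shrinkage.

    Per-feature pooled variances are shrunk toward a prior fitted across
    features (scaled inverse-chi-square model); with ``trend`` the prior
    variance is a lowess-smooth function of mean expression.  P-values come
    from a t distribution with residual + prior degrees of freedom.
    ``prior_df`` overrides the estimated prior df (0 recovers the ordinary
    equal-variance t test).
    """
    if trend and m.n_features < 10:
        raise DataError("mean-variance trend needs >= 10 features")
    x, y = _split_groups(m, pheno)
    n1, n2 = x.shape[1], y.shape[1]
    df_resid = float(n1 + n2 - 2)
    s2 = (x.var(axis=1, ddof=1) * (n1 - 1) + y.var(axis=1, ddof=1) * (n2 - 1)) / df_resid
    mean_exp = m.values.mean(axis=1).to_numpy()
    covariate = mean_exp if trend else None
    if prior_df is None:
        d0, s0sq = _fit_variance_prior(s2, df_resid, covariate, lowess_frac)
    else:
        d0 = float(prior_df)
        if d0 > 0:
            _, s0sq = _fit_variance_prior(s2, df_resid, covariate, lowess_frac)
        else:
            s0sq = np.zeros_like(s2)
    if np.isinf(d0):
        s2_post = np.broadcast_to(np.atleast_1d(s0sq), s2.shape).astype(float)
        df_total = 1e9
    else:
        s2_post = (d0 * s0sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    logratio = x.mean(axis=1) - y.mean(axis=1)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logratio / se
    pval = 2.0 * stats.t.sf(np.abs(t), df_total)
    degenerate = se == 0
    if degenerate.any():
        pval[degenerate & (logratio == 0)] = 1.0
        pval[degenerate & (logratio != 0)] = _TINY_P
    out = _assemble(m, logratio, pval, "modt", adjust)
    out.attrs["prior_df"] = float(d0)
    return out


def _rank_products(x: np.ndarray, y: np.ndarray):
    """Log rank products (down- and up-regulation) over all case x control
    pairwise fold changes.  Smaller is more extreme."""
    nf = x.shape[0]
    # diffs: feature x (case, control) comparisons
    diffs = (x[:, :, None] - y[:, None, :]).reshape(nf, -1)
    ranks_down = stats.rankdata(diffs, axis=0)        # rank 1 = most negative FC
    ranks_up = nf + 1 - ranks_down
    log_rp_down = np.log(ranks_down).mean(axis=1)
    log_rp_up = np.log(ranks_up).mean(axis=1)
    return log_rp_down, log_rp_up


def diffexp_rankprod(
    m: ExpressionMatrix,
    pheno: PhenotypeTable,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank-product test with permutation p-values.

    The one-directional statistic per feature is the geometric mean of its
    fold-change rank over every case-vs-control sample pairing; the
    two-sided test statistic is the smaller (more extreme) of the down- and
    up-regulation rank products, so a single permutation tail covers both
    directions.  Significance comes from ``n_perm`` label permutations,
    pooling the permuted statistics over all features.  Adjustment is
    always Benjamini-Hochberg.
    """
    if n_perm < 100:
        raise DataError("n_perm must be >= 100 for stable permutation p-values")
    x, y = _split_groups(m, pheno)
    n1, n2 = x.shape[1], y.shape[1]
    nf = x.shape[0]
    obs_down, obs_up = _rank_products(x, y)
    obs_stat = np.minimum(obs_down, obs_up)
    rng = np.random.default_rng(seed)
    both = np.concatenate([x, y], axis=1)
    count = np.zeros(nf)
    for _ in range(n_perm):
        perm = rng.permutation(n1 + n2)
        px, py = both[:, perm[:n1]], both[:, perm[n1:]]
        pd_down, pd_up = _rank_products(px, py)
        null_stat = np.minimum(pd_down, pd_up)
        count += np.searchsorted(np.sort(null_stat), obs_stat, side="right")
    pval = (count + 1.0) / (n_perm * nf + 1.0)
    logratio = x.mean(axis=1) - y.mean(axis=1)
    out = _assemble(m, logratio, pval, "rankprod", "BH")
    out["rank_product_down"] = np.exp(obs_down)
    out["rank_product_up"] = np.exp(obs_up)
    return out


def write_diffexp(table: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"differential-expression table missing columns: {missing}")
    table.to_csv(path, sep=sep, index=False)


def import_diffexp(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read an externally computed DE table.

    Requires columns feature, logratio, meanExp, pval, adj.pval; extra
    columns are preserved but ignored downstream.
    """
    from .core_data import _sniff_sep

    sep = _sniff_sep(path, sep)
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"differential-expression table missing columns: {missing}")
    df["feature"] = df["feature"].astype(str)
    for col in ("pval", "adj.pval"):
        v = df[col].to_numpy(dtype=float)
        if np.any((v < 0) | (v > 1) | ~np.isfinite(v)):
            raise DataError(f"column {col!r} outside [0, 1]")
    if df["feature"].duplicated().any():
        raise DataError("duplicate feature ids in imported table")
    df.attrs["method"] = "imported"
    return df
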