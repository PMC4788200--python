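"""All-pairs miRNA x mRNA correlation with a one-sided negative test.

Because a miRNA represses its targets (mostly by promoting degradation),
a genuine interaction shows up as a *negative* expression correlation.
Each miRNA-mRNA couple is therefore tested one-sided:

    H0: rho >= 0     vs     H1: rho < 0

with the p-value taken from the lower tail of the test statistic at the
null boundary rho = 0.  Pearson uses t = r * sqrt(n-2) / sqrt(1 - r^2);
Spearman applies the same machinery to (tie-corrected) ranks; Kendall
uses tau-b with a normal approximation and is refused above a pair-count
ceiling.  The multiple-testing family is always *all* computed pairs.

Correlations are computed one miRNA row at a time inside row blocks, so
results are bitwise identical for any block size and peak intermediate
memory stays proportional to block_rows x n_mRNA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import DataError, ExpressionDataset
from .diffexp import adjust_pvalues

PAIR_COLUMNS = ["miRNA", "mRNA", "cor", "pval", "adj.pval"]

_TINY_P = float(np.nextafter(0.0, 1.0))


def family_size(n_mirna: int, n_mrna: int) -> int:
    """Number of correlations computed: every miRNA paired with every mRNA."""
    return int(n_mirna) * int(n_mrna)


def percent_of_family(count: int, total: int) -> float:
    """A count expressed as a percentage of the correlation family, to 2 dp."""
    if total <= 0:
        raise DataError("family size must be positive")
    return round(100.0 * count / total, 2)


def _standardize_rows(a: np.ndarray):
    """Center rows and return (centered, row norms, zero-variance mask)."""
    centered = a - a.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered * centered).sum(axis=1))
    const = norms == 0
    return centered, norms, const


def _pearson_pvalue_lower(r: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    return stats.t.cdf(t, n - 2)


def correlate_all(
    ds: ExpressionDataset,
    method: str = "pearson",
    block_rows: int | None = None,
    adjust: str = "BH",
    kendall_max_pairs: int = 2_000_000,
) -> pd.DataFrame:
    """Correlate every miRNA with every mRNA and test for negative association.

    Returns a table with one row per (miRNA, mRNA) pair: columns ``miRNA``,
    ``mRNA``, ``cor``, ``pval`` (one-sided, lower tail), ``adj.pval``
    (family = all pairs) and ``constant`` flagging pairs involving a
    zero-variance feature (reported as cor 0, p 1).
    """
    if method not in ("pearson", "spearman", "kendall"):
        raise DataError(f"unknown correlation method {method!r}")
    x = ds.mirna.values.to_numpy()
    y = ds.mrna.values.to_numpy()
    n = x.shape[1]
    if n < 4:
        raise DataError("need >= 4 shared samples for the one-sided correlation test")
    nm, ng = x.shape[0], y.shape[0]
    if method == "kendall" and family_size(nm, ng) > kendall_max_pairs:
        raise DataError(
            f"kendall refused for {family_size(nm, ng)} pairs "
            f"(> ceiling {kendall_max_pairs}); intended for small datasets"
        )
    if block_rows is None:
        block_rows = nm
    if block_rows < 1:
        raise DataError("block_rows must be >= 1")

    cor = np.empty(nm * ng)
    pval = np.empty(nm * ng)
    const_flag = np.zeros(nm * ng, dtype=bool)

    if method == "kendall":
        for i in range(nm):
            for j in range(ng):
                idx = i * ng + j
                if np.ptp(x[i]) == 0 or np.ptp(y[j]) == 0:
                    cor[idx], pval[idx], const_flag[idx] = 0.0, 1.0, True
                    continue
                res = stats.kendalltau(x[i], y[j], variant="b")
                tau, p2 = float(res.statistic), float(res.pvalue)
                cor[idx] = tau
                pval[idx] = p2 / 2.0 if tau < 0 else 1.0 - p2 / 2.0
    else:
        xr = stats.rankdata(x, axis=1) if method == "spearman" else x
        yr = stats.rankdata(y, axis=1) if method == "spearman" else y
        yc, ynorm, yconst = _standardize_rows(yr)
        xc, xnorm, xconst = _standardize_rows(xr)
        for start in range(0, nm, block_rows):
            stop = min(start + block_rows, nm)
            block = np.empty((stop - start, ng))
            for i in range(start, stop):
                if xconst[i]:
                    block[i - start] = 0.0
                    continue
                # per-row gemv: identical result regardless of blocking
                r = yc @ xc[i]
                denom = ynorm * xnorm[i]
                with np.errstate(divide="ignore", invalid="ignore"):
                    r = np.where(yconst, 0.0, r / np.where(denom == 0, 1.0, denom))
                block[i - start] = np.clip(r, -1.0, 1.0)
            p = _pearson_pvalue_lower(block, n)
            rows_const = xconst[start:stop, None] | yconst[None, :]
            p = np.where(rows_const, 1.0, p)
            block = np.where(rows_const, 0.0, block)
            sl = slice(start * ng, stop * ng)
            cor[sl] = block.ravel()
            pval[sl] = p.ravel()
            const_flag[sl] = rows_const.ravel()

    pval = np.clip(pval, _TINY_P, 1.0)
    out = pd.DataFrame(
        {
            "miRNA": np.repeat(np.asarray(ds.mirna.feature_ids, dtype=object), ng),
            "mRNA": np.tile(np.asarray(ds.mrna.feature_ids, dtype=object), nm),
            "cor": cor,
            "pval": pval,
            "adj.pval": adjust_pvalues(pval, adjust),
            "constant": const_flag,
        }
    )
    out.attrs["method"] = method
    out.attrs["n_samples"] = n
    return out


def significant_pairs(
    table: pd.DataFrame, alpha: float, on: str = "adj.pval"
) -> pd.DataFrame:
    """Pairs with negative correlation below the chosen significance cutoff."""
    if not (0 < alpha <= 1):
        raise DataError("alpha must lie in (0, 1]")
    if on not in ("pval", "adj.pval"):
        raise DataError("selection column must be 'pval' or 'adj.pval'")
    mask = (table[on].to_numpy() < alpha) & (table["cor"].to_numpy() < 0)
    return table.loc[mask].copy()


@dataclass
class CorrelationSummary:
    """Histogram of correlation coefficients plus counts at standard cutoffs."""

    bin_edges: np.ndarray          # 102 edges -> 101 bins on [-1, 1]
    counts: np.ndarray
    cutoff_counts: dict[str, int]  # p<0.05, p<0.01, FDR<0.05, FDR<0.01
    n_pairs: int
    mean_cor: float


def correlation_density_summary(table: pd.DataFrame) -> CorrelationSummary:
    if len(table) == 0:
        raise DataError("empty correlation table")
    cor = table["cor"].to_numpy()
    edges = np.linspace(-1.0, 1.0, 102)
    counts, _ = np.histogram(cor, bins=edges)
    neg = table["cor"].to_numpy() < 0
    p = table["pval"].to_numpy()
    q = table["adj.pval"].to_numpy()
    cutoffs = {
        "p<0.05": int(((p < 0.05) & neg).sum()),
        "p<0.01": int(((p < 0.01) & neg).sum()),
        "FDR<0.05": int(((q < 0.05) & neg).sum()),
        "FDR<0.01": int(((q < 0.01) & neg).sum()),
    }
    return CorrelationSummary(edges, counts, cutoffs, len(table), float(cor.mean()))


def write_pair_table(table: pd.DataFrame, path, sep: str = "\t") -> None:
    cols = [c for c in PAIR_COLUMNS if c in table.columns]
    missing = [c for c in PAIR_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"pair table missing columns: {missing}")
    table.loc[:, cols].to_csv(path, sep=sep, index=False)


def read_pair_table(path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"pair table missing columns: {missing}")
    df["miRNA"] = df["miRNA"].astype(str)
    df["mRNA"] = df["mRNA"].astype(str)
    return df
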