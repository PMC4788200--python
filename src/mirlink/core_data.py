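"""Data model, readers/writers, expression filtering and sample alignment.

The pipeline consumes two expression matrices (miRNA x samples and
mRNA x samples) on a log2 scale, plus a two-group phenotype table.  Raw
count matrices may be ingested first and passed through the median-count
filter and a log2(x + pseudocount) transform.  All downstream stages
operate on an :class:`ExpressionDataset`, which guarantees that the two
matrices share an identical, ordered set of samples and that every
sample carries a group label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RAW_COUNTS = "raw_counts"
LOG2 = "log2"
_SCALES = (RAW_COUNTS, LOG2)


class DataError(ValueError):
    """Raised when an input matrix or phenotype table violates a contract."""


@dataclass
class ExpressionMatrix:
    """A feature x sample expression matrix with a declared scale.

    Parameters
    ----------
    values
        DataFrame with feature ids as index and sample ids as columns.
        Cells must be finite numbers; missing values are rejected.
    scale
        Either ``"raw_counts"`` (non-negative counts, pre-normalization)
        or ``"log2"`` (log2-normalized expression, the analysis scale).
    """

    values: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise DataError(f"unknown scale {self.scale!r}; expected one of {_SCALES}")
        v = self.values
        if v.shape[0] == 0 or v.shape[1] == 0:
            raise DataError("empty expression matrix")
        if v.index.duplicated().any():
            dups = sorted(set(v.index[v.index.duplicated()]))
            raise DataError(f"duplicate feature ids: {dups}")
        if v.columns.duplicated().any():
            dups = sorted(set(v.columns[v.columns.duplicated()]))
            raise DataError(f"duplicate sample ids: {dups}")
        if any(str(i) == "" for i in v.index):
            raise DataError("empty feature id")
        try:
            arr = v.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise DataError(f"non-numeric cells in expression matrix: {exc}") from exc
        bad = ~np.isfinite(arr)
        if bad.any():
            cells = [
                (str(v.index[i]), str(v.columns[j]))
                for i, j in zip(*np.nonzero(bad))
            ][:20]
            raise DataError(f"missing or non-finite cells (feature, sample): {cells}")
        # normalize dtype once so downstream math never re-coerces
        self.values = v.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class PhenotypeTable:
    """Sample -> group assignment for a two-group design.

    ``group_order`` is the ordered pair ``(control_label, case_label)``;
    log-ratios downstream are case minus control.
    """

    assignments: pd.Series  # index: sample_id, value: group label
    group_order: tuple[str, str]

    def __post_init__(self) -> None:
        self.assignments = self.assignments.astype(str)
        control, case = self.group_order
        if control == case:
            raise DataError("control and case labels must differ")
        labels = set(self.assignments.unique())
        extra = labels - {control, case}
        if extra:
            raise DataError(f"phenotype labels outside group_order: {sorted(extra)}")
        if self.assignments.index.duplicated().any():
            raise DataError("duplicate sample ids in phenotype table")

    @property
    def control_label(self) -> str:
        return self.group_order[0]

    @property
    def case_label(self) -> str:
        return self.group_order[1]

    def samples_of(self, label: str) -> list[str]:
        return [str(s) for s in self.assignments.index[self.assignments == label]]

    def subset(self, samples: Iterable[str]) -> "PhenotypeTable":
        samples = list(samples)
        missing = [s for s in samples if s not in self.assignments.index]
        if missing:
            raise DataError(f"samples without phenotype assignment: {missing}")
        return PhenotypeTable(self.assignments.loc[samples], self.group_order)


@dataclass
class ExpressionDataset:
    """Paired miRNA/mRNA matrices plus phenotype, aligned on samples."""

    mirna: ExpressionMatrix
    mrna: ExpressionMatrix
    pheno: PhenotypeTable

    def __post_init__(self) -> None:
        if self.mirna.sample_ids != self.mrna.sample_ids:
            raise DataError("miRNA and mRNA matrices must share identical sample order")
        if self.mirna.scale != LOG2 or self.mrna.scale != LOG2:
            raise DataError("both matrices must be on log2 scale")
        unassigned = [
            s for s in self.mirna.sample_ids if s not in self.pheno.assignments.index
        ]
        if unassigned:
            raise DataError(f"samples without phenotype assignment: {unassigned}")
        for label in self.pheno.group_order:
            n = sum(
                1 for s in self.mirna.sample_ids
                if self.pheno.assignments[s] == label
            )
            if n < 2:
                raise DataError(
                    f"group {label!r} has {n} samples after alignment; need >= 2"
                )

    @property
    def sample_ids(self) -> list[str]:
        return self.mirna.sample_ids


def _sniff_sep(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_expression(path: str | Path, scale: str, sep: str | None = None) -> ExpressionMatrix:
    """Read a delimited expression matrix (features in rows, samples in columns).

    The first column holds feature ids, the header row sample ids.
    Delimiter is auto-detected among tab and comma unless given.
    """
    sep = _sniff_sep(path, sep)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:
        raise DataError(f"malformed expression file {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise DataError(f"no sample columns in {path}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, scale)


def write_expression(m: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    m.values.to_csv(path, sep=sep, index_label="feature")


def read_phenotype(
    path: str | Path,
    control_label: str,
    case_label: str | None = None,
    sep: str | None = None,
) -> PhenotypeTable:
    """Read a two-column (sample_id, group) table.

    ``case_label`` defaults to the single other label present in the file.
    """
    sep = _sniff_sep(path, sep)
    df = pd.read_csv(path, sep=sep, header=0)
    if df.shape[1] < 2:
        raise DataError(f"phenotype table {path} needs >= 2 columns")
    assignments = pd.Series(
        df.iloc[:, 1].astype(str).to_numpy(), index=df.iloc[:, 0].astype(str)
    )
    labels = set(assignments.unique())
    if control_label not in labels:
        raise DataError(f"control label {control_label!r} absent from phenotype table")
    if case_label is None:
        others = sorted(labels - {control_label})
        if len(others) != 1:
            raise DataError(
                f"cannot infer case label: remaining labels are {others}"
            )
        case_label = others[0]
    return PhenotypeTable(assignments, (control_label, case_label))


def write_phenotype(p: PhenotypeTable, path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame({"sample": p.assignments.index, "group": p.assignments.to_numpy()}).to_csv(
        path, sep=sep, index=False
    )


def filter_low_expression(m: ExpressionMatrix, min_median: float = 10.0) -> ExpressionMatrix:
    """Drop features whose median raw count across all samples is below threshold.

    The rule is strict — a feature with median exactly ``min_median`` is
    kept.  Defined on raw counts only: applying it to log2 data is an error.
    """
    if m.scale != RAW_COUNTS:
        raise DataError("median-count filter is defined on raw counts, not log2 data")
    medians = m.values.median(axis=1)
    kept = m.values.loc[medians >= min_median]
    if kept.shape[0] == 0:
        raise DataError("all features removed by low-expression filter")
    n_removed = m.n_features - kept.shape[0]
    if n_removed:
        logger.info("low-expression filter removed %d/%d features", n_removed, m.n_features)
    return ExpressionMatrix(kept, RAW_COUNTS)


def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(x + pseudocount) transform of a non-negative count matrix."""
    arr = m.values.to_numpy()
    if (arr < 0).any():
        raise DataError("negative values: log2 transform expects counts >= 0")
    out = pd.DataFrame(
        np.log2(arr + pseudocount), index=m.values.index, columns=m.values.columns
    )
    return ExpressionMatrix(out, LOG2)


def align_dataset(
    mirna: ExpressionMatrix, mrna: ExpressionMatrix, pheno: PhenotypeTable
) -> ExpressionDataset:
    """Intersect and canonically order samples across both matrices and phenotype.

    Samples present in the matrices but absent from the phenotype table are
    dropped with a logged warning.  Output sample order is sorted, so the
    result does not depend on input column order.
    """
    if mirna.scale != LOG2 or mrna.scale != LOG2:
        raise DataError("align_dataset expects both matrices on log2 scale")
    shared = set(mirna.sample_ids) & set(mrna.sample_ids)
    if not shared:
        raise DataError("no samples shared between miRNA and mRNA matrices")
    with_pheno = shared & set(pheno.assignments.index.astype(str))
    dropped = sorted(shared - with_pheno)
    if dropped:
        logger.warning("dropping %d samples without phenotype: %s", len(dropped), dropped)
    if not with_pheno:
        raise DataError("no shared samples carry a phenotype assignment")
    order = sorted(with_pheno)
    ds = ExpressionDataset(
        ExpressionMatrix(mirna.values.loc[:, order], LOG2),
        ExpressionMatrix(mrna.values.loc[:, order], LOG2),
        pheno.subset(order),
    )
    return ds
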