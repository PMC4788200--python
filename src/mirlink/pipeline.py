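"""End-to-end orchestration: data -> DE -> correlation -> intersection ->
network -> enrichment -> report, with every intermediate written as TSV.

The pipeline is deterministic: identical configuration and inputs yield
byte-identical outputs, recorded in a manifest of row counts and sha256
checksums (text outputs only; PNG plots are presentation artifacts and
are not checksummed).  Any stage failure aborts with the stage name and
cause, renaming already-written outputs with a ``.partial`` suffix.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core_data, correlation, diffexp, enrichment, network, targets
from .core_data import DataError

logger = logging.getLogger(__name__)

STAGES = [
    "core_data", "diffexp", "correlation", "integration",
    "network", "enrichment", "report",
]

_DE_METHODS = {
    "ttest": diffexp.diffexp_ttest,
    "wilcoxon": diffexp.diffexp_wilcoxon,
    "modt": diffexp.diffexp_modt,
    "rankprod": diffexp.diffexp_rankprod,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    mirna_path: str
    mrna_path: str
    pheno_path: str
    control_label: str
    case_label: str | None = None
    database_paths: list = field(default_factory=list)
    out_dir: str = "mirlink_out"
    mirna_scale: str = core_data.LOG2
    mrna_scale: str = core_data.LOG2
    min_median: float = 10.0       # raw-count median filter (raw inputs only)
    pseudocount: float = 1.0
    de_method: str = "ttest"
    corr_method: str = "pearson"
    alpha: float = 0.05
    alpha_on: str = "adj.pval"
    adjust: str = "BH"
    min_dat_sum: int = 1
    gmt_path: str | None = None
    min_set: int = 5
    max_network_edges: int = 100
    seed: int = 0
    report: bool = True

    def __post_init__(self):
        if self.de_method not in _DE_METHODS:
            raise DataError(f"unknown DE method {self.de_method!r}")
        if self.corr_method not in ("pearson", "spearman", "kendall"):
            raise DataError(f"unknown correlation method {self.corr_method!r}")
        if self.adjust not in ("BH", "bonferroni"):
            raise DataError(f"unknown adjustment {self.adjust!r}")
        for p in [self.mirna_path, self.mrna_path, self.pheno_path,
                  *self.database_paths, *( [self.gmt_path] if self.gmt_path else [] )]:
            if not Path(p).exists():
                raise DataError(f"input path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise DataError(f"config {path} is not a mapping")
        return cls(**raw)


def sample_pca(m: core_data.ExpressionMatrix, n_components: int = 2) -> pd.DataFrame:
    """PCA of samples based on the correlation matrix of features.

    Features are standardized across samples (zero-variance features
    dropped), then sample scores come from the SVD of the standardized
    matrix — equivalent to eigendecomposing the feature correlation
    matrix.  Deterministic sign convention: largest-|score| positive.
    """
    v = m.values.to_numpy()
    sd = v.std(axis=1, ddof=1)
    ok = sd > 0
    z = (v[ok] - v[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
    u, s, vt = np.linalg.svd(z.T / np.sqrt(max(ok.sum() - 1, 1)), full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    for j in range(scores.shape[1]):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    total_var = float((s * s).sum())
    out = pd.DataFrame(
        scores, index=m.sample_ids,
        columns=[f"PC{i+1}" for i in range(scores.shape[1])],
    )
    out.attrs["explained_fraction"] = [float(x * x) / total_var for x in s[:n_components]]
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _n_rows(path: Path) -> int:
    with open(path) as fh:
        n = sum(1 for _ in fh)
    # header-less SIF counts all lines; headered TSVs count data rows
    return max(n - 1, 0) if path.suffix == ".tsv" or path.suffix == ".html" else n


def load_inputs(cfg: PipelineConfig) -> tuple[core_data.ExpressionDataset, list]:
    """Read, filter/transform as needed, and align the pipeline inputs."""
    mirna = core_data.read_expression(cfg.mirna_path, cfg.mirna_scale)
    mrna = core_data.read_expression(cfg.mrna_path, cfg.mrna_scale)
    if mirna.scale == core_data.RAW_COUNTS:
        mirna = core_data.log2_transform(
            core_data.filter_low_expression(mirna, cfg.min_median), cfg.pseudocount
        )
    if mrna.scale == core_data.RAW_COUNTS:
        mrna = core_data.log2_transform(
            core_data.filter_low_expression(mrna, cfg.min_median), cfg.pseudocount
        )
    pheno = core_data.read_phenotype(cfg.pheno_path, cfg.control_label, cfg.case_label)
    ds = core_data.align_dataset(mirna, mrna, pheno)
    dbs = [targets.load_target_db(p) for p in cfg.database_paths]
    return ds, dbs


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute every stage, writing TSV outputs and a checksum manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[tuple[str, Path]] = []
    current_stage = "core_data"

    def emit(stage: str, name: str, writer) -> Path:
        path = out / name
        writer(path)
        written.append((stage, path))
        return path

    try:
        # ---- core_data ----
        ds, dbs = load_inputs(cfg)
        nm, ng = ds.mirna.n_features, ds.mrna.n_features
        summary = pd.DataFrame(
            [
                ("n_mirna", nm),
                ("n_mrna", ng),
                ("n_samples", ds.mirna.n_samples),
                ("n_control", len(ds.pheno.samples_of(ds.pheno.control_label))),
                ("n_case", len(ds.pheno.samples_of(ds.pheno.case_label))),
                ("total_correlations", correlation.family_size(nm, ng)),
            ],
            columns=["quantity", "value"],
        )
        emit("core_data", "dataset_summary.tsv",
             lambda p: summary.to_csv(p, sep="\t", index=False))
        for label, mat in (("mirna", ds.mirna), ("mrna", ds.mrna)):
            pca = sample_pca(mat)
            pca["group"] = [ds.pheno.assignments[s] for s in mat.sample_ids]
            emit("core_data", f"pca_samples_{label}.tsv",
                 lambda p, pca=pca: pca.to_csv(p, sep="\t", index_label="sample"))

        # ---- diffexp ----
        current_stage = "diffexp"
        de_fn = _DE_METHODS[cfg.de_method]
        kwargs = {"seed": cfg.seed} if cfg.de_method == "rankprod" else {}
        if cfg.de_method != "rankprod":
            kwargs["adjust"] = cfg.adjust
        de_mir = de_fn(ds.mirna, ds.pheno, **kwargs)
        de_mrna = de_fn(ds.mrna, ds.pheno, **kwargs)
        emit("diffexp", "diffexp_mirna.tsv", lambda p: diffexp.write_diffexp(de_mir, p))
        emit("diffexp", "diffexp_mrna.tsv", lambda p: diffexp.write_diffexp(de_mrna, p))

        # ---- correlation ----
        current_stage = "correlation"
        pairs = correlation.correlate_all(ds, method=cfg.corr_method, adjust=cfg.adjust)
        emit("correlation", "corr_pairs.tsv", lambda p: correlation.write_pair_table(pairs, p))
        csum = correlation.correlation_density_summary(pairs)
        cutoff_df = pd.DataFrame(
            [("total", csum.n_pairs), ("mean_cor", csum.mean_cor)]
            + list(csum.cutoff_counts.items()),
            columns=["quantity", "value"],
        )
        emit("correlation", "corr_summary.tsv",
             lambda p: cutoff_df.to_csv(p, sep="\t", index=False))
        hist_df = pd.DataFrame(
            {"bin_left": csum.bin_edges[:-1], "bin_right": csum.bin_edges[1:],
             "count": csum.counts}
        )
        emit("correlation", "corr_hist.tsv",
             lambda p: hist_df.to_csv(p, sep="\t", index=False))

        # ---- integration ----
        current_stage = "integration"
        if not dbs:
            raise DataError(
                "no target databases configured; correlation results are "
                "written but interactions cannot be called"
            )
        sig = correlation.significant_pairs(pairs, cfg.alpha, cfg.alpha_on)
        combined = targets.intersect_with_targets(sig, de_mir, de_mrna, dbs, cfg.min_dat_sum)
        emit("integration", "combined_pairs.tsv", lambda p: targets.write_combined(combined, p))
        predicted = targets.union_pairs(dbs)
        expressed_pred = frozenset(
            (a, b) for a, b in predicted
            if a in set(ds.mirna.feature_ids) and b in set(ds.mrna.feature_ids)
        )
        inter_df = pd.DataFrame(
            [
                ("n_significant", len(sig)),
                ("n_predicted_expressed", len(expressed_pred)),
                ("n_interactions", len(combined)),
            ],
            columns=["quantity", "value"],
        )
        emit("integration", "intersection_summary.tsv",
             lambda p: inter_df.to_csv(p, sep="\t", index=False))
        fp = targets.mirna_fp_ratio(expressed_pred, combined)
        emit("integration", "mirna_fp_ratio.tsv",
             lambda p: fp.to_csv(p, sep="\t", index=False))
        counts = targets.count_summaries(combined, ng)
        emit("integration", "targets_per_mirna.tsv",
             lambda p: counts.targets_per_mirna.to_csv(p, sep="\t", index=False))
        emit("integration", "mirnas_per_mrna.tsv",
             lambda p: counts.mirnas_per_mrna.to_csv(p, sep="\t", index=False))
        pie_df = pd.DataFrame(
            list(counts.mirnas_per_mrna_pie.items()), columns=["n_mirnas", "n_mrnas"]
        )
        emit("integration", "mirnas_per_mrna_pie.tsv",
             lambda p: pie_df.to_csv(p, sep="\t", index=False))
        emit("integration", "cumulative_coverage.tsv",
             lambda p: counts.cumulative_coverage.to_csv(p, sep="\t", index=False))
        top15 = targets.top_interactions(combined, 15) if len(combined) else combined
        emit("integration", "top_interactions.tsv",
             lambda p: top15.to_csv(p, sep="\t", index=False))

        # ---- network ----
        current_stage = "network"
        if len(combined):
            net = network.build_network(combined, cfg.max_network_edges)
            files = network.export_sif(net, out / "network")
            for f in files:
                written.append(("network", f))
        else:
            logger.warning("no interactions; network stage skipped")

        # ---- enrichment ----
        current_stage = "enrichment"
        if cfg.gmt_path and len(combined):
            universe = frozenset(ds.mrna.feature_ids)
            gsc = enrichment.read_gmt(cfg.gmt_path, universe=universe)
            targeted = set(combined["mRNA"])
            enr = enrichment.enrich(targeted, gsc, cfg.min_set)
            emit("enrichment", "enrichment.tsv",
                 lambda p: enr.to_csv(p, sep="\t", index=False))

        # ---- report ----
        current_stage = "report"
        if cfg.report:
            from .report import make_report

            report_path = make_report(out)
            written.append(("report", report_path))

        # ---- manifest ----
        manifest = pd.DataFrame(
            [
                {
                    "stage": stage,
                    "file": path.name,
                    "n_rows": _n_rows(path),
                    "sha256": _sha256(path),
                }
                for stage, path in written
            ]
        )
        manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    except Exception as exc:
        for _, path in written:
            if path.exists():
                path.rename(path.with_name(path.name + ".partial"))
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(current_stage, exc) from exc
    return out
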