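"""Standardized HTML analysis report.

Renders the pipeline's TSV outputs into a single HTML page whose section
order mirrors the classic pdf report of this kind of analysis: data
summary & sample PCA, differential-expression summaries, correlation
summary, intersection summary, top interactions, network statistics,
target-count tables, pie/coverage, and enrichment.  Sections whose
underlying stage output is absent render an explicit "not computed"
marker.  Every number shown is read back from (or recomputed from) the
TSVs in the output directory, so the report is re-derivable.
"""

from __future__ import annotations

import html
from pathlib import Path

import pandas as pd

from . import targets

SECTIONS = [
    "Data summary",
    "Differential expression",
    "Correlation analysis",
    "Intersection with target predictions",
    "Top interactions",
    "Network",
    "Targets per miRNA and per mRNA",
    "Target coverage",
    "Functional enrichment",
]

_NOT_COMPUTED = '<p class="missing">not computed</p>'

_STYLE = """
body { font-family: sans-serif; margin: 2em; max-width: 70em; }
h2 { border-bottom: 1px solid #ccc; padding-bottom: 0.2em; }
table { border-collapse: collapse; font-size: 0.85em; }
th, td { border: 1px solid #ddd; padding: 0.25em 0.6em; text-align: right; }
th { background: #f0f0f0; }
td:first-child, th:first-child { text-align: left; }
.missing { color: #a00; font-style: italic; }
img { max-width: 40em; display: block; margin: 0.5em 0; }
"""


def _read(out_dir: Path, name: str) -> pd.DataFrame | None:
    path = out_dir / name
    if not path.exists():
        return None
    return pd.read_csv(path, sep="\t")


def _table(df: pd.DataFrame, max_rows: int = 50) -> str:
    shown = df.head(max_rows)
    note = ""
    if len(df) > max_rows:
        note = f"<p>showing first {max_rows} of {len(df)} rows</p>"
    return shown.to_html(index=False, border=0) + note


def _plot_density(out_dir: Path) -> str:
    hist = _read(out_dir, "corr_hist.tsv")
    if hist is None:
        return ""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    centers = (hist["bin_left"] + hist["bin_right"]) / 2
    width = hist["bin_right"] - hist["bin_left"]
    ax.bar(centers, hist["count"], width=width, color="#4878a8")
    ax.set_xlabel("correlation coefficient")
    ax.set_ylabel("pairs")
    fig.tight_layout()
    fig.savefig(out_dir / "corr_density.png", dpi=110)
    plt.close(fig)
    return '<img src="corr_density.png" alt="correlation density">'


def _plot_volcano(out_dir: Path) -> str:
    de = _read(out_dir, "diffexp_mirna.tsv")
    if de is None:
        return ""
    import numpy as np
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    sig = de["adj.pval"] < 0.05
    ax.scatter(de["logratio"], -np.log10(de["pval"]), s=6, c="#999999", label="ns")
    if sig.any():
        ax.scatter(de.loc[sig, "logratio"], -np.log10(de.loc[sig, "pval"]),
                   s=8, c="#c44e52", label="FDR<0.05")
    ax.set_xlabel("log2 fold change (case - control)")
    ax.set_ylabel("-log10 p")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_dir / "volcano_mirna.png", dpi=110)
    plt.close(fig)
    return '<img src="volcano_mirna.png" alt="miRNA volcano">'


def make_report(out_dir: str | Path, filename: str = "report.html") -> Path:
    """Assemble the HTML report from the TSVs in a pipeline output directory."""
    out_dir = Path(out_dir)
    parts: list[str] = []

    # 1 data summary & sample PCA
    summary = _read(out_dir, "dataset_summary.tsv")
    body = _NOT_COMPUTED
    if summary is not None:
        body = _table(summary)
        for label in ("mirna", "mrna"):
            pca = _read(out_dir, f"pca_samples_{label}.tsv")
            if pca is not None:
                body += f"<h3>Sample PCA ({label})</h3>" + _table(pca, 15)
    parts.append(body)

    # 2 differential expression: top-50 by FDR
    body = ""
    for label in ("mirna", "mrna"):
        de = _read(out_dir, f"diffexp_{label}.tsv")
        if de is None:
            continue
        top = de.sort_values(["adj.pval", "pval", "feature"], kind="mergesort").head(50)
        body += f"<h3>Top deregulated features ({label})</h3>" + _table(top)
    if body:
        body = _plot_volcano(out_dir) + body
    parts.append(body or _NOT_COMPUTED)

    # 3 correlation summary
    csum = _read(out_dir, "corr_summary.tsv")
    if csum is not None:
        body = _plot_density(out_dir) + _table(csum)
    else:
        body = _NOT_COMPUTED
    parts.append(body)

    # 4 intersection summary
    inter = _read(out_dir, "intersection_summary.tsv")
    parts.append(_table(inter) if inter is not None else _NOT_COMPUTED)

    # 5 top interactions (single source of truth: recomputed from the
    # combined table with the same deterministic ordering)
    combined_path = out_dir / "combined_pairs.tsv"
    if combined_path.exists():
        combined = targets.read_combined(combined_path)
        top15 = targets.top_interactions(combined, 15) if len(combined) else combined
        parts.append(_table(top15, 15))
    else:
        parts.append(_NOT_COMPUTED)

    # 6 network stats
    sif = out_dir / "network.sif"
    if sif.exists():
        from .network import read_sif

        triples = read_sif(sif)
        mirnas = {t[0] for t in triples}
        mrnas = {t[2] for t in triples}
        stats_df = pd.DataFrame(
            [("edges", len(triples)), ("miRNA nodes", len(mirnas)),
             ("mRNA nodes", len(mrnas))],
            columns=["quantity", "value"],
        )
        parts.append(_table(stats_df))
    else:
        parts.append(_NOT_COMPUTED)

    # 7 targets per miRNA / per mRNA
    body = ""
    tpm = _read(out_dir, "targets_per_mirna.tsv")
    if tpm is not None:
        body += "<h3>miRNAs by number of targets</h3>" + _table(tpm, 20)
    mpm = _read(out_dir, "mirnas_per_mrna.tsv")
    if mpm is not None:
        body += "<h3>mRNAs by number of targeting miRNAs</h3>" + _table(mpm, 20)
    parts.append(body or _NOT_COMPUTED)

    # 8 pie + cumulative coverage
    body = ""
    pie = _read(out_dir, "mirnas_per_mrna_pie.tsv")
    if pie is not None:
        body += "<h3>mRNAs by number of regulating miRNAs</h3>" + _table(pie)
    cov = _read(out_dir, "cumulative_coverage.tsv")
    if cov is not None:
        body += "<h3>Cumulative target coverage</h3>" + _table(cov, 20)
    parts.append(body or _NOT_COMPUTED)

    # 9 enrichment
    enr = _read(out_dir, "enrichment.tsv")
    parts.append(_table(enr, 25) if enr is not None else _NOT_COMPUTED)

    sections_html = "\n".join(
        f'<section id="sec{i+1}"><h2>{i+1}. {html.escape(title)}</h2>\n{body}</section>'
        for i, (title, body) in enumerate(zip(SECTIONS, parts))
    )
    doc = (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        f"<title>miRNA-mRNA interaction report</title><style>{_STYLE}</style></head>"
        f"<body><h1>miRNA-mRNA interaction analysis</h1>\n{sections_html}\n</body></html>\n"
    )
    path = out_dir / filename
    path.write_text(doc)
    return path
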