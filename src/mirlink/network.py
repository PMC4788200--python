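"""Interaction network construction and Cytoscape export.

Nodes are miRNAs and mRNAs annotated with their log-ratio and
deregulation direction (up/down/flat); edges carry the interaction
score, the number of supporting databases (``dat.sum``) and the adjusted
p-value.  The tested surface is the exported files: a SIF triple file
(``mirna<TAB>regulates<TAB>mrna``) plus node- and edge-attribute tables,
all with deterministic (sorted) line order.  Shape/colour conventions
(miRNA = square, up = red, down = green) are presentation hints left to
a Cytoscape style file; only kind and direction are stored.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .core_data import DataError
from .targets import top_interactions

RELATION = "regulates"


def _direction(logratio: float) -> str:
    if logratio > 0:
        return "up"
    if logratio < 0:
        return "down"
    return "flat"


@dataclass
class InteractionNetwork:
    nodes: pd.DataFrame  # id, kind, logratio, direction
    edges: pd.DataFrame  # miRNA, mRNA, score, dat.sum, adj.pval

    def __len__(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for _, r in self.nodes.iterrows():
            g.add_node(
                (r["id"], r["kind"]),
                kind=r["kind"], logratio=r["logratio"], direction=r["direction"],
            )
        for _, r in self.edges.iterrows():
            g.add_edge(
                (r["miRNA"], "miRNA"), (r["mRNA"], "mRNA"),
                score=r["score"], dat_sum=int(r["dat.sum"]), adj_pval=r["adj.pval"],
            )
        return g


def build_network(
    combined: pd.DataFrame,
    max_edges: int | None = None,
    sort_key: str = "adj.pval",
) -> InteractionNetwork:
    """Network of the top interactions (default ordering: adj.pval ascending).

    The edge selection uses the same deterministic ordering and tie-break
    as :func:`mirlink.targets.top_interactions`.
    """
    if max_edges is not None:
        if max_edges < 1:
            raise DataError("max_edges must be >= 1")
        sel = top_interactions(combined, max_edges, sort_key)
    else:
        sel = top_interactions(combined, max(len(combined), 1), sort_key) if len(combined) else combined
    edges = sel.loc[:, ["miRNA", "mRNA", "score", "dat.sum", "adj.pval"]].copy()
    edges = edges.drop_duplicates(subset=["miRNA", "mRNA"]).reset_index(drop=True)
    node_rows = []
    seen = set()
    for _, r in sel.iterrows():
        for id_col, kind, lr_col in (
            ("miRNA", "miRNA", "logratio.miRNA"),
            ("mRNA", "mRNA", "logratio.mRNA"),
        ):
            key = (r[id_col], kind)
            if key not in seen:
                seen.add(key)
                node_rows.append(
                    {
                        "id": r[id_col],
                        "kind": kind,
                        "logratio": float(r[lr_col]),
                        "direction": _direction(float(r[lr_col])),
                    }
                )
    nodes = pd.DataFrame(node_rows, columns=["id", "kind", "logratio", "direction"])
    if len(nodes):
        nodes = nodes.sort_values(["kind", "id"], kind="mergesort").reset_index(drop=True)
    return InteractionNetwork(nodes, edges)


def export_sif(net: InteractionNetwork, path_prefix: str | Path) -> list[Path]:
    """Write <prefix>.sif, <prefix>.node_attrs.tsv and <prefix>.edge_attrs.tsv.

    Line order is sorted, so re-export is byte-identical.
    """
    if len(net.edges) == 0:
        raise DataError("cannot export an empty network")
    prefix = Path(path_prefix)
    sif_path = prefix.with_name(prefix.name + ".sif")
    node_path = prefix.with_name(prefix.name + ".node_attrs.tsv")
    edge_path = prefix.with_name(prefix.name + ".edge_attrs.tsv")

    edges = net.edges.sort_values(["miRNA", "mRNA"], kind="mergesort")
    with open(sif_path, "w") as fh:
        for _, r in edges.iterrows():
            fh.write(f"{r['miRNA']}\t{RELATION}\t{r['mRNA']}\n")

    nodes = net.nodes.sort_values(["kind", "id"], kind="mergesort")
    with open(node_path, "w") as fh:
        fh.write("id\tkind\tlogratio\tdirection\n")
        for _, r in nodes.iterrows():
            fh.write(f"{r['id']}\t{r['kind']}\t{r['logratio']!r}\t{r['direction']}\n")

    with open(edge_path, "w") as fh:
        fh.write("edge\tscore\tdat.sum\tadj.pval\n")
        for _, r in edges.iterrows():
            key = f"{r['miRNA']} ({RELATION}) {r['mRNA']}"
            fh.write(f"{key}\t{r['score']!r}\t{int(r['dat.sum'])}\t{r['adj.pval']!r}\n")
    return [sif_path, node_path, edge_path]


def read_sif(path: str | Path) -> set:
    """Parse a SIF file back into a set of (source, relation, target) triples."""
    triples = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise DataError(f"malformed SIF line: {line!r}")
            triples.add(tuple(parts))
    return triples


def export_graphml(net: InteractionNetwork, path: str | Path) -> None:
    g = nx.DiGraph()
    for _, r in net.nodes.iterrows():
        g.add_node(f"{r['kind']}:{r['id']}", kind=r["kind"],
                   logratio=float(r["logratio"]), direction=r["direction"])
    for _, r in net.edges.iterrows():
        g.add_edge(f"miRNA:{r['miRNA']}", f"mRNA:{r['mRNA']}",
                   score=float(r["score"]), dat_sum=int(r["dat.sum"]),
                   adj_pval=float(r["adj.pval"]))
    nx.write_graphml(g, path)


def plot_network(net: InteractionNetwork, path: str | Path, seed: int = 0) -> None:
    """Best-effort static rendering (untested surface; files are the contract)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = net.to_networkx()
    pos = nx.spring_layout(g, seed=seed)
    colors = [
        {"up": "#d62728", "down": "#2ca02c", "flat": "#999999"}[d]
        for d in nx.get_node_attributes(g, "direction").values()
    ]
    fig, ax = plt.subplots(figsize=(8, 6))
    nx.draw_networkx(
        g, pos, ax=ax, node_color=colors, with_labels=True,
        labels={n: n[0] for n in g.nodes}, font_size=6, node_size=120,
        edge_color="#555555", arrows=True,
    )
    ax.set_axis_off()
    fig.savefig(path, dpi=120)
    plt.close(fig)
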