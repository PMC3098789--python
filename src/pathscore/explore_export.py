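"""Bi-dimensional clustering, heatmap export and per-sample network drawings.

The score matrix (rows = pathway x metric, columns = samples) is clustered
hierarchically on rows and columns independently; the heatmap is written as
an image plus a reordered plain-text matrix so the ordering is testable
without pixel comparison.  Per-sample network exports encode molecule
expression (white → turquoise fill), interaction activity (node size) and
interaction consistency (edge colour, dark green → bright blue), with altered
genes outlined in yellow; DOT and GraphML outputs carry the exact numeric
values as attributes so files are diffable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib
import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from .metrics import InteractionScores
from .pathway_model import PathwayNetwork

logger = logging.getLogger(__name__)

__all__ = ["ClusterResult", "bicluster", "export_heatmap", "export_network"]

# endpoint colours from the published drawing conventions
_FILL_LOW = np.array([1.0, 1.0, 1.0])         # white, lowest expression
_FILL_HIGH = np.array([0.25, 0.88, 0.82])     # bright turquoise, highest
_EDGE_LOW = np.array([0.0, 0.39, 0.0])        # dark green, low consistency
_EDGE_HIGH = np.array([0.0, 0.75, 1.0])       # bright blue, high consistency
_ALTERED_OUTLINE = "#ffd700"                   # yellow


@dataclass
class ClusterResult:
    row_order: list[int]
    col_order: list[int]
    row_tree: np.ndarray | None  # scipy linkage matrices (None when trivial)
    col_tree: np.ndarray | None
    row_labels: list[str]
    col_labels: list[str]


def _linkage_order(mat: np.ndarray, distance: str, linkage: str) -> tuple[list[int], np.ndarray | None]:
    n = mat.shape[0]
    if n < 2:
        return list(range(n)), None
    d = pdist(mat, metric=distance)
    d = np.nan_to_num(d, nan=1.0)  # correlation distance of flat rows
    tree = hierarchy.linkage(d, method=linkage)
    order = hierarchy.leaves_list(tree).tolist()
    return order, tree


def bicluster(
    matrix: pd.DataFrame,
    distance: str = "correlation",
    linkage: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of rows and columns independently.

    Rows containing missing values are dropped with a warning.  With fewer
    than two rows or columns the identity ordering is returned.  Given a
    fixed input order the result is deterministic.
    """
    if distance not in ("euclidean", "correlation"):
        raise ValueError(f"unsupported distance {distance!r}")
    if linkage not in ("average", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    clean = matrix.dropna(axis=0, how="any")
    if len(clean) < len(matrix):
        logger.warning("dropped %d rows with missing scores", len(matrix) - len(clean))
    vals = clean.to_numpy(dtype=float)
    row_order, row_tree = _linkage_order(vals, distance, linkage)
    col_order, col_tree = _linkage_order(vals.T, distance, linkage)
    return ClusterResult(
        row_order=row_order,
        col_order=col_order,
        row_tree=row_tree,
        col_tree=col_tree,
        row_labels=[str(i) for i in clean.index],
        col_labels=[str(c) for c in clean.columns],
    )


def export_heatmap(
    matrix: pd.DataFrame,
    cluster: ClusterResult,
    path: str | Path,
    annotations: Mapping[str, str] | None = None,
    cmap: str = "viridis",
) -> Path:
    """Write the clustered heatmap image plus a ``.ordered.tsv`` text twin.

    ``annotations`` maps sample ids to category labels shown as a colour bar
    under the heatmap; an annotation naming an unknown sample raises.
    Returns the path of the reordered-matrix text file.
    """
    path = Path(path)
    clean = matrix.loc[cluster.row_labels, cluster.col_labels]
    ordered = clean.iloc[cluster.row_order, cluster.col_order]
    if annotations is not None:
        unknown = sorted(set(annotations) - set(map(str, matrix.columns)))
        if unknown:
            raise KeyError(f"annotations name unknown samples: {unknown}")

    n_rows, n_cols = ordered.shape
    fig_h = max(3.0, 0.18 * n_rows + 1.5)
    fig_w = max(4.0, 0.18 * n_cols + 2.0)
    n_panels = 2 if annotations else 1
    fig, axes = plt.subplots(
        n_panels, 1, figsize=(fig_w, fig_h), squeeze=False,
        gridspec_kw={"height_ratios": [20, 1] if annotations else [1]},
    )
    ax = axes[0][0]
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap=cmap, vmin=0, vmax=1)
    ax.set_yticks(range(n_rows))
    ax.set_yticklabels(ordered.index, fontsize=5)
    ax.set_xticks(range(n_cols))
    ax.set_xticklabels(ordered.columns, fontsize=5, rotation=90)
    fig.colorbar(im, ax=ax, shrink=0.6)
    if annotations:
        cats = sorted(set(annotations.values()))
        cat_idx = {c: i for i, c in enumerate(cats)}
        bar = np.array(
            [[cat_idx.get(annotations.get(str(c), ""), -1) for c in ordered.columns]]
        )
        ax2 = axes[1][0]
        ax2.imshow(bar, aspect="auto", cmap="tab10", vmin=0, vmax=9)
        ax2.set_yticks([])
        ax2.set_xticks([])
        ax2.set_title(", ".join(f"{i}: {c}" for c, i in cat_idx.items()), fontsize=5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)

    text_path = path.with_suffix(".ordered.tsv")
    ordered.to_csv(text_path, sep="\t", lineterminator="\n", float_format="%.10g")
    return text_path


def top_variance(matrix: pd.DataFrame, k: int) -> pd.DataFrame:
    """Keep the k rows with the highest sample-wide variance."""
    variances = matrix.var(axis=1, ddof=1)
    keep = variances.sort_values(ascending=False, kind="stable").index[:k]
    return matrix.loc[[i for i in matrix.index if i in set(keep)]]


def _hex(rgb: np.ndarray) -> str:
    r, g, b = (int(round(255 * v)) for v in np.clip(rgb, 0, 1))
    return f"#{r:02x}{g:02x}{b:02x}"


def _fill_color(prob: float | None) -> str:
    if prob is None:
        return "#d3d3d3"  # unmeasured: light grey
    return _hex(_FILL_LOW + prob * (_FILL_HIGH - _FILL_LOW))


def _edge_color(consistency: float | None) -> str:
    if consistency is None:
        return "#808080"
    return _hex(_EDGE_LOW + consistency * (_EDGE_HIGH - _EDGE_LOW))


def build_network_graph(
    net: PathwayNetwork,
    interaction_scores: Sequence[InteractionScores],
    molecule_probs: Mapping[str, float | None],
    altered_genes: set[str] | None = None,
) -> nx.DiGraph:
    """Attribute-rich graph: one node per molecule and per interaction.

    Molecule fill scales linearly from white (p = 0) to turquoise (p = 1);
    interaction node size scales from 0.2 to 1.0 with activity; edges from an
    interaction to its outputs are coloured by consistency.  Molecules whose
    gene set intersects ``altered_genes`` get a yellow outline.
    """
    altered_genes = altered_genes or set()
    by_id = {s.interaction_id: s for s in interaction_scores}
    g = nx.DiGraph(pathway_id=net.pathway_id, name=net.name)
    for mid, mol in net.molecules.items():
        prob = molecule_probs.get(mid)
        altered = bool(set(mol.entrez_ids) & altered_genes)
        g.add_node(
            f"mol:{mid}",
            kind="molecule",
            label=mol.label or mid,
            probability=-1.0 if prob is None else float(prob),
            fillcolor=_fill_color(prob),
            altered=altered,
            outline=_ALTERED_OUTLINE if altered else "#000000",
            shape="box",
        )
    for ia in net.interactions:
        s = by_id.get(ia.interaction_id)
        act = None if s is None or np.isnan(s.activity) else float(s.activity)
        cons = None if s is None or s.consistency is None else float(s.consistency)
        node = f"int:{ia.interaction_id}"
        g.add_node(
            node,
            kind="interaction",
            label=ia.interaction_id,
            activity=-1.0 if act is None else act,
            consistency=-1.0 if cons is None else cons,
            width=0.2 if act is None else 0.2 + 0.8 * act,
            shape="circle",
        )
        for mid in ia.promoters:
            g.add_edge(f"mol:{mid}", node, role="promoter", color="#000000")
        for mid in ia.inhibitors:
            g.add_edge(f"mol:{mid}", node, role="inhibitor", color="#000000")
        for mid in ia.outputs:
            g.add_edge(
                node, f"mol:{mid}", role="output",
                consistency=-1.0 if cons is None else cons,
                color=_edge_color(cons),
            )
    return g


def _dot_quote(s: str) -> str:
    return '"' + str(s).replace('"', r"\"") + '"'


def _write_dot(g: nx.DiGraph, path: Path) -> None:
    """Minimal DOT writer (node and edge attributes, digraph)."""
    lines = [f"digraph {_dot_quote(g.graph.get('pathway_id', 'pathway'))} {{"]
    for node, attrs in g.nodes(data=True):
        parts = ", ".join(
            f"{k}={_dot_quote(v)}" for k, v in sorted(attrs.items())
        )
        lines.append(f"  {_dot_quote(node)} [{parts}];")
    for u, v, attrs in g.edges(data=True):
        parts = ", ".join(
            f"{k}={_dot_quote(val)}" for k, val in sorted(attrs.items())
        )
        lines.append(f"  {_dot_quote(u)} -> {_dot_quote(v)} [{parts}];")
    lines.append("}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def export_network(
    net: PathwayNetwork,
    interaction_scores: Sequence[InteractionScores],
    molecule_probs: Mapping[str, float | None],
    path: str | Path,
    fmt: str = "dot",
    altered_genes: set[str] | None = None,
) -> Path:
    """Write the annotated pathway graph for one sample as DOT or GraphML."""
    path = Path(path)
    g = build_network_graph(net, interaction_scores, molecule_probs, altered_genes)
    if fmt == "dot":
        _write_dot(g, path)
    elif fmt == "graphml":
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    return path
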