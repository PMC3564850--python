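"""Threshold-based subnetwork extraction and static network rendering.

The interactive viewer this replaces let the user click a point on the
degree or reoccurrence plot to redraw the network at that level; here the
same operation is :func:`threshold_network` plus a re-render.  Rendering
is deterministic: a seeded force-directed layout plus fixed style rules —
node size grows with degree, edge stroke with reoccurrence, and the three
edge classes keep the established colour semantics (undirected blue,
directed pink with a pink arrow, merged drawn as a blue line carrying a
pink arrow).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from .errors import DataError
from .integrate import (
    BACKWARD,
    DIRECTED,
    FORWARD,
    MERGED,
    IntegratedNetwork,
    UNDIRECTED,
)
from .report import cumulative_stats

logger = logging.getLogger(__name__)

_FORMATS = ("png", "tiff")

BLUE = "#2b6ca3"   # undirected lines
PINK = "#e05fa0"   # directed lines and all arrowheads


@dataclass(frozen=True)
class RenderStyle:
    """Visual encoding rules; sizes in points, widths in points."""

    node_size_base: float = 120.0
    node_size_per_degree: float = 60.0
    edge_width_base: float = 0.8
    edge_width_per_reoccurrence: float = 1.2
    undirected_color: str = BLUE
    directed_color: str = PINK
    merged_color: str = BLUE  # merged edge body is the undirected line
    arrow_color: str = PINK
    node_color: str = "#c8d8e8"
    label_nodes: bool = True

    def node_size(self, degree: int) -> float:
        return self.node_size_base + self.node_size_per_degree * degree

    def edge_width(self, reoccurrence: int) -> float:
        return (
            self.edge_width_base
            + self.edge_width_per_reoccurrence * reoccurrence
        )

    def edge_color(self, status: str) -> str:
        return {
            UNDIRECTED: self.undirected_color,
            DIRECTED: self.directed_color,
            MERGED: self.merged_color,
        }[status]


@dataclass(frozen=True)
class LayoutResult:
    """Node positions from one seeded layout run."""

    positions: tuple[tuple[str, tuple[float, float]], ...]
    seed: int

    @property
    def position_map(self) -> dict[str, tuple[float, float]]:
        return dict(self.positions)


def threshold_network(
    network: IntegratedNetwork,
    min_degree: int | None = None,
    min_reoccurrence: int | None = None,
) -> IntegratedNetwork:
    """Redraw-level extraction: keep strong edges between strong nodes.

    An edge survives when its reoccurrence reaches *min_reoccurrence*
    (when given) and both endpoints have degree >= *min_degree* in the
    ORIGINAL network (the degrees the user saw on the statistics plot).
    Nodes left without edges are dropped; degrees and node provenance are
    recomputed on the result.
    """
    for t in (min_degree, min_reoccurrence):
        if t is not None and t < 1:
            raise DataError("thresholds must be >= 1")
    deg = network.degree_map
    kept = []
    for e in network.edges:
        if min_reoccurrence is not None and e.reoccurrence < min_reoccurrence:
            continue
        if min_degree is not None and (
            deg[e.key[0]] < min_degree or deg[e.key[1]] < min_degree
        ):
            continue
        kept.append(e)
    from collections import defaultdict

    degrees: dict[str, int] = defaultdict(int)
    node_srcs: dict[str, set] = defaultdict(set)
    for e in kept:
        a, b = e.key
        degrees[a] += 1
        if b != a:
            degrees[b] += 1
        node_srcs[a].update(e.sources)
        node_srcs[b].update(e.sources)
    if not kept:
        logger.warning("thresholds removed every edge")
    return IntegratedNetwork(
        edges=tuple(kept),
        degrees=tuple(sorted(degrees.items())),
        node_sources=tuple(
            (n, tuple(sorted(s))) for n, s in sorted(node_srcs.items())
        ),
    )


def layout_network(network: IntegratedNetwork, seed: int = 0) -> LayoutResult:
    """Seeded force-directed (Fruchterman–Reingold) layout.

    Deterministic for a fixed (network, seed) pair; a single node sits at
    the canvas centre.
    """
    if not network.nodes:
        raise DataError("cannot lay out an empty network")
    if len(network.nodes) == 1:
        return LayoutResult(
            positions=((network.nodes[0], (0.0, 0.0)),), seed=seed
        )
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    g.add_edges_from(e.key for e in network.edges if not e.is_self_loop)
    pos = nx.spring_layout(g, seed=seed, iterations=60)
    items = tuple(
        (node, (float(xy[0]), float(xy[1])))
        for node, xy in sorted(pos.items())
    )
    for _, (x, y) in items:
        if not (np.isfinite(x) and np.isfinite(y)):
            raise DataError("layout produced non-finite coordinates")
    return LayoutResult(positions=items, seed=seed)


def _draw_arrow(ax, start, end, style, shrink):
    ax.annotate(
        "",
        xy=end,
        xytext=start,
        arrowprops=dict(
            arrowstyle="-|>",
            color=style.arrow_color,
            lw=1.2,
            shrinkA=shrink,
            shrinkB=shrink,
            mutation_scale=16,
        ),
        zorder=3,
    )


def render_network(
    network: IntegratedNetwork,
    layout: LayoutResult,
    style: RenderStyle | None = None,
    path="network.png",
    format: str | None = None,
) -> Path:
    """Render the network to a PNG or TIFF image file.

    Every observed orientation of a directed or merged edge gets an
    arrowhead, drawn over the edge body in the arrow colour.
    """
    style = style or RenderStyle()
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".") or "png").lower()
    if fmt == "tif":
        fmt = "tiff"
    if fmt not in _FORMATS:
        raise DataError(f"unsupported image format {fmt!r} (png or tiff)")
    if network.is_empty:
        raise DataError("refusing to render an empty network")
    pos = layout.position_map
    missing = [n for n in network.nodes if n not in pos]
    if missing:
        raise DataError(f"layout is missing nodes: {missing}")

    fig, ax = plt.subplots(figsize=(8, 8))
    ax.set_axis_off()
    for e in network.edges:
        (x0, y0), (x1, y1) = pos[e.key[0]], pos[e.key[1]]
        if e.is_self_loop:
            ax.plot(
                [x0], [y0],
                marker="o", mfc="none",
                mec=style.edge_color(e.direction_status),
                ms=24, mew=style.edge_width(e.reoccurrence), zorder=1,
            )
            continue
        ax.plot(
            [x0, x1], [y0, y1],
            color=style.edge_color(e.direction_status),
            lw=style.edge_width(e.reoccurrence),
            solid_capstyle="round", zorder=1,
        )
        if FORWARD in e.directions:
            _draw_arrow(ax, (x0, y0), (x1, y1), style, shrink=12)
        if BACKWARD in e.directions:
            _draw_arrow(ax, (x1, y1), (x0, y0), style, shrink=12)

    deg = network.degree_map
    xs = [pos[n][0] for n in network.nodes]
    ys = [pos[n][1] for n in network.nodes]
    sizes = [style.node_size(deg[n]) for n in network.nodes]
    ax.scatter(
        xs, ys, s=sizes, c=style.node_color, edgecolors="#33506b",
        linewidths=1.0, zorder=2,
    )
    if style.label_nodes:
        for n in network.nodes:
            ax.annotate(
                n, pos[n], textcoords="offset points", xytext=(0, 9),
                ha="center", fontsize=8, zorder=4,
            )
    ax.margins(0.15)
    fig.savefig(path, format=fmt, dpi=120)
    plt.close(fig)
    return path


def render_stats_chart(network: IntegratedNetwork, path) -> Path:
    """The two companion statistics plots as one static image.

    Top: number of nodes at or above each node degree.  Bottom: number
    of edges at or above each edge reoccurrence.  These are the levels a
    user would pick thresholds from.
    """
    if network.is_empty:
        raise DataError("refusing to chart an empty network")
    path = Path(path)
    node_stats = cumulative_stats([d for _, d in network.degrees])
    edge_stats = cumulative_stats([e.reoccurrence for e in network.edges])
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(6, 7))
    for ax, stats, xlab, ylab, color in (
        (ax1, node_stats, "node degree", "nodes (>= degree)", BLUE),
        (ax2, edge_stats, "edge reoccurrence", "edges (>= reoccurrence)",
         PINK),
    ):
        levels = [lv for lv, _ in stats.rows]
        counts = [c for _, c in stats.rows]
        ax.plot(levels, counts, "o-", color=color)
        ax.set_xlabel(xlab)
        ax.set_ylabel(ylab)
        ax.set_xticks(levels)
        ax.grid(True, alpha=0.3)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
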