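"""Cumulative network statistics and tab-delimited result reports.

A list run produces one table (element, reoccurrence, sources).  A
network run produces four: node statistics, edge statistics, nodes and
edges.  The statistics tables are cumulative: for every observed level v
they give the number of items whose degree (nodes) or reoccurrence
(edges) is >= v.  Reports carry their provenance — which files were
integrated and which filters applied — as '#'-prefixed header lines, so
the tables below stay machine-parseable; the edges table is a plain
five-column edge list importable into Cytoscape and the like.

Also here: the one-sided Fisher (hypergeometric tail) overrepresentation
test used to ask whether known genes of interest are enriched among the
prioritized candidates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from scipy.stats import hypergeom

from .errors import DataError
from .integrate import (
    IntegratedEdge,
    IntegratedElement,
    IntegratedNetwork,
    direction_status,
    rank_candidates,
)

_LIST_COLUMNS = ("element", "reoccurrence", "sources")
_NODE_COLUMNS = ("node", "reoccurrence", "sources")
_EDGE_COLUMNS = ("node_a", "node_b", "direction_status", "reoccurrence",
                 "sources")
SOURCE_SEP = ";"


@dataclass(frozen=True)
class StatsTable:
    """Cumulative 'count at-or-above level' rows, one per observed level."""

    rows: tuple[tuple[int, int], ...]

    def __post_init__(self):
        levels = [lv for lv, _ in self.rows]
        counts = [c for _, c in self.rows]
        if levels != sorted(set(levels)):
            raise DataError("stats levels must be strictly increasing")
        if any(c <= 0 for c in counts) or any(
            counts[i] < counts[i + 1] for i in range(len(counts) - 1)
        ):
            raise DataError("stats counts must be positive, non-increasing")

    @property
    def total(self) -> int:
        return self.rows[0][1] if self.rows else 0


def cumulative_stats(values: Iterable[int]) -> StatsTable:
    """For each distinct observed value v, count items with value >= v."""
    vals = sorted(values)
    if not vals:
        raise DataError("cumulative_stats needs at least one value")
    n = len(vals)
    rows = []
    for level in sorted(set(vals)):
        # vals is sorted ascending: items >= level form a suffix
        at_or_above = n - _first_index_at_least(vals, level)
        rows.append((level, at_or_above))
    return StatsTable(rows=tuple(rows))


def _first_index_at_least(sorted_vals, level):
    import bisect

    return bisect.bisect_left(sorted_vals, level)


@dataclass(frozen=True)
class RunReport:
    """Provenance header of one integration run."""

    kind: str  # "list" | "network"
    mode: str  # "defined" | "undefined"
    sources: tuple[str, ...]
    applied_filters: tuple[tuple[str, tuple[str, ...]], ...] = ()

    def header_lines(self) -> list[str]:
        lines = [
            f"# run_kind: {self.kind}",
            f"# mode: {self.mode}",
            f"# integrated_files: {SOURCE_SEP.join(self.sources)}",
        ]
        for source, descs in self.applied_filters:
            if descs:
                lines.append(f"# filter: {source}: " + " AND ".join(descs))
            else:
                lines.append(f"# filter: {source}: (none)")
        return lines


def _render_sources(sources: Sequence[str]) -> str:
    return SOURCE_SEP.join(sorted(sources))


def write_list_report(
    elements: Sequence[IntegratedElement], report: RunReport, path
) -> None:
    """Write the ranked three-column list result with provenance header."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        for line in report.header_lines():
            fh.write(line + "\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_LIST_COLUMNS)
        for el in elements:
            writer.writerow(
                [el.element, el.reoccurrence, _render_sources(el.sources)]
            )


def read_list_report(path) -> list[IntegratedElement]:
    """Parse a written list report back into its ranked elements."""
    rows = _read_tables(path)["__single__"]
    out = []
    for row in rows:
        el, reocc, srcs = row
        out.append(
            IntegratedElement(
                element=el,
                reoccurrence=int(reocc),
                sources=tuple(sorted(s for s in srcs.split(SOURCE_SEP) if s)),
            )
        )
    return out


def write_network_report(
    network: IntegratedNetwork, report: RunReport, path
) -> None:
    """Write the four network result tables (stats, nodes, edges).

    Table order: node statistics, edge statistics, nodes, edges — each
    introduced by a '# table:' marker line and separated by one blank
    line.  Nodes and edges are in reoccurrence-rank order.
    """
    path = Path(path)
    if network.is_empty:
        node_stats = edge_stats = StatsTable(rows=())
    else:
        node_stats = cumulative_stats(
            [d for _, d in network.degrees]
        )
        edge_stats = cumulative_stats(
            [e.reoccurrence for e in network.edges]
        )
    node_items = [
        IntegratedElement(
            element=n,
            reoccurrence=len(network.node_source_map[n]),
            sources=network.node_source_map[n],
        )
        for n in network.nodes
    ]
    with path.open("w", encoding="utf-8", newline="") as fh:
        for line in report.header_lines():
            fh.write(line + "\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")

        fh.write("# table: node_statistics\n")
        writer.writerow(("degree", "nodes_at_or_above"))
        for level, count in node_stats.rows:
            writer.writerow((level, count))
        fh.write("\n# table: edge_statistics\n")
        writer.writerow(("reoccurrence", "edges_at_or_above"))
        for level, count in edge_stats.rows:
            writer.writerow((level, count))
        fh.write("\n# table: nodes\n")
        writer.writerow(_NODE_COLUMNS)
        for it in rank_candidates(node_items):
            writer.writerow(
                (it.element, it.reoccurrence, _render_sources(it.sources))
            )
        fh.write("\n# table: edges\n")
        writer.writerow(_EDGE_COLUMNS)
        for e in rank_candidates(network.edges):
            writer.writerow(
                (
                    e.key[0],
                    e.key[1],
                    e.direction_status,
                    e.reoccurrence,
                    _render_sources(e.sources),
                )
            )


def read_network_report(path) -> IntegratedNetwork:
    """Reconstruct an IntegratedNetwork from a written network report.

    Edge provenance, reoccurrence and direction status round-trip
    exactly; per-orientation detail inside a directed/merged edge is
    collapsed to a representative orientation.  Degrees are recomputed
    from the edge set.
    """
    from .integrate import BACKWARD, FORWARD, NONE, canonical_edge_key

    tables = _read_tables(path)
    if "edges" not in tables or "nodes" not in tables:
        raise DataError(f"{path}: not a network report (missing tables)")
    edges = []
    for row in tables["edges"]:
        if len(row) != len(_EDGE_COLUMNS):
            raise DataError(f"{path}: malformed edges row {row!r}")
        a, b, status, reocc, srcs = row
        key = canonical_edge_key(a, b)
        if status == "undirected":
            dirs = frozenset({NONE})
        elif status == "directed":
            dirs = frozenset({FORWARD})
        elif status == "merged":
            dirs = frozenset({NONE, FORWARD})
        else:
            raise DataError(f"{path}: unknown direction status {status!r}")
        edges.append(
            IntegratedEdge(
                key=key,
                reoccurrence=int(reocc),
                sources=tuple(sorted(s for s in srcs.split(SOURCE_SEP) if s)),
                direction_status=status,
                directions=dirs,
            )
        )
    node_sources = {}
    for row in tables["nodes"]:
        node, _reocc, srcs = row
        node_sources[node] = tuple(
            sorted(s for s in srcs.split(SOURCE_SEP) if s)
        )
    from collections import defaultdict

    degrees: dict[str, int] = defaultdict(int)
    for e in edges:
        degrees[e.key[0]] += 1
        if e.key[1] != e.key[0]:
            degrees[e.key[1]] += 1
    for node in node_sources:
        degrees.setdefault(node, 0)
    return IntegratedNetwork(
        edges=tuple(sorted(edges, key=lambda e: e.key)),
        degrees=tuple(sorted(degrees.items())),
        node_sources=tuple(sorted(node_sources.items())),
    )


def _read_tables(path) -> dict[str, list[list[str]]]:
    """Split a report file into its tables, skipping provenance lines.

    Files without '# table:' markers (list reports) yield one table under
    the key '__single__'.  The first non-comment line of each table is
    its column header and is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"report not found: {path}")
    tables: dict[str, list[list[str]]] = {}
    current: list[list[str]] | None = None
    expect_header = False
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# table:"):
                name = line.split(":", 1)[1].strip()
                tables[name] = []
                current = tables[name]
                expect_header = True
                continue
            if line.startswith("#"):
                continue
            if line == "":
                continue
            if current is None:
                tables["__single__"] = []
                current = tables["__single__"]
                expect_header = True
            if expect_header:
                expect_header = False  # drop the column-name row
                continue
            current.append(line.split("\t"))
    return tables


def enrichment_test(
    hits_selected: int, selected: int, hits_total: int, universe: int
) -> float:
    """One-sided overrepresentation p-value: P(X >= hits_selected).

    X follows the hypergeometric distribution of drawing ``selected``
    items without replacement from a ``universe`` containing
    ``hits_total`` hits.  Typical use: are known disease genes
    overrepresented among the prioritized candidates relative to the
    full candidate pool?
    """
    ok = (
        0 <= hits_selected <= min(selected, hits_total)
        and 0 <= selected <= universe
        and 0 <= hits_total <= universe
        and hits_selected >= selected + hits_total - universe
    )
    if not ok:
        raise DataError(
            f"inconsistent counts: {hits_selected} hits in {selected} "
            f"selected, {hits_total} hits in universe {universe}"
        )
    return float(hypergeom.sf(hits_selected - 1, universe, hits_total,
                              selected))
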