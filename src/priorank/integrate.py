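"""Qualitative integration of filtered sources and reoccurrence ranking.

Each list or network file is one *source*.  In **defined** mode every
source is first reduced by its own FilterSet; **undefined** mode ignores
all attributes and filters.  The surviving (source, element) or
(source, edge) observations are then merged: an element's or edge's
*reoccurrence* is the number of distinct sources that contain it after
filtering, and the set of supporting source names is kept as provenance.
Duplicate rows inside one source collapse — reoccurrence is a
per-dataset notion, not a row count.

Edges are identified by the unordered node pair, so A→B and B→A from
different sources land on one edge record; the orientations actually
observed are retained, and an edge supported by both undirected and
directed observations is flagged ``merged``.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .criteria import FilterSet, apply_filter_set
from .errors import DataError
from .io import LIST, NETWORK, SourceTable

DEFINED = "defined"
UNDEFINED = "undefined"

DIRECTED = "directed"
UNDIRECTED = "undirected"
MERGED = "merged"

# Orientation tokens, relative to the canonical (a, b) edge key.
FORWARD = "a->b"
BACKWARD = "b->a"
NONE = "none"


@dataclass(frozen=True)
class IntegratedElement:
    """A list element with its reoccurrence and supporting sources."""

    element: str
    reoccurrence: int
    sources: tuple[str, ...]  # sorted

    @property
    def label(self) -> str:
        return self.element


def canonical_edge_key(a: str, b: str) -> tuple[str, str]:
    """Unordered pair as a lexicographically sorted tuple.

    Symmetric — key(a, b) == key(b, a) — and case-sensitive, so ``nrl``
    and ``Nrl`` remain distinct nodes.  A self-loop keys as (a, a).
    """
    if not a or not b:
        raise DataError("edge endpoints must be non-blank")
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class IntegratedEdge:
    """An integrated edge: unordered pair, provenance and direction status."""

    key: tuple[str, str]
    reoccurrence: int
    sources: tuple[str, ...]  # sorted
    direction_status: str  # UNDIRECTED | DIRECTED | MERGED
    directions: frozenset[str]  # subset of {FORWARD, BACKWARD, NONE}

    @property
    def label(self) -> str:
        return f"{self.key[0]}|{self.key[1]}"

    @property
    def is_self_loop(self) -> bool:
        return self.key[0] == self.key[1]


@dataclass(frozen=True)
class IntegratedNetwork:
    """Integrated edges plus node degrees and node-level provenance.

    A node's degree is the number of distinct integrated edges incident to
    it (a self-loop contributes one); its reoccurrence is the number of
    distinct sources in which it appears in any surviving edge.
    """

    edges: tuple[IntegratedEdge, ...]
    degrees: tuple[tuple[str, int], ...]
    node_sources: tuple[tuple[str, tuple[str, ...]], ...]

    @property
    def edge_map(self) -> dict[tuple[str, str], IntegratedEdge]:
        return {e.key: e for e in self.edges}

    @property
    def degree_map(self) -> dict[str, int]:
        return dict(self.degrees)

    @property
    def node_source_map(self) -> dict[str, tuple[str, ...]]:
        return dict(self.node_sources)

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.degrees)

    @property
    def is_empty(self) -> bool:
        return not self.edges


def direction_status(directions: Iterable[str]) -> str:
    """Classify an edge from its observed orientations.

    merged iff both an undirected and a directed observation exist;
    directed iff only directed; undirected iff only undirected.
    """
    dirs = set(directions)
    has_undirected = NONE in dirs
    has_directed = bool(dirs - {NONE})
    if has_undirected and has_directed:
        return MERGED
    if has_directed:
        return DIRECTED
    return UNDIRECTED


def _filtered(
    tables: Sequence[SourceTable],
    filters: Mapping[str, FilterSet] | None,
    mode: str,
    kind: str,
) -> list[SourceTable]:
    if mode not in (DEFINED, UNDEFINED):
        raise DataError(f"unknown run mode {mode!r}")
    if not tables:
        raise DataError("no sources to integrate")
    names = [t.name for t in tables]
    if len(set(names)) != len(names):
        raise DataError(f"duplicate source names: {names}")
    wrong = [t.name for t in tables if t.kind != kind]
    if wrong:
        raise DataError(
            f"cannot mix list and network sources in one run "
            f"(expected {kind}: {wrong})"
        )
    if mode == UNDEFINED or not filters:
        return list(tables)
    out = []
    for t in tables:
        fs = filters.get(t.name)
        out.append(apply_filter_set(t, fs) if fs is not None else t)
    return out


def integrate_lists(
    tables: Sequence[SourceTable],
    filters: Mapping[str, FilterSet] | None = None,
    mode: str = UNDEFINED,
) -> list[IntegratedElement]:
    """Merge list sources into elements with reoccurrence and provenance.

    Returns one IntegratedElement per distinct identifier surviving in at
    least one source, in lexicographic order (use :func:`rank_candidates`
    for the reoccurrence ranking).
    """
    support: dict[str, set[str]] = defaultdict(set)
    for table in _filtered(tables, filters, mode, LIST):
        for rec in table.records:
            support[rec.keys[0]].add(table.name)
    return [
        IntegratedElement(
            element=el,
            reoccurrence=len(srcs),
            sources=tuple(sorted(srcs)),
        )
        for el, srcs in sorted(support.items())
    ]


def integrate_networks(
    tables: Sequence[SourceTable],
    filters: Mapping[str, FilterSet] | None = None,
    mode: str = UNDEFINED,
    directedness: Mapping[str, str] | None = None,
) -> IntegratedNetwork:
    """Merge network sources into an IntegratedNetwork.

    *directedness* declares, per source name, whether that file's edges
    are ``directed`` (row order is tail→head) or ``undirected``; the
    node-pair format itself carries no direction marker.  Undeclared
    sources default to undirected.
    """
    directedness = dict(directedness or {})
    for name, d in directedness.items():
        if d not in (DIRECTED, UNDIRECTED):
            raise DataError(f"source {name!r}: directedness must be "
                            f"'directed' or 'undirected', got {d!r}")

    edge_sources: dict[tuple[str, str], set[str]] = defaultdict(set)
    edge_dirs: dict[tuple[str, str], set[str]] = defaultdict(set)
    node_srcs: dict[str, set[str]] = defaultdict(set)

    for table in _filtered(tables, filters, mode, NETWORK):
        directed = directedness.get(table.name, UNDIRECTED) == DIRECTED
        for rec in table.records:
            a, b = rec.keys
            key = canonical_edge_key(a, b)
            edge_sources[key].add(table.name)
            if not directed:
                orient = NONE
            else:
                orient = FORWARD if (a, b) == key else BACKWARD
            edge_dirs[key].add(orient)
            node_srcs[a].add(table.name)
            node_srcs[b].add(table.name)

    edges = tuple(
        IntegratedEdge(
            key=key,
            reoccurrence=len(srcs),
            sources=tuple(sorted(srcs)),
            direction_status=direction_status(edge_dirs[key]),
            directions=frozenset(edge_dirs[key]),
        )
        for key, srcs in sorted(edge_sources.items())
    )
    degrees: dict[str, int] = defaultdict(int)
    for e in edges:
        a, b = e.key
        degrees[a] += 1
        if b != a:
            degrees[b] += 1
    return IntegratedNetwork(
        edges=edges,
        degrees=tuple(sorted(degrees.items())),
        node_sources=tuple(
            (n, tuple(sorted(s))) for n, s in sorted(node_srcs.items())
        ),
    )


def rank_candidates(items):
    """Rank by descending reoccurrence, ties by ascending label.

    Works for IntegratedElement, IntegratedEdge, or anything exposing
    ``reoccurrence`` and ``label``.  Deterministic.
    """
    return sorted(items, key=lambda it: (-it.reoccurrence, it.label))
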