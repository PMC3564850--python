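"""Synthetic list and network sources with planted, known-answer structure.

Every generator returns both the source tables and exact per-source
ground truth, so the full pipeline — read, filter, integrate, rank,
report, render — is testable without any external download.  Attribute
values are drawn from the passing or failing region of each source's
filter by construction, never left to chance, so the ground-truth pass
sets are exact rather than probabilistic.

The case-study-shaped generator emulates the structure of a retinal
development candidate screen: six co-expression lists carrying a
correlation coefficient filtered at |r| > 0.9, and two
differentially-expressed-gene lists carrying a developmental-age tag
filtered to the P6/P10 time points.  Planted genes pass all eight
filters; every background gene fails at least one, so the planted genes
are exactly the reoccurrence-8 tier.  Only the structure (attributes,
criteria, cardinalities) is emulated — the identifiers are synthetic,
not real genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .criteria import Criterion, FilterSet, parse_criterion
from .errors import DataError
from .io import (
    LABEL,
    LIST,
    NETWORK,
    VALUE,
    AttributeSchema,
    Record,
    SourceTable,
    write_source_table,
)

AGES = ("E16", "P2", "P6", "P10", "4wk")
PASSING_AGES = ("P6", "P10")

_CASE_N_COEXPR = 6
_CASE_N_DEG = 2
# Case-study-scale defaults: five planted candidates among 272 genes.
CASE_N_PLANTED = 5
CASE_UNIVERSE = 272
# Chance that a background gene clears any single source's filter.
BACKGROUND_PASS_PROB = 0.25


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a planted-structure fixture."""

    n_sources: int = 3
    universe: tuple[str, ...] = ()
    planted: tuple[str, ...] = ()
    background_pass_prob: float = BACKGROUND_PASS_PROB
    seed: int = 0

    def __post_init__(self):
        if not self.universe:
            raise DataError("fixture universe must be non-empty")
        if not set(self.planted) <= set(self.universe):
            raise DataError("planted identifiers must lie in the universe")
        if not 0.0 <= self.background_pass_prob <= 1.0:
            raise DataError("background pass probability must be in [0, 1]")
        if self.n_sources < 1:
            raise DataError("need at least one source")


def default_universe(size: int, prefix: str = "g") -> tuple[str, ...]:
    width = len(str(size))
    return tuple(f"{prefix}{i:0{width}d}" for i in range(1, size + 1))


def _score_record(gene: str, rng, passing: bool) -> Record:
    # Filter is "score > 0.9"; keep a small margin off the boundary.
    if passing:
        x = rng.uniform(0.905, 1.0)
    else:
        x = rng.uniform(-1.0, 0.895)
    return Record(keys=(gene,), attributes=(("score", f"{x:.6f}"),))


def generate_list_sources(
    spec: FixtureSpec,
) -> tuple[list[SourceTable], dict[str, FilterSet], dict[str, set[str]]]:
    """Generic planted list fixture: one numeric score per source.

    Every source contains the whole universe; planted elements score
    inside the passing region of the shared filter (score > 0.9), each
    background element passes with ``background_pass_prob`` per source.
    Returns (tables, per-source FilterSets, per-source ground-truth pass
    sets).
    """
    rng = np.random.default_rng(spec.seed)
    schema = (AttributeSchema("score", VALUE),)
    planted = set(spec.planted)
    tables, filters, truth = [], {}, {}
    for i in range(1, spec.n_sources + 1):
        name = f"S{i}"
        records, passing = [], set()
        for gene in spec.universe:
            ok = gene in planted or bool(
                rng.random() < spec.background_pass_prob
            )
            records.append(_score_record(gene, rng, ok))
            if ok:
                passing.add(gene)
        tables.append(
            SourceTable(
                name=name, kind=LIST, key_columns=("gene",),
                attributes=schema, records=tuple(records),
            )
        )
        filters[name] = FilterSet.build(
            name, groups={"score": [parse_criterion("score > 0.9", schema)]}
        )
        truth[name] = passing
    return tables, filters, truth


def _corr_record(gene: str, rng, passing: bool) -> Record:
    if passing:
        r = rng.uniform(0.9005, 1.0) * rng.choice((-1.0, 1.0))
    else:
        r = rng.uniform(-0.8995, 0.8995)
    return Record(keys=(gene,), attributes=(("corr", f"{r:.6f}"),))


def _age_record(gene: str, rng, passing: bool) -> Record:
    pool = PASSING_AGES if passing else tuple(
        a for a in AGES if a not in PASSING_AGES
    )
    return Record(keys=(gene,), attributes=(("age", str(rng.choice(pool))),))


def generate_case_study_fixture(
    seed: int = 0,
    n_planted: int = CASE_N_PLANTED,
    universe_size: int = CASE_UNIVERSE,
    background_pass_prob: float = BACKGROUND_PASS_PROB,
) -> tuple[list[SourceTable], dict[str, FilterSet], dict]:
    """Eight-list fixture shaped like the retinal candidate screen.

    Six correlation lists (value attribute ``corr``, filter
    ``corr > 0.9 OR corr < -0.9``) and two developmental-age lists
    (label attribute ``age``, filter ``age == P6 | P10``).  The
    ``n_planted`` planted genes pass all eight filters; a background
    gene clears each filter with ``background_pass_prob`` but is
    resampled to fail one source if it would otherwise clear all eight.
    Returns (tables, filters, ground_truth) where ground_truth maps
    'planted' to the planted identifiers and 'pass_sets' to the exact
    per-source pass sets.
    """
    if n_planted > universe_size:
        raise DataError("more planted genes than the universe holds")
    if universe_size < 1:
        raise DataError("universe must be non-empty")
    rng = np.random.default_rng(seed)
    universe = default_universe(universe_size)
    planted = tuple(
        sorted(str(g) for g in rng.choice(universe, size=n_planted,
                                          replace=False))
    ) if n_planted else ()
    planted_set = set(planted)

    names = [f"coexpr_{i}" for i in range(1, _CASE_N_COEXPR + 1)] + [
        f"deg_{i}" for i in range(1, _CASE_N_DEG + 1)
    ]
    # Decide pass/fail per (gene, source); background genes that would
    # pass everywhere are forced to fail one randomly chosen source.
    passes = {}
    for gene in universe:
        if gene in planted_set:
            row = [True] * len(names)
        else:
            row = [
                bool(rng.random() < background_pass_prob) for _ in names
            ]
            if all(row):
                row[int(rng.integers(len(names)))] = False
        passes[gene] = row

    corr_schema = (AttributeSchema("corr", VALUE),)
    age_schema = (AttributeSchema("age", LABEL),)
    tables, filters, pass_sets = [], {}, {}
    for j, name in enumerate(names):
        is_corr = name.startswith("coexpr")
        records = []
        for gene in universe:
            ok = passes[gene][j]
            records.append(
                _corr_record(gene, rng, ok)
                if is_corr
                else _age_record(gene, rng, ok)
            )
        tables.append(
            SourceTable(
                name=name, kind=LIST, key_columns=("gene",),
                attributes=corr_schema if is_corr else age_schema,
                records=tuple(records),
            )
        )
        if is_corr:
            filters[name] = FilterSet.build(
                name,
                groups={
                    "corr": [
                        parse_criterion("corr > 0.9", corr_schema),
                        parse_criterion("corr < -0.9", corr_schema),
                    ]
                },
                logic={"corr": "any"},
            )
        else:
            filters[name] = FilterSet.build(
                name,
                groups={
                    "age": [
                        parse_criterion(
                            "age == " + " | ".join(PASSING_AGES), age_schema
                        )
                    ]
                },
            )
        pass_sets[name] = {g for g in universe if passes[g][j]}
    ground_truth = {"planted": planted, "pass_sets": pass_sets}
    return tables, filters, ground_truth


def generate_network_sources(
    spec: FixtureSpec,
    directedness: Sequence[str] | None = None,
    n_planted_edges: int = 4,
    n_background_edges: int = 6,
) -> tuple[list[SourceTable], dict[str, str], dict]:
    """Edge-list sources sharing planted edges plus source-unique noise.

    Planted edges appear in every source (ground-truth reoccurrence =
    n_sources; merged status whenever the directedness plan mixes
    directed and undirected sources).  Background edges are unique to
    one source each.  Returns (tables, directedness map, ground truth).
    """
    from .integrate import DIRECTED, UNDIRECTED, canonical_edge_key

    rng = np.random.default_rng(spec.seed)
    nodes = list(spec.universe)
    if len(nodes) < 2:
        raise DataError("network fixture needs at least two nodes")
    if directedness is None:
        directedness = [
            DIRECTED if i % 2 else UNDIRECTED for i in range(spec.n_sources)
        ]
    if len(directedness) != spec.n_sources:
        raise DataError("directedness plan must cover every source")

    def sample_edge(used: set) -> tuple[str, str]:
        while True:
            a, b = rng.choice(nodes, size=2, replace=False)
            key = canonical_edge_key(str(a), str(b))
            if key not in used:
                used.add(key)
                return key

    used: set = set()
    planted = [sample_edge(used) for _ in range(n_planted_edges)]
    tables, dir_map = [], {}
    background: dict[str, list] = {}
    for i in range(spec.n_sources):
        name = f"N{i + 1}"
        dir_map[name] = directedness[i]
        own = [sample_edge(used) for _ in range(n_background_edges)]
        background[name] = own
        rows = []
        for a, b in planted + own:
            if dir_map[name] == DIRECTED and rng.random() < 0.5:
                a, b = b, a  # orientation is free; identity is unordered
            rows.append(Record(keys=(a, b)))
        tables.append(
            SourceTable(
                name=name, kind=NETWORK, key_columns=("node_a", "node_b"),
                attributes=(), records=tuple(rows),
            )
        )
    ground_truth = {"planted_edges": planted, "background_edges": background}
    return tables, dir_map, ground_truth


def write_fixture_run(
    out_dir,
    tables: Sequence[SourceTable],
    filters: Mapping[str, FilterSet],
    mode: str = "defined",
    directedness: Mapping[str, str] | None = None,
    seed: int = 0,
) -> Path:
    """Write fixture tables as TSV plus a ready-to-run YAML config.

    Returns the config path; `priorank integrate --config <path>` runs
    the written fixture end to end.
    """
    import yaml

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    kind = tables[0].kind
    sources = []
    for t in tables:
        fname = f"{t.name}.tsv"
        write_source_table(t, out_dir / fname)
        entry: dict = {
            "path": fname,
            "name": t.name,
            "attributes": {a.name: a.kind for a in t.attributes},
        }
        if directedness and t.name in directedness:
            entry["directed"] = directedness[t.name] == "directed"
        fs = filters.get(t.name)
        if fs is not None and not fs.is_empty:
            fdict = {}
            for attr, crits in fs.groups:
                fdict[attr] = {
                    "logic": fs.logic_of(attr),
                    "criteria": [c.describe() for c in crits],
                }
            entry["filters"] = fdict
        sources.append(entry)
    config = {
        "kind": kind,
        "mode": mode,
        "out": "report.tsv",
        "sources": sources,
        "render": {"seed": seed, "format": "png"},
    }
    config_path = out_dir / "run.yaml"
    with config_path.open("w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return config_path
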