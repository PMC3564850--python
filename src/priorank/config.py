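"""The declarative run configuration.

One YAML file describes one integration run: the run kind (list or
network), the mode (defined = apply per-source filters, undefined =
ignore them), every source with its declared attribute kinds,
directedness and filter expressions, the output path, and rendering
options.  Attribute kinds are declared, not inferred, whenever filters
reference them, so a run's meaning never drifts with its data.

Validation is aggregate: every problem in the file is reported in one
ConfigError, with the source it belongs to named.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .criteria import FilterSet, parse_criterion
from .errors import ConfigError
from .io import LABEL, LIST, NETWORK, VALUE, AttributeSchema, TableDecl
from .integrate import DEFINED, DIRECTED, UNDEFINED, UNDIRECTED

_TOP_KEYS = {"kind", "mode", "sources", "out", "render"}
_SOURCE_KEYS = {"path", "name", "attributes", "directed", "filters"}
_RENDER_KEYS = {"min_degree", "min_reoccurrence", "seed", "format"}


@dataclass(frozen=True)
class SourceConfig:
    path: Path
    name: str
    kind: str = LIST
    attribute_kinds: tuple[tuple[str, str], ...] = ()
    directed: bool = False
    filters: FilterSet | None = None

    @property
    def decl(self) -> TableDecl:
        return TableDecl(
            name=self.name,
            kind=self.kind,
            attribute_kinds=dict(self.attribute_kinds),
        )

    @property
    def schema(self) -> tuple[AttributeSchema, ...]:
        return tuple(
            AttributeSchema(n, k) for n, k in self.attribute_kinds
        )


@dataclass(frozen=True)
class RenderConfig:
    min_degree: int | None = None
    min_reoccurrence: int | None = None
    seed: int = 0
    format: str = "png"


@dataclass(frozen=True)
class RunConfig:
    kind: str  # list | network
    mode: str  # defined | undefined
    sources: tuple[SourceConfig, ...]
    out: Path
    render: RenderConfig = RenderConfig()
    base_dir: Path = Path(".")

    @property
    def filter_map(self) -> dict[str, FilterSet]:
        return {
            s.name: s.filters for s in self.sources if s.filters is not None
        }

    @property
    def directedness(self) -> dict[str, str]:
        return {
            s.name: DIRECTED if s.directed else UNDIRECTED
            for s in self.sources
        }


def _parse_source(raw, base_dir: Path, kind: str, problems: list[str],
                  index: int) -> SourceConfig | None:
    label = f"sources[{index}]"
    if not isinstance(raw, Mapping):
        problems.append(f"{label}: must be a mapping")
        return None
    unknown = set(raw) - _SOURCE_KEYS
    if unknown:
        problems.append(f"{label}: unknown keys {sorted(unknown)}")
    if "path" not in raw:
        problems.append(f"{label}: missing 'path'")
        return None
    path = base_dir / str(raw["path"])
    name = str(raw.get("name") or path.stem)
    label = f"source {name!r}"
    if not path.exists():
        problems.append(f"{label}: file not found: {path}")
    kinds = []
    for attr, k in (raw.get("attributes") or {}).items():
        if k not in (VALUE, LABEL):
            problems.append(
                f"{label}: attribute {attr!r} kind must be 'value' or "
                f"'label', got {k!r}"
            )
        else:
            kinds.append((str(attr), str(k)))
    schema = tuple(AttributeSchema(n, k) for n, k in kinds)
    declared = {n for n, _ in kinds}

    filters = None
    raw_filters = raw.get("filters") or {}
    if not isinstance(raw_filters, Mapping):
        problems.append(f"{label}: 'filters' must map attribute -> group")
        raw_filters = {}
    groups, logic = {}, {}
    for attr, group in raw_filters.items():
        attr = str(attr)
        if attr not in declared:
            problems.append(
                f"{label}: filter on undeclared attribute {attr!r}"
            )
            continue
        if isinstance(group, Mapping):
            g_logic = str(group.get("logic", "all"))
            exprs = group.get("criteria") or []
        else:  # plain list shorthand, AND logic
            g_logic = "all"
            exprs = group
        if g_logic not in ("all", "any"):
            problems.append(
                f"{label}: filter group {attr!r}: logic must be "
                f"'all' or 'any', got {g_logic!r}"
            )
            continue
        if not isinstance(exprs, (list, tuple)) or not exprs:
            problems.append(
                f"{label}: filter group {attr!r} needs a non-empty "
                "criteria list"
            )
            continue
        crits = []
        for expr in exprs:
            try:
                c = parse_criterion(str(expr), schema)
            except ConfigError as exc:
                problems.append(f"{label}: {exc}")
                continue
            if c.attribute != attr:
                problems.append(
                    f"{label}: criterion {expr!r} targets "
                    f"{c.attribute!r}, placed under {attr!r}"
                )
                continue
            crits.append(c)
        if crits:
            groups[attr] = crits
            logic[attr] = g_logic
    if groups:
        filters = FilterSet.build(name, groups=groups, logic=logic)

    directed = bool(raw.get("directed", False))
    if directed and kind == LIST:
        problems.append(f"{label}: 'directed' applies to network runs only")
    return SourceConfig(
        path=path, name=name, kind=kind, attribute_kinds=tuple(kinds),
        directed=directed, filters=filters,
    )


def load_config(path) -> RunConfig:
    """Load and fully validate one run configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with path.open(encoding="utf-8") as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: invalid YAML: {exc}")
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: config must be a mapping")

    problems: list[str] = []
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        problems.append(f"unknown top-level keys {sorted(unknown)}")
    kind = str(raw.get("kind", LIST))
    if kind not in (LIST, NETWORK):
        problems.append(f"kind must be 'list' or 'network', got {kind!r}")
        kind = LIST
    mode = str(raw.get("mode", DEFINED))
    if mode not in (DEFINED, UNDEFINED):
        problems.append(
            f"mode must be 'defined' or 'undefined', got {mode!r}"
        )
        mode = DEFINED

    base_dir = path.parent
    raw_sources = raw.get("sources")
    sources: list[SourceConfig] = []
    if not isinstance(raw_sources, list) or not raw_sources:
        problems.append("config needs a non-empty 'sources' list")
    else:
        for i, rs in enumerate(raw_sources):
            sc = _parse_source(rs, base_dir, kind, problems, i)
            if sc is not None:
                sources.append(sc)
        names = [s.name for s in sources]
        dupes = sorted({n for n in names if names.count(n) > 1})
        if dupes:
            problems.append(f"duplicate source names: {dupes}")

    raw_render = raw.get("render") or {}
    render = RenderConfig()
    if not isinstance(raw_render, Mapping):
        problems.append("'render' must be a mapping")
    else:
        unknown = set(raw_render) - _RENDER_KEYS
        if unknown:
            problems.append(f"render: unknown keys {sorted(unknown)}")
        fmt = str(raw_render.get("format", "png")).lower()
        if fmt not in ("png", "tiff"):
            problems.append(f"render: format must be png or tiff, got {fmt!r}")
            fmt = "png"
        try:
            render = RenderConfig(
                min_degree=(
                    int(raw_render["min_degree"])
                    if raw_render.get("min_degree") is not None else None
                ),
                min_reoccurrence=(
                    int(raw_render["min_reoccurrence"])
                    if raw_render.get("min_reoccurrence") is not None
                    else None
                ),
                seed=int(raw_render.get("seed", 0)),
                format=fmt,
            )
        except (TypeError, ValueError) as exc:
            problems.append(f"render: {exc}")

    if problems:
        raise ConfigError([f"{path}: {p}" for p in problems])
    out = base_dir / str(raw.get("out", "report.tsv"))
    return RunConfig(
        kind=kind, mode=mode, sources=tuple(sources), out=out,
        render=render, base_dir=base_dir,
    )
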