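"""Attribute-based filter criteria and their evaluation.

Filtering is entirely attribute-based: criteria never touch the key
(identifier) columns.  A value attribute is filtered with a comparison
operator (<, <=, >, >=, ==) against a number; a label attribute is
filtered by membership in a tag set (OR between tags).  Criteria on one
attribute form a *group* combined with explicit ``all`` (AND, e.g. a
cutoff range) or ``any`` (OR, e.g. an absolute-value cutoff |r| > 0.9
written as r > 0.9 OR r < -0.9) logic; the groups for different
attributes are always combined with AND.

A blank cell fails every criterion: a record with missing data for a
filtered attribute is never retained by that filter.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import ConfigError, DataError
from .io import LABEL, VALUE, AttributeSchema, Record, SourceTable, is_number

logger = logging.getLogger(__name__)

COMPARISON = "comparison"
TAG_SET = "tag_set"

_OPERATORS = ("<=", ">=", "==", "<", ">")
# Equality on floats uses a fixed absolute tolerance.
_EQ_TOL = 1e-9

_EXPR_RE = re.compile(r"^\s*(.+?)\s*(<=|>=|==|<|>)\s*(.+?)\s*$")


@dataclass(frozen=True)
class Criterion:
    """One predicate over a single attribute.

    Comparison form: ``operator``/``number`` against a value attribute.
    Tag-set form: ``tags`` membership against a label attribute.
    """

    attribute: str
    form: str  # COMPARISON or TAG_SET
    operator: str | None = None
    number: float | None = None
    tags: frozenset[str] | None = None

    def __post_init__(self):
        if self.form == COMPARISON:
            if self.operator not in _OPERATORS or self.number is None:
                raise ConfigError(
                    f"comparison criterion on {self.attribute!r} needs an "
                    "operator and a numeric operand"
                )
            if not math.isfinite(self.number):
                raise ConfigError(
                    f"criterion on {self.attribute!r}: operand must be finite"
                )
        elif self.form == TAG_SET:
            if not self.tags:
                raise ConfigError(
                    f"tag criterion on {self.attribute!r} needs at least one tag"
                )
        else:
            raise ConfigError(f"unknown criterion form {self.form!r}")

    def describe(self) -> str:
        if self.form == COMPARISON:
            return f"{self.attribute} {self.operator} {self.number:g}"
        return f"{self.attribute} == " + " | ".join(sorted(self.tags))


def parse_criterion(
    text: str, schema: Sequence[AttributeSchema]
) -> Criterion:
    """Parse ``attr OP number`` or ``attr == tag1 | tag2 | ...``.

    The attribute's declared kind disambiguates the two forms: a value
    attribute yields a comparison, a label attribute a tag set (tags only
    combine with ``==``).
    """
    m = _EXPR_RE.match(text)
    if not m:
        raise ConfigError(f"cannot parse criterion {text!r}")
    attr, op, operand = m.group(1), m.group(2), m.group(3)
    by_name = {s.name: s for s in schema}
    if attr not in by_name:
        raise ConfigError(
            f"criterion {text!r}: unknown attribute {attr!r} "
            f"(declared: {sorted(by_name)})"
        )
    kind = by_name[attr].kind
    if kind == VALUE:
        if not is_number(operand):
            raise ConfigError(
                f"criterion {text!r}: operand {operand!r} is not numeric "
                f"({attr!r} is a value attribute)"
            )
        return Criterion(attr, COMPARISON, operator=op, number=float(operand))
    # label attribute
    if op != "==":
        raise ConfigError(
            f"criterion {text!r}: comparison operator {op!r} cannot apply "
            f"to label attribute {attr!r}"
        )
    tags = frozenset(t.strip() for t in operand.split("|") if t.strip())
    if not tags:
        raise ConfigError(f"criterion {text!r}: empty tag list")
    return Criterion(attr, TAG_SET, tags=tags)


def evaluate_criterion(record: Record, criterion: Criterion) -> bool:
    """True iff the record's cell satisfies the criterion.

    Blank cells always evaluate False.
    """
    raw = record.cell(criterion.attribute).strip()
    if raw == "":
        return False
    if criterion.form == TAG_SET:
        return raw in criterion.tags
    if not is_number(raw):
        return False
    x = float(raw)
    op, y = criterion.operator, criterion.number
    if op == "<":
        return x < y
    if op == "<=":
        return x <= y
    if op == ">":
        return x > y
    if op == ">=":
        return x >= y
    return abs(x - y) <= _EQ_TOL  # "==" within tolerance


@dataclass(frozen=True)
class FilterSet:
    """The per-source conjunction of per-attribute criterion groups."""

    source: str
    groups: tuple[tuple[str, tuple[Criterion, ...]], ...] = ()
    group_logic: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        logic = dict(self.group_logic)
        for attr, crits in self.groups:
            for c in crits:
                if c.attribute != attr:
                    raise ConfigError(
                        f"criterion on {c.attribute!r} placed in group {attr!r}"
                    )
            if logic.get(attr, "all") not in ("all", "any"):
                raise ConfigError(
                    f"group {attr!r}: logic must be 'all' or 'any'"
                )

    @classmethod
    def build(
        cls,
        source: str,
        groups: Mapping[str, Sequence[Criterion]] | None = None,
        logic: Mapping[str, str] | None = None,
    ) -> "FilterSet":
        groups = groups or {}
        logic = logic or {}
        return cls(
            source=source,
            groups=tuple((a, tuple(cs)) for a, cs in groups.items()),
            group_logic=tuple(logic.items()),
        )

    @property
    def is_empty(self) -> bool:
        return not self.groups

    def logic_of(self, attribute: str) -> str:
        return dict(self.group_logic).get(attribute, "all")

    @property
    def attributes(self) -> tuple[str, ...]:
        return tuple(a for a, _ in self.groups)

    def describe(self) -> list[str]:
        """Human-readable per-group description for report provenance."""
        out = []
        for attr, crits in self.groups:
            joiner = " AND " if self.logic_of(attr) == "all" else " OR "
            out.append(joiner.join(c.describe() for c in crits))
        return out


def evaluate_filter_set(record: Record, filters: FilterSet) -> bool:
    """AND across attribute groups; all/any logic within each group.

    An empty FilterSet retains everything.
    """
    for attr, crits in filters.groups:
        results = (evaluate_criterion(record, c) for c in crits)
        ok = all(results) if filters.logic_of(attr) == "all" else any(results)
        if not ok:
            return False
    return True


def apply_filter_set(table: SourceTable, filters: FilterSet) -> SourceTable:
    """Return a new table with exactly the records passing the FilterSet.

    The input table is untouched; schema and name carry over.  Record
    counts in/out are logged so the provenance of a run is auditable.
    """
    if filters.source != table.name:
        raise DataError(
            f"filter set for {filters.source!r} applied to table {table.name!r}"
        )
    missing = set(filters.attributes) - set(table.attribute_names)
    if missing:
        raise ConfigError(
            f"{table.name}: filters reference absent attribute(s) "
            f"{sorted(missing)}"
        )
    kept = tuple(
        rec for rec in table.records if evaluate_filter_set(rec, filters)
    )
    logger.info(
        "filter %s: %d records in, %d retained", table.name,
        len(table.records), len(kept),
    )
    if table.records and not kept and not filters.is_empty:
        logger.warning("filter %s retained no records", table.name)
    return table.with_records(kept)
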