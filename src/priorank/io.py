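"""Reading, typing and validating named-matrix source files.

A *named matrix* is a tab-delimited UTF-8 table with a mandatory header
row.  A **list** source has one leading identifier column; a **network**
source has two leading node columns (an edge is the pair of nodes it
connects).  Any further columns are attributes, each either a ``value``
(numeric) or a ``label`` (tag) column.  Blank attribute cells are allowed
and preserved; blank key cells are an error.

Cells are kept as their raw text so that writing a table back out
reproduces the input byte for byte; numeric interpretation happens lazily
through :meth:`SourceTable.value_of`.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import DataError, TableFormatError

VALUE = "value"
LABEL = "label"

LIST = "list"
NETWORK = "network"

# Decimal or scientific notation only; no locale separators, no inf/nan.
_NUMBER_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def is_number(text: str) -> bool:
    """True iff *text* is a finite decimal/scientific numeric literal."""
    return bool(_NUMBER_RE.match(text.strip()))


@dataclass(frozen=True)
class AttributeSchema:
    """One attribute column: its name and whether it is numeric or a tag."""

    name: str
    kind: str  # VALUE or LABEL

    def __post_init__(self):
        if not self.name:
            raise DataError("attribute name must be non-empty")
        if self.kind not in (VALUE, LABEL):
            raise DataError(f"unknown attribute kind {self.kind!r}")


@dataclass(frozen=True)
class Record:
    """One row: 1 (list) or 2 (network) key identifiers plus attribute cells.

    Attribute cells are raw strings; the empty string is a blank cell.
    """

    keys: tuple[str, ...]
    attributes: tuple[tuple[str, str], ...] = ()

    @property
    def attribute_map(self) -> dict[str, str]:
        return dict(self.attributes)

    def cell(self, attribute: str) -> str:
        for name, raw in self.attributes:
            if name == attribute:
                return raw
        raise KeyError(attribute)


@dataclass(frozen=True)
class SourceTable:
    """One named list or network matrix, as read from a file."""

    name: str
    kind: str  # LIST or NETWORK
    key_columns: tuple[str, ...]
    attributes: tuple[AttributeSchema, ...]
    records: tuple[Record, ...]

    def __post_init__(self):
        expected = 1 if self.kind == LIST else 2
        if self.kind not in (LIST, NETWORK):
            raise DataError(f"unknown table kind {self.kind!r}")
        if len(self.key_columns) != expected:
            raise DataError(
                f"{self.name}: {self.kind} table needs {expected} key "
                f"column(s), got {len(self.key_columns)}"
            )
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise DataError(f"{self.name}: duplicate attribute names")

    @property
    def attribute_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.attributes)

    @property
    def columns(self) -> tuple[str, ...]:
        return self.key_columns + self.attribute_names

    def schema_of(self, attribute: str) -> AttributeSchema:
        for a in self.attributes:
            if a.name == attribute:
                return a
        raise KeyError(attribute)

    def value_of(self, record: Record, attribute: str) -> float | None:
        """Numeric value of a cell, or None when blank."""
        raw = record.cell(attribute).strip()
        if raw == "":
            return None
        if not is_number(raw):
            raise DataError(
                f"{self.name}: non-numeric cell {raw!r} in value "
                f"attribute {attribute!r}"
            )
        return float(raw)

    def with_records(self, records: Iterable[Record]) -> "SourceTable":
        return replace(self, records=tuple(records))


@dataclass(frozen=True)
class TableDecl:
    """Optional up-front declaration of a table's roles and kinds.

    Anything left as None is inferred: the table kind defaults to ``list``,
    key columns are the leading one or two header columns, and attribute
    kinds come from :func:`infer_schema`.
    """

    name: str | None = None
    kind: str | None = None
    key_columns: tuple[str, ...] | None = None
    attribute_kinds: Mapping[str, str] | None = None


@dataclass(frozen=True)
class Diagnostic:
    level: str  # "warning" | "error"
    message: str
    row: int | None = None  # 1-based file line number

    def __str__(self):
        where = f" (row {self.row})" if self.row is not None else ""
        return f"{self.level}: {self.message}{where}"


def infer_schema(
    attribute_columns: Sequence[str], rows: Sequence[Sequence[str]]
) -> tuple[AttributeSchema, ...]:
    """Infer value/label kinds from the data.

    A column is ``value`` iff it has at least one non-blank cell and every
    non-blank cell parses as a finite number; otherwise (mixed content or
    entirely blank) it is ``label``.  Deterministic and row-order
    independent: the decision is a conjunction over cells.
    """
    schemas = []
    for j, name in enumerate(attribute_columns):
        cells = [row[j].strip() for row in rows]
        nonblank = [c for c in cells if c != ""]
        if nonblank and all(is_number(c) for c in nonblank):
            kind = VALUE
        else:
            kind = LABEL
        schemas.append(AttributeSchema(name, kind))
    return tuple(schemas)


def read_source_table(path, declared: TableDecl | None = None) -> SourceTable:
    """Read one tab-delimited named matrix into a :class:`SourceTable`.

    The first row is the header.  Column roles and attribute kinds are
    taken from *declared* when given, otherwise inferred.  All malformed
    rows (wrong field count, blank key, non-numeric cell in a declared
    value column) are collected and reported together in a single
    :class:`TableFormatError` naming the offending file lines.
    """
    path = Path(path)
    declared = declared or TableDecl()
    if not path.exists():
        raise DataError(f"source file not found: {path}")

    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise TableFormatError(path, ["file is empty (no header row)"])
        header = [h.strip() for h in header]
        raw_rows = list(reader)

    kind = declared.kind or LIST
    n_keys = 1 if kind == LIST else 2
    if len(header) < n_keys:
        raise TableFormatError(
            path, [f"{kind} table needs at least {n_keys} column(s)"]
        )

    key_columns = tuple(header[:n_keys])
    if declared.key_columns is not None:
        if tuple(declared.key_columns) != key_columns:
            raise TableFormatError(
                path,
                [
                    f"declared key columns {tuple(declared.key_columns)} do not "
                    f"match leading header columns {key_columns}"
                ],
            )
    attr_names = header[n_keys:]
    if len(set(header)) != len(header):
        raise TableFormatError(path, ["duplicate column names in header"])

    problems: list[str] = []
    good_rows: list[tuple[int, list[str]]] = []
    for i, row in enumerate(raw_rows):
        line_no = i + 2  # 1-based, after the header
        if len(row) != len(header):
            problems.append(
                f"row {line_no}: expected {len(header)} fields, got {len(row)}"
            )
            continue
        keys = tuple(c.strip() for c in row[:n_keys])
        if any(k == "" for k in keys):
            problems.append(f"row {line_no}: blank key identifier")
            continue
        good_rows.append((line_no, row))

    # Attribute kinds: declared wins, otherwise inferred from good rows.
    if declared.attribute_kinds is not None:
        unknown = set(declared.attribute_kinds) - set(attr_names)
        if unknown:
            raise TableFormatError(
                path, [f"declared kinds for unknown columns: {sorted(unknown)}"]
            )
        inferred = dict(
            zip(
                attr_names,
                (
                    s.kind
                    for s in infer_schema(
                        attr_names, [r[n_keys:] for _, r in good_rows]
                    )
                ),
            )
        )
        schemas = tuple(
            AttributeSchema(n, declared.attribute_kinds.get(n, inferred[n]))
            for n in attr_names
        )
    else:
        schemas = infer_schema(attr_names, [r[n_keys:] for _, r in good_rows])

    # A declared value column must be numeric wherever non-blank.
    by_name = {s.name: s for s in schemas}
    for line_no, row in good_rows:
        for name, raw in zip(attr_names, row[n_keys:]):
            if by_name[name].kind == VALUE and raw.strip() != "":
                if not is_number(raw):
                    problems.append(
                        f"row {line_no}: non-numeric cell {raw.strip()!r} "
                        f"in value column {name!r}"
                    )

    if problems:
        raise TableFormatError(path, problems)

    records = tuple(
        Record(
            keys=tuple(c.strip() for c in row[:n_keys]),
            attributes=tuple(zip(attr_names, row[n_keys:])),
        )
        for _, row in good_rows
    )
    name = declared.name or path.stem
    return SourceTable(
        name=name,
        kind=kind,
        key_columns=key_columns,
        attributes=schemas,
        records=records,
    )


def write_source_table(table: SourceTable, path) -> None:
    """Write a table back to TSV; re-reading reproduces it exactly."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(table.columns)
        for rec in table.records:
            writer.writerow(list(rec.keys) + [raw for _, raw in rec.attributes])


def validate_table(table: SourceTable) -> list[Diagnostic]:
    """Non-mutating sanity checks: duplicate rows, blanks, self-loops, types.

    Everything reported here is advisory — duplicates within one source are
    legal (they collapse at integration time) and self-loops are retained.
    """
    diags: list[Diagnostic] = []
    seen: dict[tuple[str, ...], int] = {}
    for i, rec in enumerate(table.records):
        line_no = i + 2
        if any(k == "" for k in rec.keys):
            diags.append(Diagnostic("error", "blank key identifier", line_no))
        key = rec.keys if table.kind == LIST else tuple(sorted(rec.keys))
        if key in seen:
            diags.append(
                Diagnostic(
                    "warning",
                    f"duplicate entry {'|'.join(rec.keys)} "
                    f"(first at row {seen[key]})",
                    line_no,
                )
            )
        else:
            seen[key] = line_no
        if table.kind == NETWORK and rec.keys[0] == rec.keys[1]:
            diags.append(
                Diagnostic("warning", f"self-loop ({rec.keys[0]})", line_no)
            )
        for schema in table.attributes:
            if schema.kind == VALUE:
                raw = rec.cell(schema.name).strip()
                if raw != "" and not is_number(raw):
                    diags.append(
                        Diagnostic(
                            "error",
                            f"non-numeric cell {raw!r} in value "
                            f"attribute {schema.name!r}",
                            line_no,
                        )
                    )
    return diags
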