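"""Independent brute-force oracles and random-input builders for tests.

Everything here is deliberately naive: direct per-row predicate checks,
set-membership counting, exhaustive enumeration with math.comb.  None of
it calls the library code paths it is used to check.
"""

from __future__ import annotations

import math
import random

from priorank.criteria import COMPARISON, Criterion, FilterSet
from priorank.io import (
    LABEL,
    LIST,
    NETWORK,
    VALUE,
    AttributeSchema,
    Record,
    SourceTable,
)

TAGS = ("red", "green", "blue", "amber")


# ---------------------------------------------------------------- oracles

def oracle_criterion(raw_cell: str, criterion: Criterion) -> bool:
    """Plain re-statement of one-criterion semantics."""
    cell = raw_cell.strip()
    if cell == "":
        return False
    if criterion.form == COMPARISON:
        try:
            x = float(cell)
        except ValueError:
            return False
        y = criterion.number
        return {
            "<": x < y,
            "<=": x <= y,
            ">": x > y,
            ">=": x >= y,
            "==": abs(x - y) <= 1e-9,
        }[criterion.operator]
    return cell in criterion.tags


def oracle_filter_set(record: Record, filters: FilterSet) -> bool:
    """Row-by-row: AND over groups, all/any within each group."""
    cells = dict(record.attributes)
    for attr, crits in filters.groups:
        outcomes = [oracle_criterion(cells[attr], c) for c in crits]
        combined = (
            all(outcomes) if filters.logic_of(attr) == "all"
            else any(outcomes)
        )
        if not combined:
            return False
    return True


def oracle_list_reoccurrence(tables) -> dict[str, tuple[int, set]]:
    """Set-membership counting over distinct per-source elements."""
    support: dict[str, set] = {}
    for t in tables:
        for el in {r.keys[0] for r in t.records}:
            support.setdefault(el, set()).add(t.name)
    return {el: (len(s), s) for el, s in support.items()}


def oracle_edge_reoccurrence(tables) -> dict[tuple, tuple[int, set]]:
    """Same counting, on unordered node pairs."""
    support: dict[tuple, set] = {}
    for t in tables:
        for key in {tuple(sorted(r.keys)) for r in t.records}:
            support.setdefault(key, set()).add(t.name)
    return {k: (len(s), s) for k, s in support.items()}


def oracle_cumulative(values) -> list[tuple[int, int]]:
    """Direct threshold counting for each distinct observed level."""
    return [
        (level, sum(1 for v in values if v >= level))
        for level in sorted(set(values))
    ]


def oracle_hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by full enumeration with binomial coefficients."""
    total = math.comb(N, n)
    lo, hi = max(0, n + K - N), min(n, K)
    acc = 0
    for i in range(max(k, lo), hi + 1):
        acc += math.comb(K, i) * math.comb(N - K, n - i)
    return acc / total


# --------------------------------------------------------------- builders

def random_list_table(rng: random.Random, name: str,
                      n_rows: int | None = None) -> SourceTable:
    """A list table with one value and one label attribute, with blanks."""
    n_rows = n_rows if n_rows is not None else rng.randint(1, 25)
    schema = (AttributeSchema("x", VALUE), AttributeSchema("tag", LABEL))
    records = []
    for i in range(n_rows):
        # duplicate identifiers on purpose, sometimes
        ident = f"g{rng.randint(1, max(2, n_rows))}"
        x = "" if rng.random() < 0.15 else f"{rng.uniform(-2, 2):.4f}"
        tag = "" if rng.random() < 0.15 else rng.choice(TAGS)
        records.append(Record((ident,), (("x", x), ("tag", tag))))
    return SourceTable(name, LIST, ("gene",), schema, tuple(records))


def random_filter_set(rng: random.Random, name: str) -> FilterSet:
    """A random FilterSet over the random_list_table schema."""
    groups: dict[str, list[Criterion]] = {}
    logic: dict[str, str] = {}
    if rng.random() < 0.8:
        ops = ("<", "<=", ">", ">=", "==")
        crits = [
            Criterion("x", COMPARISON, operator=rng.choice(ops),
                      number=round(rng.uniform(-2, 2), 3))
            for _ in range(rng.randint(1, 3))
        ]
        groups["x"] = crits
        logic["x"] = rng.choice(("all", "any"))
    if rng.random() < 0.6:
        k = rng.randint(1, len(TAGS))
        groups["tag"] = [
            Criterion("tag", "tag_set",
                      tags=frozenset(rng.sample(TAGS, k)))
        ]
        logic["tag"] = "all"
    return FilterSet.build(name, groups=groups, logic=logic)


def random_network_table(rng: random.Random, name: str,
                         n_nodes: int = 8,
                         n_rows: int | None = None) -> SourceTable:
    n_rows = n_rows if n_rows is not None else rng.randint(1, 15)
    nodes = [f"n{i}" for i in range(1, n_nodes + 1)]
    records = []
    for _ in range(n_rows):
        a = rng.choice(nodes)
        b = rng.choice(nodes)  # self-loops allowed
        records.append(Record((a, b)))
    return SourceTable(name, NETWORK, ("node_a", "node_b"), (),
                       tuple(records))
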