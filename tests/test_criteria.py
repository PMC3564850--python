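"""Criterion parsing, blank-cell semantics and FilterSet evaluation."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import oracle_filter_set, random_filter_set, random_list_table
from priorank.criteria import (
    COMPARISON,
    TAG_SET,
    Criterion,
    FilterSet,
    apply_filter_set,
    evaluate_criterion,
    evaluate_filter_set,
    parse_criterion,
)
from priorank.errors import ConfigError, DataError
from priorank.io import LABEL, LIST, VALUE, AttributeSchema, Record, SourceTable

SCHEMA = (AttributeSchema("corr", VALUE), AttributeSchema("age", LABEL))


def rec(corr="", age=""):
    return Record(("g",), (("corr", corr), ("age", age)))


class TestParseCriterion:
    def test_comparison_on_value_attribute(self):
        c = parse_criterion("corr > 0.9", SCHEMA)
        assert c == Criterion("corr", COMPARISON, operator=">", number=0.9)

    def test_tag_set_on_label_attribute(self):
        c = parse_criterion("age == P6 | P10", SCHEMA)
        assert c.form == TAG_SET
        assert c.tags == frozenset({"P6", "P10"})

    @pytest.mark.parametrize("expr,msg", [
        ("corr > high", "not numeric"),
        ("size > 1", "unknown attribute"),
        ("age > P6", "cannot apply"),
        ("age == ", "empty tag list"),
        ("age == |", "empty tag list"),
        ("corr 0.9", "cannot parse"),
    ])
    def test_malformed_expressions(self, expr, msg):
        with pytest.raises(ConfigError, match=msg):
            parse_criterion(expr, SCHEMA)

    @pytest.mark.parametrize("op", ["<", "<=", ">", ">=", "=="])
    def test_all_five_operators_parse(self, op):
        c = parse_criterion(f"corr {op} -0.5", SCHEMA)
        assert (c.operator, c.number) == (op, -0.5)


class TestEvaluateCriterion:
    gt09 = Criterion("corr", COMPARISON, operator=">", number=0.9)
    tags = Criterion("age", TAG_SET, tags=frozenset({"P6", "P10"}))

    def test_numeric_relation_holds(self):
        assert evaluate_criterion(rec(corr="0.95"), self.gt09)
        assert not evaluate_criterion(rec(corr="0.85"), self.gt09)

    def test_tag_membership(self):
        assert evaluate_criterion(rec(age="P6"), self.tags)
        assert not evaluate_criterion(rec(age="E16"), self.tags)

    def test_blank_cell_always_fails(self):
        assert not evaluate_criterion(rec(), self.gt09)
        assert not evaluate_criterion(rec(), self.tags)

    def test_float_equality_within_tolerance(self):
        eq = Criterion("corr", COMPARISON, operator="==", number=0.3)
        assert evaluate_criterion(rec(corr="0.3000000000004"), eq)
        assert not evaluate_criterion(rec(corr="0.301"), eq)


class TestEvaluateFilterSet:
    def test_cutoff_range_all_logic(self):
        fs = FilterSet.build("S", groups={"corr": [
            parse_criterion("corr >= 0.4", SCHEMA),
            parse_criterion("corr <= 0.6", SCHEMA),
        ]})
        assert evaluate_filter_set(rec(corr="0.5"), fs)
        assert not evaluate_filter_set(rec(corr="0.7"), fs)

    def test_absolute_value_cutoff_any_logic(self):
        fs = FilterSet.build("S", groups={"corr": [
            parse_criterion("corr > 0.9", SCHEMA),
            parse_criterion("corr < -0.9", SCHEMA),
        ]}, logic={"corr": "any"})
        assert evaluate_filter_set(rec(corr="-0.95"), fs)
        assert evaluate_filter_set(rec(corr="0.95"), fs)
        assert not evaluate_filter_set(rec(corr="0.0"), fs)

    def test_and_across_attribute_groups(self):
        fs = FilterSet.build("S", groups={
            "corr": [parse_criterion("corr > 0.9", SCHEMA)],
            "age": [parse_criterion("age == P6 | P10", SCHEMA)],
        })
        assert evaluate_filter_set(rec(corr="0.95", age="P6"), fs)
        assert not evaluate_filter_set(rec(corr="0.95", age="E16"), fs)

    def test_empty_filter_set_retains_everything(self):
        assert evaluate_filter_set(rec(), FilterSet.build("S"))


class TestApplyFilterSet:
    def make_table(self, corrs):
        return SourceTable(
            "S", LIST, ("gene",), SCHEMA,
            tuple(Record((f"g{i}",), (("corr", c), ("age", "")))
                  for i, c in enumerate(corrs)),
        )

    def test_retains_exactly_passing_records(self):
        corrs = ["0.95", "0.2", "0.91", "", "0.99", "-0.5", "0.93", "0.1",
                 "0.5", "0.92"]
        t = self.make_table(corrs)
        fs = FilterSet.build(
            "S", groups={"corr": [parse_criterion("corr > 0.9", SCHEMA)]})
        out = apply_filter_set(t, fs)
        assert len(out.records) == 5
        assert len(t.records) == 10  # original untouched
        assert all(float(r.cell("corr")) > 0.9 for r in out.records)

    def test_empty_filter_is_identity(self):
        t = self.make_table(["0.1", "0.2"])
        assert apply_filter_set(t, FilterSet.build("S")).records == t.records

    def test_all_fail_yields_empty_table(self):
        t = self.make_table(["0.1", "0.2"])
        fs = FilterSet.build(
            "S", groups={"corr": [parse_criterion("corr > 99", SCHEMA)]})
        assert apply_filter_set(t, fs).records == ()

    def test_source_name_mismatch_is_an_error(self):
        t = self.make_table(["0.1"])
        with pytest.raises(DataError, match="applied to table"):
            apply_filter_set(t, FilterSet.build("other"))

    def test_absent_attribute_is_an_error(self):
        t = self.make_table(["0.1"])
        fs = FilterSet.build("S", groups={"zzz": [
            Criterion("zzz", COMPARISON, operator=">", number=0.0)]})
        with pytest.raises(ConfigError, match="absent"):
            apply_filter_set(t, fs)


class TestFilterProperties:
    def test_oracle_equivalence(self, rng):
        """Retained set == independent row-by-row predicate evaluation."""
        for i in range(200):
            t = random_list_table(rng, "S")
            fs = random_filter_set(rng, "S")
            kept = apply_filter_set(t, fs).records
            expected = tuple(r for r in t.records if oracle_filter_set(r, fs))
            assert kept == expected

    def test_idempotence(self, rng):
        for i in range(50):
            t = random_list_table(rng, "S")
            fs = random_filter_set(rng, "S")
            once = apply_filter_set(t, fs)
            assert apply_filter_set(once, fs).records == once.records

    def test_monotonicity_adding_a_criterion_never_enlarges(self, rng):
        for i in range(50):
            t = random_list_table(rng, "S")
            fs = random_filter_set(rng, "S")
            extra = Criterion("x", COMPARISON, operator=">",
                              number=round(rng.uniform(-2, 2), 3))
            groups = dict(fs.groups)
            groups["x"] = tuple(groups.get("x", ())) + (extra,)
            logic = dict(fs.group_logic)
            logic["x"] = "all"  # conjunction can only shrink
            tighter = FilterSet.build("S", groups=groups, logic=logic)
            base = apply_filter_set(t, fs).records
            tight = apply_filter_set(t, tighter).records
            assert len(tight) <= len(base)
            assert all(r in base for r in tight)
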