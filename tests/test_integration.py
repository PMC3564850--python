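"""Merging sources into ranked elements and networks with provenance."""

import itertools
import random

import pytest

from oracles import (
    oracle_edge_reoccurrence,
    oracle_list_reoccurrence,
    random_filter_set,
    random_list_table,
    random_network_table,
)
from priorank.criteria import FilterSet, apply_filter_set
from priorank.errors import DataError
from priorank.integrate import (
    BACKWARD,
    DEFINED,
    DIRECTED,
    FORWARD,
    MERGED,
    NONE,
    UNDEFINED,
    UNDIRECTED,
    canonical_edge_key,
    integrate_lists,
    integrate_networks,
    rank_candidates,
)
from priorank.io import LIST, NETWORK, Record, SourceTable


def list_table(name, elements):
    return SourceTable(name, LIST, ("gene",), (),
                       tuple(Record((e,)) for e in elements))


def net_table(name, pairs):
    return SourceTable(name, NETWORK, ("a", "b"), (),
                       tuple(Record(p) for p in pairs))


class TestIntegrateLists:
    def test_three_source_membership_counting(self):
        tables = [
            list_table("S1", ["g1", "g2", "g3"]),
            list_table("S2", ["g2", "g3"]),
            list_table("S3", ["g2"]),
        ]
        out = {e.element: e for e in integrate_lists(tables)}
        assert (out["g2"].reoccurrence, out["g2"].sources) == \
            (3, ("S1", "S2", "S3"))
        assert (out["g3"].reoccurrence, out["g3"].sources) == (2, ("S1", "S2"))
        assert (out["g1"].reoccurrence, out["g1"].sources) == (1, ("S1",))

    def test_single_source_gives_reoccurrence_one(self):
        out = integrate_lists([list_table("S1", ["a", "b"])])
        assert all(e.reoccurrence == 1 for e in out)

    def test_within_source_duplicates_collapse(self):
        out = integrate_lists([list_table("S1", ["g5", "g5"])])
        assert [(e.element, e.reoccurrence) for e in out] == [("g5", 1)]

    def test_mixing_kinds_is_an_error(self):
        with pytest.raises(DataError, match="mix"):
            integrate_lists([list_table("S1", ["a"]),
                             net_table("S2", [("A", "B")])])

    def test_defined_mode_filters_first(self, rng):
        t = random_list_table(rng, "S1")
        fs = random_filter_set(rng, "S1")
        defined = integrate_lists([t], {"S1": fs}, mode=DEFINED)
        manual = integrate_lists([apply_filter_set(t, fs)])
        assert defined == manual


class TestCanonicalEdgeKey:
    def test_symmetry(self):
        assert canonical_edge_key("B", "A") == ("A", "B")
        assert canonical_edge_key("A", "B") == canonical_edge_key("B", "A")

    def test_self_loop(self):
        assert canonical_edge_key("A", "A") == ("A", "A")

    def test_case_sensitive(self):
        assert canonical_edge_key("nrl", "Nrl") == ("Nrl", "nrl")

    def test_blank_endpoint_rejected(self):
        with pytest.raises(DataError):
            canonical_edge_key("", "A")


class TestIntegrateNetworks:
    def test_worked_two_source_merge(self, worked_network):
        edges = worked_network.edge_map
        ab = edges[("A", "B")]
        assert (ab.reoccurrence, ab.direction_status) == (2, MERGED)
        assert ab.sources == ("S1", "S2")
        bc = edges[("B", "C")]
        assert (bc.reoccurrence, bc.direction_status) == (1, UNDIRECTED)
        cd = edges[("C", "D")]
        assert (cd.reoccurrence, cd.direction_status) == (1, DIRECTED)
        assert worked_network.degree_map == {"A": 1, "B": 2, "C": 2, "D": 1}

    def test_renamed_copy_doubles_reoccurrence(self):
        pairs = [("A", "B"), ("B", "C")]
        net = integrate_networks(
            [net_table("S1", pairs), net_table("S1copy", pairs)])
        assert all(e.reoccurrence == 2 for e in net.edges)
        assert len(net.edges) == 2

    def test_opposite_orientations_share_one_edge(self):
        net = integrate_networks(
            [net_table("S1", [("A", "B")]), net_table("S2", [("B", "A")])],
            directedness={"S1": DIRECTED, "S2": DIRECTED},
        )
        (e,) = net.edges
        assert e.key == ("A", "B")
        assert e.reoccurrence == 2
        assert e.direction_status == DIRECTED
        assert e.directions == frozenset({FORWARD, BACKWARD})

    def test_direction_merge_exhaustive_27_cases(self):
        """All 3-source combinations of undirected / a->b / b->a."""
        kinds = ("undirected", "forward", "backward")
        for combo in itertools.product(kinds, repeat=3):
            tables, directedness = [], {}
            for i, k in enumerate(combo):
                name = f"S{i}"
                pair = ("A", "B") if k != "backward" else ("B", "A")
                tables.append(net_table(name, [pair]))
                directedness[name] = (
                    UNDIRECTED if k == "undirected" else DIRECTED
                )
            net = integrate_networks(tables, directedness=directedness)
            (e,) = net.edges
            has_und = "undirected" in combo
            has_dir = any(k != "undirected" for k in combo)
            expected = (
                MERGED if has_und and has_dir
                else DIRECTED if has_dir else UNDIRECTED
            )
            assert e.direction_status == expected, combo
            assert e.reoccurrence == 3

    def test_self_loop_degree_contribution(self):
        net = integrate_networks([net_table("S1", [("A", "A"), ("A", "B")])])
        assert net.degree_map["A"] == 2  # loop counts once


class TestRankCandidates:
    def test_reoccurrence_then_lexicographic(self):
        items = integrate_lists([
            list_table("S1", ["B", "A", "C"]),
            list_table("S2", ["B", "A"]),
        ])
        ranked = rank_candidates(items)
        assert [e.element for e in ranked] == ["A", "B", "C"]

    def test_all_ties_is_pure_lexicographic(self):
        items = integrate_lists([list_table("S1", ["c", "a", "b"])])
        assert [e.element for e in rank_candidates(items)] == ["a", "b", "c"]

    def test_empty_input(self):
        assert rank_candidates([]) == []


class TestIntegrationProperties:
    def test_list_oracle_equivalence(self, rng):
        for _ in range(60):
            n = rng.randint(1, 5)
            tables = [random_list_table(rng, f"S{i}") for i in range(n)]
            got = {e.element: (e.reoccurrence, set(e.sources))
                   for e in integrate_lists(tables)}
            assert got == oracle_list_reoccurrence(tables)

    def test_network_oracle_equivalence(self, rng):
        for _ in range(60):
            n = rng.randint(1, 4)
            tables = [random_network_table(rng, f"S{i}") for i in range(n)]
            net = integrate_networks(tables)
            got = {e.key: (e.reoccurrence, set(e.sources))
                   for e in net.edges}
            assert got == oracle_edge_reoccurrence(tables)

    def test_permutation_invariance(self, rng):
        tables = [random_network_table(rng, f"S{i}") for i in range(4)]
        base = integrate_networks(tables)
        for _ in range(5):
            shuffled = tables[:]
            rng.shuffle(shuffled)
            shuffled = [
                t.with_records(
                    tuple(rng.sample(list(t.records), len(t.records))))
                for t in shuffled
            ]
            assert integrate_networks(shuffled) == base

    def test_degree_sum_identity(self, rng):
        for _ in range(30):
            tables = [random_network_table(rng, f"S{i}")
                      for i in range(rng.randint(1, 4))]
            net = integrate_networks(tables)
            loops = sum(1 for e in net.edges if e.is_self_loop)
            assert sum(net.degree_map.values()) == \
                2 * (len(net.edges) - loops) + loops

    def test_undefined_mode_equals_empty_filter_sets(self, rng):
        tables = [random_list_table(rng, f"S{i}") for i in range(3)]
        empties = {t.name: FilterSet.build(t.name) for t in tables}
        assert integrate_lists(tables, None, mode=UNDEFINED) == \
            integrate_lists(tables, empties, mode=DEFINED)

    def test_reoccurrence_bounds(self, rng):
        tables = [random_list_table(rng, f"S{i}") for i in range(4)]
        for e in integrate_lists(tables):
            assert 1 <= e.reoccurrence <= 4
            assert e.reoccurrence == len(e.sources)

    def test_conservation_of_source_element_pairs(self, rng):
        """Union of per-element source sets == surviving (source, element)."""
        tables = [random_list_table(rng, f"S{i}") for i in range(3)]
        filters = {t.name: random_filter_set(rng, t.name) for t in tables}
        out = integrate_lists(tables, filters, mode=DEFINED)
        integrated_pairs = {
            (s, e.element) for e in out for s in e.sources
        }
        surviving = {
            (t.name, r.keys[0])
            for t in tables
            for r in apply_filter_set(t, filters[t.name]).records
        }
        assert integrated_pairs == surviving
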