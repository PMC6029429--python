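"""Tree model: parsing, validation, canonical serialization, DOT export."""

import re

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import foodfta as f
from foodfta.fixtures import generate_random_tree
from foodfta.model import (
    EventNode,
    FaultTree,
    Gate,
    PopulationGroup,
    Subtree,
    TransferRef,
)
from tests.conftest import MINIMAL_OR


class TestParse:
    def test_minimal_tree(self, minimal_or):
        assert len(minimal_or.events) == 3
        assert len(minimal_or.subtrees) == 1
        assert minimal_or.top_event.id == "top"
        assert {e.id for e in minimal_or.basic_events()} == {"a", "b"}

    def test_accepts_json_text(self, minimal_or):
        # canonical serialization is JSON, which the parser reads back
        assert f.parse_tree(f.serialize_tree(minimal_or)) == minimal_or

    def test_self_loop_is_cycle_error(self):
        doc = """
id: t
subtrees: [{id: main, top_event: top}]
events:
  - {id: top, label: T, kind: top, subtree: main, gate: {type: or, inputs: [x]}}
  - {id: x, label: X, kind: intermediate, subtree: main, gate: {type: or, inputs: [x]}}
"""
        with pytest.raises(f.CycleError):
            f.parse_tree(doc)

    def test_transfer_cycle_detected(self):
        doc = """
id: t
subtrees: [{id: main, top_event: top}, {id: s1, top_event: u}]
events:
  - {id: top, label: T, kind: top, subtree: main, gate: {type: or, inputs: ["subtree:s1"]}}
  - {id: u, label: U, kind: intermediate, subtree: s1, gate: {type: or, inputs: [v]}}
  - {id: v, label: V, kind: intermediate, subtree: s1, gate: {type: or, inputs: ["subtree:s1"]}}
"""
        with pytest.raises(f.CycleError):
            f.parse_tree(doc)

    def test_unknown_reference(self):
        doc = MINIMAL_OR.replace("inputs: [a, b]", "inputs: [a, nope]")
        with pytest.raises(f.UnknownReferenceError):
            f.parse_tree(doc)

    def test_duplicate_id(self):
        doc = MINIMAL_OR + "  - {id: a, label: again, kind: basic, subtree: main}\n"
        with pytest.raises(f.DuplicateIdError):
            f.parse_tree(doc)

    def test_schema_violation_names_path(self):
        with pytest.raises(f.TreeParseError) as exc:
            f.parse_tree("id: t\nevents:\n  - {id: x, label: X}\n")
        assert "$.events[0]" in str(exc.value)


def _tree(events, groups=(), subtrees=None):
    if subtrees is None:
        subtrees = [Subtree(id="main", title="", top_event_id="top")]
    return FaultTree(id="t", events=events, subtrees=subtrees, groups=groups)


def _basic(ev_id, subtree="main", indicator=None):
    return EventNode(id=ev_id, label=ev_id, kind="basic", subtree_id=subtree,
                     indicator=indicator)


def _top(inputs, gtype="or", overrides=()):
    return EventNode(id="top", label="top", kind="top", subtree_id="main",
                     gate=Gate(type=gtype, inputs=tuple(inputs), overrides=dict(overrides)))


class TestValidation:
    def test_valid_minimal(self, minimal_or):
        report = f.validate_tree(minimal_or)
        assert report.ok and not report.errors

    @pytest.mark.parametrize(
        "mutation, code",
        [
            ("two_tops", "top-count"),
            ("gate_on_basic", "gate-on-basic"),
            ("gate_missing", "gate-missing"),
            ("indicator_on_top", "indicator-on-nonbasic"),
            ("bad_weights", "weight-sum"),
            ("zero_inputs", "gate-arity"),
            ("bad_override_group", "override-unknown-group"),
            ("subtree_top_elsewhere", "subtree-top-outside"),
            ("bad_pft", "indicator-pft-range"),
        ],
    )
    def test_each_violation_yields_its_error(self, mutation, code):
        """Introducing exactly one invariant violation produces exactly the
        corresponding error entry."""
        ind = f.IndicatorSpec(name="x", units="u", fail_when="ge", threshold=1.0)
        if mutation == "two_tops":
            tree = _tree([_top(["a"]),
                          EventNode(id="top2", label="", kind="top", subtree_id="main",
                                    gate=Gate("or", ("a",))),
                          _basic("a")])
        elif mutation == "gate_on_basic":
            tree = _tree([_top(["a", "b"]),
                          EventNode(id="a", label="a", kind="basic", subtree_id="main",
                                    gate=Gate("or", ("b",))),
                          _basic("b")])
        elif mutation == "gate_missing":
            tree = _tree([EventNode(id="top", label="", kind="top", subtree_id="main"),
                          _basic("a")])
        elif mutation == "indicator_on_top":
            tree = _tree([EventNode(id="top", label="", kind="top", subtree_id="main",
                                    gate=Gate("or", ("a",)), indicator=ind),
                          _basic("a")])
        elif mutation == "bad_weights":
            tree = _tree([_top(["a"]), _basic("a")],
                         groups=[PopulationGroup("g1", "", 0.7),
                                 PopulationGroup("g2", "", 0.7)])
        elif mutation == "zero_inputs":
            tree = _tree([_top([]), _basic("a")])
        elif mutation == "bad_override_group":
            tree = _tree([_top(["a"], overrides={"ghost": "and"}), _basic("a")])
        elif mutation == "subtree_top_elsewhere":
            tree = _tree([_top(["a"]), _basic("a", subtree="s1")],
                         subtrees=[Subtree("main", "", "top"), Subtree("s1", "", "top")])
        elif mutation == "bad_pft":
            bad = f.IndicatorSpec(name="x", units="u", fail_when="ge", threshold=1.0,
                                  population_fraction_threshold=1.5)
            tree = _tree([_top(["a"]), _basic("a", indicator=bad)])
        report = f.validate_tree(tree)
        assert not report.ok
        assert [e.code for e in report.errors] == [code]

    def test_orphan_is_warning_not_error(self):
        tree = _tree([_top(["a"]), _basic("a"), _basic("stray")])
        report = f.validate_tree(tree)
        assert report.ok
        assert [w.code for w in report.warnings] == ["orphan"]
        assert report.warnings[0].location == "stray"

    def test_findings_deterministically_ordered(self):
        tree = _tree([_top([]), _basic("a", subtree="ghost"),
                      _basic("b", subtree="ghost")])
        r1 = f.validate_tree(tree)
        r2 = f.validate_tree(tree)
        assert [(e.location, e.code) for e in r1.errors] == \
               [(e.location, e.code) for e in r2.errors]
        assert [e.location for e in r1.errors] == sorted(e.location for e in r1.errors)

    @pytest.mark.parametrize("seed", range(20))
    def test_dag_check_matches_topological_oracle(self, seed):
        """Cycle detection agrees with an independent DFS-based oracle on
        random graphs, including graphs with planted cycles."""
        import random

        rng = random.Random(seed)
        n = rng.randint(3, 9)
        tree = generate_random_tree(n_basic=n, max_depth=3, seed=seed)
        events = dict(tree.events)
        planted = seed % 2 == 1
        if planted:
            # every basic is reachable from the top, so feeding the top event
            # back into one basic's new gate always closes a cycle
            victim = rng.choice([e.id for e in tree.basic_events()])
            events[victim] = EventNode(id=victim, label=victim, kind="intermediate",
                                       subtree_id="main", gate=Gate("or", ("top",)))
        mutated = FaultTree(id="m", events=events.values(),
                            subtrees=tree.subtrees.values())

        # oracle: iterative DFS cycle detection, independent of networkx
        graph = {ev.id: mutated.resolved_inputs(ev) for ev in mutated.events.values()}
        WHITE, GREY, BLACK = 0, 1, 2
        color = {v: WHITE for v in graph}
        has_cycle = False
        for start in graph:
            if color[start] != WHITE:
                continue
            stack = [(start, iter(graph[start]))]
            color[start] = GREY
            while stack:
                node, it = stack[-1]
                advanced = False
                for nxt in it:
                    if color[nxt] == GREY:
                        has_cycle = True
                    elif color[nxt] == WHITE:
                        color[nxt] = GREY
                        stack.append((nxt, iter(graph[nxt])))
                        advanced = True
                        break
                if not advanced:
                    color[node] = BLACK
                    stack.pop()

        report = f.validate_tree(mutated)
        assert has_cycle == any(e.code == "cycle" for e in report.errors)
        if planted:
            assert has_cycle


class TestSerialization:
    def test_round_trip_minimal(self, minimal_or):
        assert f.parse_tree(f.serialize_tree(minimal_or)) == minimal_or

    def test_round_trip_food_tree(self, food_tree):
        assert f.parse_tree(f.serialize_tree(food_tree)) == food_tree

    def test_canonical_form_is_byte_identical(self, food_tree):
        a = f.serialize_tree(food_tree)
        b = f.serialize_tree(f.parse_tree(a))
        assert a == b

    def test_refuses_invalid_tree(self):
        tree = _tree([_top([]), _basic("a")])
        with pytest.raises(f.ValidationFailedError) as exc:
            f.serialize_tree(tree)
        assert exc.value.report.errors

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(n=st.integers(1, 12), depth=st.integers(1, 4),
           af=st.floats(0, 1), seed=st.integers(0, 10_000))
    def test_round_trip_random_trees(self, n, depth, af, seed):
        tree = generate_random_tree(n, depth, and_fraction=af, seed=seed)
        assert f.parse_tree(f.serialize_tree(tree)) == tree


class TestDotExport:
    def test_minimal_counts(self, minimal_or):
        dot = f.export_dot(minimal_or)
        event_nodes = re.findall(r'^\s+"(top|a|b)" \[shape=', dot, re.M)
        gate_nodes = re.findall(r'^\s+"gate_\w+" \[shape=', dot, re.M)
        edges = re.findall(r'" -> "', dot)
        assert len(event_nodes) == 3
        assert len(gate_nodes) == 1
        assert len(edges) == 3
        assert dot.startswith("digraph") and dot.rstrip().endswith("}")

    def test_deterministic(self, food_tree):
        assert f.export_dot(food_tree) == f.export_dot(food_tree)

    def test_group_selects_effective_gate_label(self, food_tree):
        dot_dr = f.export_dot(food_tree, group="donation_reliant")
        dot_gen = f.export_dot(food_tree, group="general")
        avail_dr = re.search(r'"gate_food_unavailable" \[shape=\w+, label="(\w+)"\]', dot_dr)
        avail_gen = re.search(r'"gate_food_unavailable" \[shape=\w+, label="(\w+)"\]', dot_gen)
        assert avail_dr.group(1) == "OR"
        assert avail_gen.group(1) == "AND"

    def test_unknown_group_rejected(self, food_tree):
        with pytest.raises(f.UnknownReferenceError):
            f.export_dot(food_tree, group="martians")

    def test_transfer_edges_point_at_subtree_tops(self, food_tree):
        dot = f.export_dot(food_tree)
        assert '"production_failure" -> "gate_supply_chain_failure";' in dot
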