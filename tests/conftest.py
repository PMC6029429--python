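"""Shared fixtures and independent oracles.

The oracles deliberately avoid the library's evaluation/enumeration code
paths: Boolean evaluation is a naive unmemoized recursion, cut sets come
from exhaustive truth tables with subset minimalization, and probabilities
are weighted sums over all 2^n assignments driven by the naive evaluator.
"""

from itertools import combinations, product

import pytest

from foodfta import StateAssignment, load_food_system_tree, parse_tree
from foodfta.model import FaultTree


# ---------------------------------------------------------------------------
# independent oracles


def naive_eval(tree: FaultTree, states: dict[str, bool], group: str | None = None) -> dict[str, bool]:
    """Recursive truth evaluation without memoization or topological order."""

    def value(ev_id: str) -> bool:
        ev = tree.events[ev_id]
        if ev.is_basic:
            return bool(states.get(ev_id, False))
        gtype = ev.gate.overrides.get(group, ev.gate.type) if group else ev.gate.type
        vals = [value(tree.resolve_ref(r)) for r in ev.gate.inputs]
        return all(vals) if gtype == "and" else any(vals)

    return {ev_id: value(ev_id) for ev_id in tree.events}


def truth_table_top(tree: FaultTree, group: str | None = None):
    """(basics, {assignment-tuple: top_failed}) over all 2^n assignments."""
    basics = sorted(e.id for e in tree.basic_events())
    top = tree.top_event.id
    table = {}
    for bits in product([False, True], repeat=len(basics)):
        states = dict(zip(basics, bits))
        table[bits] = naive_eval(tree, states, group)[top]
    return basics, table


def brute_cut_sets(tree: FaultTree, group: str | None = None) -> set[frozenset]:
    """Minimal failing sets via the truth table + subset minimalization."""
    basics, table = truth_table_top(tree, group)
    failing = [
        frozenset(b for b, bit in zip(basics, bits) if bit)
        for bits, top in table.items()
        if top
    ]
    failing = [s for s in failing if s]
    minimal = set()
    for s in sorted(failing, key=len):
        if not any(m <= s for m in minimal):
            minimal.add(s)
    return minimal


def brute_top_probability(tree: FaultTree, probs: dict[str, float], group=None) -> float:
    """Exact P(top) by weighted truth-table sum (independent basics)."""
    basics, table = truth_table_top(tree, group)
    total = 0.0
    for bits, top in table.items():
        if not top:
            continue
        w = 1.0
        for b, bit in zip(basics, bits):
            w *= probs[b] if bit else 1.0 - probs[b]
        total += w
    return total


def all_false(tree: FaultTree) -> StateAssignment:
    return StateAssignment({e.id: False for e in tree.basic_events()})


def failing_only(tree: FaultTree, *failed: str) -> StateAssignment:
    states = {e.id: False for e in tree.basic_events()}
    for b in failed:
        states[b] = True
    return StateAssignment(states)


# ---------------------------------------------------------------------------
# trees


MINIMAL_OR = """
id: minimal
subtrees: [{id: main, top_event: top}]
events:
  - {id: top, label: system fails, kind: top, subtree: main, gate: {type: or, inputs: [a, b]}}
  - {id: a, label: component A fails, kind: basic, subtree: main}
  - {id: b, label: component B fails, kind: basic, subtree: main}
"""

TEXTBOOK = """
id: textbook
subtrees: [{id: main, top_event: top}]
events:
  - {id: top, label: T, kind: top, subtree: main, gate: {type: or, inputs: [a, band]}}
  - {id: band, label: B and C, kind: intermediate, subtree: main, gate: {type: and, inputs: [b, c]}}
  - {id: a, label: A, kind: basic, subtree: main}
  - {id: b, label: B, kind: basic, subtree: main}
  - {id: c, label: C, kind: basic, subtree: main}
"""

AND_ONLY = """
id: andtree
subtrees: [{id: main, top_event: top}]
events:
  - {id: top, label: T, kind: top, subtree: main, gate: {type: and, inputs: [a, b]}}
  - {id: a, label: A, kind: basic, subtree: main}
  - {id: b, label: B, kind: basic, subtree: main}
"""

# shared basic event s feeding both branches of an AND (repeated event)
SHARED = """
id: shared
subtrees: [{id: main, top_event: top}]
events:
  - {id: top, label: T, kind: top, subtree: main, gate: {type: and, inputs: [left, right]}}
  - {id: left, label: L, kind: intermediate, subtree: main, gate: {type: or, inputs: [s, x]}}
  - {id: right, label: R, kind: intermediate, subtree: main, gate: {type: or, inputs: [s, y]}}
  - {id: s, label: shared, kind: basic, subtree: main}
  - {id: x, label: X, kind: basic, subtree: main}
  - {id: y, label: Y, kind: basic, subtree: main}
"""


@pytest.fixture
def minimal_or():
    return parse_tree(MINIMAL_OR)


@pytest.fixture
def textbook():
    return parse_tree(TEXTBOOK)


@pytest.fixture
def and_only():
    return parse_tree(AND_ONLY)


@pytest.fixture
def shared_tree():
    return parse_tree(SHARED)


@pytest.fixture(scope="session")
def food_tree():
    return load_food_system_tree()
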