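"""Qualitative vulnerability analysis: minimal cut sets and path sets.

A *minimal cut set* is a minimal set of basic events whose joint failure
forces the top event — the formal notion of a vulnerability point.  The
dual *minimal path set* is a minimal set of basic events whose joint
functioning guarantees the system functions.

Cut sets are enumerated by top-down gate expansion (MOCUS-style): starting
from the top event, OR gates branch the working collection of sets and AND
gates extend each set, with repeated events absorbed by idempotent set
union; subset absorption at the end leaves only minimal sets.  Path sets
are the cut sets of the dual tree (AND and OR swapped everywhere,
including group overrides).
"""

from __future__ import annotations

from dataclasses import dataclass

from .engine import StateAssignment, evaluate_states, resolve_gate
from .model import EventNode, FaultTree, FaultTreeError, Gate

__all__ = [
    "CutSet",
    "CombinatorialGuardError",
    "minimal_cut_sets",
    "minimal_path_sets",
    "single_points_of_failure",
    "dual_tree",
]

DEFAULT_CAP = 10**6


class CombinatorialGuardError(FaultTreeError):
    def __init__(self, size: int, cap: int):
        super().__init__(
            f"intermediate product-set size {size} exceeds cap {cap}; "
            "set max_order to bound the expansion"
        )


@dataclass(frozen=True)
class CutSet:
    """A set of basic events; ``order`` is its cardinality."""

    events: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "events", frozenset(self.events))
        if not self.events:
            raise ValueError("cut sets are nonempty")

    @property
    def order(self) -> int:
        return len(self.events)

    def sort_key(self):
        return (self.order, tuple(sorted(self.events)))

    def __iter__(self):
        return iter(sorted(self.events))


def _minimize(sets: list[frozenset[str]]) -> list[frozenset[str]]:
    """Subset absorption: drop every set with a proper subset present."""
    uniq = sorted(set(sets), key=len)
    kept: list[frozenset[str]] = []
    for s in uniq:
        if not any(k <= s for k in kept):
            kept.append(s)
    return kept


def minimal_cut_sets(
    tree: FaultTree,
    group: str | None = None,
    max_order: int | None = None,
    cap: int = DEFAULT_CAP,
) -> list[CutSet]:
    """Enumerate minimal cut sets, sorted by order then lexicographically.

    Complete overall when ``max_order`` is absent, complete up to
    ``max_order`` otherwise.  If the working collection grows past ``cap``
    a :class:`CombinatorialGuardError` asks the caller to bound the order.
    """
    top = tree.top_event.id
    # working sets may contain intermediate ids; expand until only basics remain
    work: list[frozenset[str]] = [frozenset({top})]
    basics = {e.id for e in tree.basic_events()}

    def expand_one(s: frozenset[str]) -> list[frozenset[str]] | None:
        for ev_id in sorted(s):
            if ev_id in basics:
                continue
            ev = tree.events[ev_id]
            eff = resolve_gate(tree, ev.gate, group)
            inputs = tree.resolved_inputs(ev)
            rest = s - {ev_id}
            if eff == "and":
                return [rest | set(inputs)]
            return [rest | {i} for i in inputs]
        return None  # all basic

    done: list[frozenset[str]] = []
    while work:
        s = work.pop()
        expanded = expand_one(s)
        if expanded is None:
            done.append(s)
            continue
        for t in expanded:
            if max_order is not None and len(t & basics) > max_order:
                continue
            work.append(t)
        if len(work) + len(done) > cap:
            raise CombinatorialGuardError(len(work) + len(done), cap)

    minimal = _minimize(done)
    if max_order is not None:
        minimal = [s for s in minimal if len(s) <= max_order]
    return sorted((CutSet(s) for s in minimal), key=CutSet.sort_key)


def dual_tree(tree: FaultTree) -> FaultTree:
    """Structural dual: every AND becomes OR and vice versa (overrides too)."""
    flip = {"and": "or", "or": "and"}
    events = []
    for ev in tree.events.values():
        gate = ev.gate
        if gate is not None:
            gate = Gate(
                type=flip[gate.type],
                inputs=gate.inputs,
                overrides={g: flip[t] for g, t in gate.overrides.items()},
            )
        events.append(
            EventNode(
                id=ev.id, label=ev.label, kind=ev.kind, subtree_id=ev.subtree_id,
                gate=gate, indicator=ev.indicator, citation=ev.citation,
            )
        )
    return FaultTree(
        id=tree.id + "_dual", title=tree.title, version=tree.version,
        events=events, subtrees=tree.subtrees.values(), groups=tree.groups.values(),
        metadata=tree.metadata,
    )


def minimal_path_sets(
    tree: FaultTree,
    group: str | None = None,
    max_order: int | None = None,
    cap: int = DEFAULT_CAP,
) -> list[CutSet]:
    """Minimal path sets: minimal cut sets of the dual tree.

    Keeping every event of a path set operational guarantees the top event
    does not fail, whatever the other components do.
    """
    return minimal_cut_sets(dual_tree(tree), group=group, max_order=max_order, cap=cap)


def single_points_of_failure(tree: FaultTree, group: str | None = None) -> list[str]:
    """Basic events whose lone failure fails the top event (order-1 cuts)."""
    spofs = []
    basics = sorted(e.id for e in tree.basic_events())
    for b in basics:
        assignment = StateAssignment({x: x == b for x in basics})
        if evaluate_states(tree, assignment, group=group).top_failed:
            spofs.append(b)
    return spofs
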