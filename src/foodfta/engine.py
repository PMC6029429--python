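"""Deterministic Boolean evaluation of fault trees.

Indicator values are turned into basic-event failed/operational states by
inclusive threshold comparison, then gate logic propagates states bottom-up
to the top event in a single memoized pass over the DAG.  ``True`` denotes
*failure* (the event occurs), matching fault-tree convention; functionality
is the complement.

Gates may resolve differently per population group: ``resolve_gate``
returns the override for the requested group when one is declared,
otherwise the structural gate type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .model import FaultTree, Gate, FaultTreeError, UnknownReferenceError

__all__ = [
    "StateAssignment",
    "IndicatorAssignment",
    "EvaluationResult",
    "MissingStateError",
    "resolve_gate",
    "apply_thresholds",
    "evaluate_states",
    "evaluate_matrix",
]


class MissingStateError(FaultTreeError):
    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(
            "no state assigned to basic events (and no default policy): "
            + ", ".join(self.missing)
        )


@dataclass
class StateAssignment:
    """Map basic-event id -> failed? (True = failed)."""

    states: dict[str, bool]
    source: str = "direct"  # "direct" | "thresholded"

    def merged_with(self, other: "StateAssignment") -> "StateAssignment":
        """Overlay ``other`` on top of this assignment (other wins on clash)."""
        merged = dict(self.states)
        merged.update(other.states)
        src = self.source if self.source == other.source else "direct"
        return StateAssignment(merged, source=src)


@dataclass
class IndicatorAssignment:
    """Observed indicator values (and optional affected-population fractions)."""

    values: dict[str, float]
    affected_fraction: dict[str, float] = field(default_factory=dict)


@dataclass
class EvaluationResult:
    node_states: dict[str, bool]
    group: str
    top_failed: bool


def resolve_gate(tree: FaultTree, gate: Gate, group: str | None = None) -> str:
    """Effective gate type for a population group (override wins)."""
    if group is None:
        return gate.type
    if group not in tree.groups:
        raise UnknownReferenceError(f"undeclared population group: {group}")
    return gate.overrides.get(group, gate.type)


def apply_thresholds(tree: FaultTree, indicators: IndicatorAssignment) -> StateAssignment:
    """Convert indicator observations into basic-event states.

    An event is failed iff its value crosses the threshold (inclusive, in
    the declared direction) and, when both a population-fraction threshold
    and an affected fraction are supplied, enough of the population is
    affected.  Values for events without an indicator spec are errors, as
    are non-finite values.
    """
    states: dict[str, bool] = {}
    for ev_id, value in indicators.values.items():
        ev = tree.events.get(ev_id)
        if ev is None or ev.indicator is None:
            raise FaultTreeError(f"event {ev_id!r} has no indicator specification")
        if not np.isfinite(value):
            raise FaultTreeError(f"non-finite indicator value for {ev_id!r}: {value}")
        spec = ev.indicator
        crossed = value >= spec.threshold if spec.fail_when == "ge" else value <= spec.threshold
        if crossed and spec.population_fraction_threshold is not None:
            frac = indicators.affected_fraction.get(ev_id)
            if frac is not None:
                crossed = frac >= spec.population_fraction_threshold
        states[ev_id] = bool(crossed)
    return StateAssignment(states, source="thresholded")


def _combine(gate_type: str, values) -> bool:
    return all(values) if gate_type == "and" else any(values)


def evaluate_states(
    tree: FaultTree,
    assignment: StateAssignment,
    group: str | None = None,
    default_operational: bool = False,
) -> EvaluationResult:
    """Propagate basic-event states up to the top event.

    Single bottom-up pass in topological order; shared (transfer-referenced)
    events are evaluated once.  Basic events missing from the assignment
    raise :class:`MissingStateError` unless ``default_operational`` opts into
    treating them as not failed.
    """
    if group is not None and group not in tree.groups:
        raise UnknownReferenceError(f"undeclared population group: {group}")
    unknown = set(assignment.states) - {e.id for e in tree.basic_events()}
    if unknown:
        raise FaultTreeError(
            "states assigned to non-basic or unknown events: " + ", ".join(sorted(unknown))
        )
    missing = {e.id for e in tree.basic_events()} - set(assignment.states)
    if missing and not default_operational:
        raise MissingStateError(missing)

    node_states: dict[str, bool] = {}
    for ev_id in tree.topological_order():
        ev = tree.events[ev_id]
        if ev.is_basic:
            node_states[ev_id] = bool(assignment.states.get(ev_id, False))
        else:
            eff = resolve_gate(tree, ev.gate, group)
            node_states[ev_id] = _combine(
                eff, (node_states[i] for i in tree.resolved_inputs(ev))
            )
    top = tree.top_event.id
    return EvaluationResult(
        node_states=node_states,
        group=group if group is not None else "default",
        top_failed=node_states[top],
    )


def evaluate_matrix(
    tree: FaultTree,
    basic_states: Mapping[str, np.ndarray],
    group: str | None = None,
) -> dict[str, np.ndarray]:
    """Vectorized evaluation over many assignments at once.

    ``basic_states`` maps basic-event id -> boolean vector (one entry per
    assignment); unlisted basics are treated as operational.  Returns a
    boolean vector per event.  Used by enumeration and Monte-Carlo
    probability methods.
    """
    if group is not None and group not in tree.groups:
        raise UnknownReferenceError(f"undeclared population group: {group}")
    n = len(next(iter(basic_states.values()))) if basic_states else 1
    out: dict[str, np.ndarray] = {}
    for ev_id in tree.topological_order():
        ev = tree.events[ev_id]
        if ev.is_basic:
            arr = basic_states.get(ev_id)
            out[ev_id] = (
                np.zeros(n, dtype=bool) if arr is None else np.asarray(arr, dtype=bool)
            )
        else:
            eff = resolve_gate(tree, ev.gate, group)
            inputs = [out[i] for i in tree.resolved_inputs(ev)]
            acc = inputs[0].copy()
            if eff == "and":
                for arr in inputs[1:]:
                    acc &= arr
            else:
                for arr in inputs[1:]:
                    acc |= arr
            out[ev_id] = acc
    return out
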