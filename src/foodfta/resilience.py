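"""Temporal analysis: tree evaluation along scenarios, functionality curves,
resilience indices, and recovery times.

Resilience is operationalized as *functionality over time*: at each
scenario time point, indicator values are thresholded into basic-event
states and propagated through the tree; a node's functionality is
``1 - failed``.  A population-weighted curve averages per-group
functionality with the tree's group weights, turning different gate logic
per group (e.g. donation-reliant vs general population) into a graded
community functionality level.

The resilience index of a curve over a window is the normalized area under
the step-interpolated functionality curve — 1 when fully functional
throughout, 0 when failed throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .engine import (
    IndicatorAssignment,
    StateAssignment,
    apply_thresholds,
    evaluate_states,
)
from .model import FaultTree, FaultTreeError
from .scenario import ScenarioTimeline

__all__ = [
    "FunctionalityCurve",
    "evaluate_timeline",
    "functionality_curve",
    "population_weighted_curve",
    "resilience_index",
    "recovery_time",
    "NOT_RECOVERED",
]

NOT_RECOVERED = None  # sentinel returned when a series never recovers


@dataclass
class FunctionalityCurve:
    """Functioning level of one event over time, in [0,1] (1 = functional)."""

    times: np.ndarray
    values: np.ndarray
    node: str
    group: str  # group id, "default", or "population_weighted"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise FaultTreeError("curve times and values differ in length")
        if np.any((self.values < 0) | (self.values > 1)):
            raise FaultTreeError("functionality values must lie in [0,1]")


def evaluate_timeline(
    tree: FaultTree,
    scenario: ScenarioTimeline,
    group: str | None = None,
    default_operational: bool = False,
) -> dict[str, np.ndarray]:
    """Evaluate the tree at every scenario time point.

    Per time point: threshold the indicator observations, overlay direct
    state series, and propagate gate logic; returns a Boolean failed-series
    per event, aligned with ``scenario.times`` (step semantics between
    points).  Indicator units must match the event's indicator spec.
    """
    for ev_id, units in scenario.indicator_units.items():
        ev = tree.events.get(ev_id)
        if ev is None or ev.indicator is None:
            raise FaultTreeError(f"scenario indicator series for {ev_id!r}, "
                                 "but the event has no indicator spec")
        if units != "value" and units != ev.indicator.units:
            raise FaultTreeError(
                f"unit mismatch for {ev_id!r}: scenario {units!r} vs spec {ev.indicator.units!r}"
            )

    n = len(scenario.times)
    out: dict[str, list[bool]] = {ev_id: [] for ev_id in tree.events}
    for i in range(n):
        values = {ev: series[i] for ev, series in scenario.indicators.items()}
        affected = {ev: series[i] for ev, series in scenario.affected.items()}
        thresholded = apply_thresholds(tree, IndicatorAssignment(values, affected))
        direct = StateAssignment(
            {ev: bool(series[i]) for ev, series in scenario.states.items()}
        )
        assignment = thresholded.merged_with(direct)
        result = evaluate_states(tree, assignment, group=group,
                                 default_operational=default_operational)
        for ev_id, state in result.node_states.items():
            out[ev_id].append(state)
    return {ev_id: np.array(vals, dtype=bool) for ev_id, vals in out.items()}


def functionality_curve(
    times: np.ndarray,
    failed: np.ndarray,
    node: str,
    group: str = "default",
) -> FunctionalityCurve:
    """Single-group curve: F(t) = 1 - failed(t)."""
    failed = np.asarray(failed, dtype=bool)
    return FunctionalityCurve(times=times, values=1.0 - failed.astype(float),
                              node=node, group=group)


def population_weighted_curve(
    times: np.ndarray,
    failed_by_group: Mapping[str, np.ndarray],
    weights: Mapping[str, float],
    node: str,
) -> FunctionalityCurve:
    """Weighted curve: F(t) = sum_g w_g (1 - failed_g(t)).

    A convex combination of the per-group curves, hence bounded by their
    pointwise min and max.
    """
    if not weights:
        raise FaultTreeError("population weights required for the weighted curve")
    missing = set(failed_by_group) - set(weights)
    if missing:
        raise FaultTreeError("no weight for groups: " + ", ".join(sorted(missing)))
    values = np.zeros(len(np.asarray(times)), dtype=float)
    for g, failed in failed_by_group.items():
        values += weights[g] * (1.0 - np.asarray(failed, dtype=bool).astype(float))
    return FunctionalityCurve(times=times, values=values, node=node,
                              group="population_weighted")


def resilience_index(
    curve: FunctionalityCurve,
    window: tuple[float, float] | None = None,
) -> float:
    """Normalized area under the step functionality curve over a window.

    R = (1/(t_end - t_start)) * integral F(t) dt with zero-order-hold
    interpolation; 1 iff fully functional throughout, 0 iff failed
    throughout.  The window must lie within the curve's span and be
    nonempty.
    """
    t = curve.times
    if window is None:
        window = (float(t[0]), float(t[-1]))
    a, b = float(window[0]), float(window[1])
    if b <= a:
        raise FaultTreeError(f"empty resilience window: [{a}, {b}]")
    if a < t[0] or b > t[-1]:
        raise FaultTreeError(f"window [{a}, {b}] outside curve span [{t[0]}, {t[-1]}]")
    # segment i holds value values[i] on [t_i, t_{i+1})
    edges = np.append(t, t[-1])
    area = 0.0
    for i in range(len(t)):
        left = t[i]
        right = t[i + 1] if i + 1 < len(t) else b
        lo = max(left, a)
        hi = min(right, b)
        if hi > lo:
            area += curve.values[i] * (hi - lo)
    return area / (b - a)


def _first_sustained_after(times: np.ndarray, bad: np.ndarray) -> float | None:
    """First time after the last 'bad' point; None if bad at the end."""
    idx = np.flatnonzero(bad)
    if len(idx) == 0:
        return float(times[0])
    last = idx[-1]
    if last == len(times) - 1:
        return None
    return float(times[last + 1])


def recovery_time(
    times: np.ndarray,
    series: np.ndarray,
    mode: str = "outage",
    nominal: float | None = None,
    t0: float = 0.0,
    tol: float = 1e-9,
):
    """Recovery duration of one event series.

    ``outage`` (Boolean series): duration from the first failure to the
    first *sustained* recovery (no relapse through the end of the series;
    relapses restart the clock).  0 when the series never fails;
    ``NOT_RECOVERED`` (None) when it never recovers.

    ``restoration_interval`` (indicator series): length of the graded
    restoration phase — from the end of the total-outage plateau (the run
    of worst values) to the first return to the nominal value.

    ``full_restoration`` (indicator series): time from ``t0`` to the first
    sustained return to the nominal value.
    """
    times = np.asarray(times, dtype=float)
    series = np.asarray(series)
    if len(series) == 0:
        raise FaultTreeError("empty series")

    if mode == "outage":
        failed = series.astype(bool)
        if not failed.any():
            return 0.0
        t_fail = float(times[np.flatnonzero(failed)[0]])
        t_rec = _first_sustained_after(times, failed)
        if t_rec is None:
            return NOT_RECOVERED
        return t_rec - t_fail

    values = series.astype(float)
    nom = float(nominal) if nominal is not None else float(values[0])
    deviation = np.abs(values - nom)

    if mode == "restoration_interval":
        worst = deviation.max()
        if worst <= tol:
            return 0.0
        at_worst = deviation >= worst - tol
        first = int(np.flatnonzero(at_worst)[0])
        end = first
        while end + 1 < len(values) and at_worst[end + 1]:
            end += 1
        back = np.flatnonzero(deviation[end + 1:] <= tol)
        if len(back) == 0:
            return NOT_RECOVERED
        return float(times[end + 1 + back[0]] - times[end])

    if mode == "full_restoration":
        off_nominal = deviation > tol
        if not off_nominal.any():
            return 0.0
        t_rec = _first_sustained_after(times, off_nominal)
        if t_rec is None:
            return NOT_RECOVERED
        return max(t_rec - t0, 0.0)

    raise FaultTreeError(f"unknown recovery mode: {mode!r}")
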