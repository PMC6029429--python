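"""Probabilistic fault-tree analysis.

Basic events are modelled as independent Bernoulli failures over the
analysis horizon (independence is an explicit contract, not a checked
property).  The top-event probability can be computed three ways:

``bottom_up``
    Closed form on proper trees (no event feeding two gates):
    P(AND) = prod p_i, P(OR) = 1 - prod(1 - p_i).  Structurally invalid in
    the presence of repeated (transfer-shared) events.
``enumeration``
    Exact sum over all 2^n basic-state assignments; handles repeated
    events; n is capped (default 20) because the cost is exponential.
``monte_carlo``
    Unbiased seed-reproducible estimate with a binomial standard error.

``auto`` picks bottom_up when structurally valid, else enumeration when n
is small enough, else Monte Carlo.

Importance measures: Birnbaum I_B(b) = P(top | b failed) - P(top | b
operational); Fussell-Vesely FV(b) = P(some minimal cut set containing b
is fully failed) / P(top).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .engine import evaluate_matrix
from .model import FaultTree, FaultTreeError
from .structure import minimal_cut_sets

__all__ = [
    "ProbabilityAssignment",
    "TopEventProbability",
    "RepeatedEventsError",
    "top_event_probability",
    "birnbaum_importance",
    "fussell_vesely_importance",
    "importance_report",
    "mitigation_delta",
    "has_repeated_events",
]

ENUMERATION_LIMIT = 20
DEFAULT_N_SAMPLES = 100_000
_CHUNK = 1 << 16


class RepeatedEventsError(FaultTreeError):
    pass


@dataclass
class ProbabilityAssignment:
    """Basic-event failure probabilities over the analysis horizon."""

    probs: dict[str, float]

    def __post_init__(self):
        for ev_id, p in self.probs.items():
            if not (0.0 <= p <= 1.0):
                raise FaultTreeError(f"probability for {ev_id!r} outside [0,1]: {p}")

    def replacing(self, updates: Mapping[str, float]) -> "ProbabilityAssignment":
        merged = dict(self.probs)
        merged.update(updates)
        return ProbabilityAssignment(merged)


@dataclass
class TopEventProbability:
    estimate: float
    stderr: float | None
    method: str
    n_basic: int


def _reachable_basics(tree: FaultTree) -> list[str]:
    import networkx as nx

    g = tree.input_graph()
    top = tree.top_event.id
    reach = nx.ancestors(g, top) | {top}
    return sorted(e.id for e in tree.basic_events() if e.id in reach)


def has_repeated_events(tree: FaultTree) -> bool:
    """True when some event reaches the top through two distinct paths.

    Detected as any event occurring more than once as a (resolved) gate
    input among events reachable from the top — exactly the condition under
    which the bottom_up closed form is invalid.
    """
    import networkx as nx

    g = tree.input_graph()
    top = tree.top_event.id
    reach = nx.ancestors(g, top) | {top}
    seen: dict[str, int] = {}
    for ev_id in reach:
        ev = tree.events[ev_id]
        if ev.gate is None:
            continue
        for src in tree.resolved_inputs(ev):
            seen[src] = seen.get(src, 0) + 1
    return any(c > 1 for c in seen.values())


def _check_total(tree: FaultTree, probs: ProbabilityAssignment, basics: list[str]):
    missing = set(basics) - set(probs.probs)
    if missing:
        raise FaultTreeError(
            "no probability assigned to basic events: " + ", ".join(sorted(missing))
        )


def _bottom_up(tree: FaultTree, probs: ProbabilityAssignment, group: str | None) -> float:
    if has_repeated_events(tree):
        raise RepeatedEventsError(
            "bottom_up is invalid on trees with repeated (shared) events; "
            "use enumeration or monte_carlo"
        )
    from .engine import resolve_gate

    value: dict[str, float] = {}
    for ev_id in tree.topological_order():
        ev = tree.events[ev_id]
        if ev.is_basic:
            value[ev_id] = probs.probs.get(ev_id, 0.0)
        else:
            eff = resolve_gate(tree, ev.gate, group)
            ps = [value[i] for i in tree.resolved_inputs(ev)]
            if eff == "and":
                value[ev_id] = float(np.prod(ps))
            else:
                value[ev_id] = float(1.0 - np.prod([1.0 - p for p in ps]))
    return value[tree.top_event.id]


def _enumerate(tree: FaultTree, probs: ProbabilityAssignment, group: str | None,
               basics: list[str]) -> float:
    n = len(basics)
    p = np.array([probs.probs.get(b, 0.0) for b in basics])
    total = 0.0
    n_rows = 1 << n
    for start in range(0, n_rows, _CHUNK):
        idx = np.arange(start, min(start + _CHUNK, n_rows), dtype=np.uint64)
        cols = ((idx[:, None] >> np.arange(n, dtype=np.uint64)) & 1).astype(bool)
        weights = np.prod(np.where(cols, p, 1.0 - p), axis=1)
        states = {b: cols[:, j] for j, b in enumerate(basics)}
        top = evaluate_matrix(tree, states, group=group)[tree.top_event.id]
        total += float(weights[top].sum())
    return total


def _monte_carlo(tree: FaultTree, probs: ProbabilityAssignment, group: str | None,
                 basics: list[str], n_samples: int, seed: int) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    p = np.array([probs.probs.get(b, 0.0) for b in basics])
    draws = rng.random((n_samples, len(basics))) < p
    states = {b: draws[:, j] for j, b in enumerate(basics)}
    top = evaluate_matrix(tree, states, group=group)[tree.top_event.id]
    est = float(top.mean())
    stderr = float(np.sqrt(est * (1.0 - est) / n_samples))
    return est, stderr


def top_event_probability(
    tree: FaultTree,
    probs: ProbabilityAssignment,
    group: str | None = None,
    method: str = "auto",
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
) -> TopEventProbability:
    """Probability the top event fails, assuming independent basic events.

    ``bottom_up`` and ``enumeration`` agree to ~1e-12 whenever both are
    valid; ``monte_carlo`` reports a standard error and is reproducible at
    a fixed seed.
    """
    basics = _reachable_basics(tree)
    _check_total(tree, probs, basics)
    if method == "auto":
        if not has_repeated_events(tree):
            method = "bottom_up"
        elif len(basics) <= ENUMERATION_LIMIT:
            method = "enumeration"
        else:
            method = "monte_carlo"
    if method == "bottom_up":
        return TopEventProbability(_bottom_up(tree, probs, group), None, method, len(basics))
    if method == "enumeration":
        if len(basics) > ENUMERATION_LIMIT:
            raise FaultTreeError(
                f"enumeration limited to {ENUMERATION_LIMIT} basic events, tree has {len(basics)}"
            )
        return TopEventProbability(_enumerate(tree, probs, group, basics), None, method, len(basics))
    if method == "monte_carlo":
        est, se = _monte_carlo(tree, probs, group, basics, n_samples, seed)
        return TopEventProbability(est, se, method, len(basics))
    raise FaultTreeError(f"unknown method: {method!r}")


def birnbaum_importance(
    tree: FaultTree,
    probs: ProbabilityAssignment,
    group: str | None = None,
    method: str = "auto",
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
) -> pd.DataFrame:
    """Birnbaum importance per basic event, sorted descending (ties by id).

    Computed as the difference of two conditioned top-event probabilities
    (event forced failed vs forced operational) with a shared method and
    seed, so Monte-Carlo noise largely cancels.
    """
    basics = _reachable_basics(tree)
    _check_total(tree, probs, basics)
    rows = []
    for b in basics:
        hi = top_event_probability(tree, probs.replacing({b: 1.0}), group, method, n_samples, seed)
        lo = top_event_probability(tree, probs.replacing({b: 0.0}), group, method, n_samples, seed)
        rows.append({"event_id": b, "birnbaum": hi.estimate - lo.estimate})
    df = pd.DataFrame(rows).sort_values(
        ["birnbaum", "event_id"], ascending=[False, True], ignore_index=True
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def _cut_union_probability(
    cut_sets: list[frozenset[str]],
    probs: ProbabilityAssignment,
    n_samples: int,
    seed: int,
) -> float:
    """P(at least one of the given cut sets is fully failed), exactly when
    the involved basic-event count permits enumeration, else Monte Carlo."""
    involved = sorted(set().union(*cut_sets)) if cut_sets else []
    if not involved:
        return 0.0
    p = np.array([probs.probs.get(b, 0.0) for b in involved])
    col = {b: j for j, b in enumerate(involved)}
    if len(involved) <= ENUMERATION_LIMIT:
        n = len(involved)
        total = 0.0
        n_rows = 1 << n
        for start in range(0, n_rows, _CHUNK):
            idx = np.arange(start, min(start + _CHUNK, n_rows), dtype=np.uint64)
            cols = ((idx[:, None] >> np.arange(n, dtype=np.uint64)) & 1).astype(bool)
            weights = np.prod(np.where(cols, p, 1.0 - p), axis=1)
            hit = np.zeros(len(idx), dtype=bool)
            for s in cut_sets:
                sub = np.ones(len(idx), dtype=bool)
                for b in s:
                    sub &= cols[:, col[b]]
                hit |= sub
            total += float(weights[hit].sum())
        return total
    rng = np.random.default_rng(seed)
    draws = rng.random((n_samples, len(involved))) < p
    hit = np.zeros(n_samples, dtype=bool)
    for s in cut_sets:
        sub = np.ones(n_samples, dtype=bool)
        for b in s:
            sub &= draws[:, col[b]]
        hit |= sub
    return float(hit.mean())


def fussell_vesely_importance(
    tree: FaultTree,
    probs: ProbabilityAssignment,
    group: str | None = None,
    method: str = "auto",
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
) -> pd.DataFrame:
    """Fussell-Vesely importance: share of top-event probability carried by
    cut sets containing each basic event.  NaN when P(top) = 0 (undefined)."""
    basics = _reachable_basics(tree)
    _check_total(tree, probs, basics)
    cuts = [c.events for c in minimal_cut_sets(tree, group=group)]
    p_top = top_event_probability(tree, probs, group, method, n_samples, seed).estimate
    rows = []
    for b in basics:
        mine = [c for c in cuts if b in c]
        if p_top == 0.0:
            fv = float("nan")
        else:
            num = _cut_union_probability(mine, probs, n_samples, seed)
            fv = min(num / p_top, 1.0)
        rows.append({"event_id": b, "fussell_vesely": fv})
    df = pd.DataFrame(rows).sort_values(
        ["fussell_vesely", "event_id"], ascending=[False, True], ignore_index=True
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def importance_report(
    tree: FaultTree,
    probs: ProbabilityAssignment,
    group: str | None = None,
    method: str = "auto",
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
) -> pd.DataFrame:
    """Both importance measures in one table (sorted by Birnbaum)."""
    bir = birnbaum_importance(tree, probs, group, method, n_samples, seed)
    fv = fussell_vesely_importance(tree, probs, group, method, n_samples, seed)
    return bir.drop(columns="rank").merge(
        fv.drop(columns="rank"), on="event_id", how="outer"
    ).sort_values(["birnbaum", "event_id"], ascending=[False, True], ignore_index=True)


def mitigation_delta(
    tree: FaultTree,
    probs: ProbabilityAssignment,
    intervention: Mapping[str, float],
    group: str | None = None,
    method: str = "auto",
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
) -> dict:
    """Effect of an intervention: baseline minus mitigated top probability.

    Both runs share method and seed, so for Monte Carlo the comparison uses
    common random numbers.  In a monotone (AND/OR) tree, lowering failure
    probabilities never increases the top probability, so delta >= 0.
    """
    base = top_event_probability(tree, probs, group, method, n_samples, seed)
    mitigated = top_event_probability(
        tree, probs.replacing(intervention), group, base.method, n_samples, seed
    )
    return {
        "baseline": base.estimate,
        "mitigated": mitigated.estimate,
        "delta": base.estimate - mitigated.estimate,
        "method": base.method,
    }
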