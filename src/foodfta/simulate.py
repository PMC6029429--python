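"""Monte-Carlo hazard simulation: synthetic scenario timelines and
distributions of resilience outcomes.

A hazard strikes once at t=0: each covered basic event fails with its
onset probability and, if failed, recovers after a random number of time
steps drawn from its recovery distribution (``fixed``, ``geometric`` with
support 1,2,... and mean 1/p, or ``lognormal`` discretized by ceiling).
Draws use inverse-transform sampling from per-event uniforms in a fixed
event order, so two hazards compared under the same seed share common
random numbers — useful for intervention what-ifs.

Per-run seeds are derived from the master seed by a counter-based scheme
(``numpy.random.SeedSequence([seed, run_index])``), making every run
independently reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .model import FaultTree, FaultTreeError
from .resilience import (
    evaluate_timeline,
    functionality_curve,
    population_weighted_curve,
    resilience_index,
)
from .scenario import ScenarioTimeline

__all__ = [
    "RecoveryDist",
    "EventHazard",
    "HazardSpec",
    "SimulationSummary",
    "sample_scenario",
    "simulate_resilience_distribution",
    "load_hazard",
]


@dataclass(frozen=True)
class RecoveryDist:
    """Recovery-duration distribution, in whole time steps >= 1."""

    kind: str  # "fixed" | "geometric" | "lognormal"
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "params", dict(self.params))
        if self.kind == "fixed":
            steps = self.params.get("steps")
            if steps is None or steps < 1 or int(steps) != steps:
                raise FaultTreeError(f"fixed recovery requires integer steps >= 1, got {steps}")
        elif self.kind == "geometric":
            p = self.params.get("p")
            if p is None or not (0.0 < p <= 1.0):
                raise FaultTreeError(f"geometric recovery requires p in (0,1], got {p}")
        elif self.kind == "lognormal":
            if "mu" not in self.params or "sigma" not in self.params:
                raise FaultTreeError("lognormal recovery requires mu and sigma")
            if self.params["sigma"] < 0:
                raise FaultTreeError("lognormal sigma must be >= 0")
        else:
            raise FaultTreeError(f"unknown recovery distribution: {self.kind!r}")

    def draw(self, u: float) -> int:
        """Inverse-transform a uniform u in [0,1) into a duration >= 1."""
        if self.kind == "fixed":
            return int(self.params["steps"])
        if self.kind == "geometric":
            p = self.params["p"]
            if p == 1.0:
                return 1
            # inverse CDF of the geometric on {1,2,...}: ceil(log(1-u)/log(1-p))
            return max(1, math.ceil(math.log1p(-u) / math.log1p(-p)))
        mu, sigma = self.params["mu"], self.params["sigma"]
        from scipy.stats import norm  # lazy; scipy only needed for lognormal

        z = norm.ppf(min(max(u, 1e-12), 1 - 1e-12))
        return max(1, math.ceil(math.exp(mu + sigma * z)))

    @property
    def mean(self) -> float:
        if self.kind == "fixed":
            return float(self.params["steps"])
        if self.kind == "geometric":
            return 1.0 / self.params["p"]
        return float("nan")  # discretized lognormal mean has no simple closed form


@dataclass(frozen=True)
class EventHazard:
    fail_prob: float
    recovery: RecoveryDist

    def __post_init__(self):
        if not (0.0 <= self.fail_prob <= 1.0):
            raise FaultTreeError(f"fail_prob outside [0,1]: {self.fail_prob}")


@dataclass
class HazardSpec:
    events: dict[str, EventHazard]
    horizon: int  # number of time steps after onset
    time_unit: str = "hours"

    def __post_init__(self):
        if self.horizon < 1:
            raise FaultTreeError(f"horizon must be >= 1, got {self.horizon}")


def load_hazard(source: str | Path | Mapping) -> HazardSpec:
    """Load a hazard specification from YAML/JSON text, a path, or a mapping."""
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        raw = yaml.safe_load(Path(source).read_text())
    elif isinstance(source, str):
        raw = yaml.safe_load(source)
    else:
        raw = source
    events = {}
    for ev_id, spec in (raw.get("events") or {}).items():
        rec = spec.get("recovery") or {"kind": "fixed", "steps": 1}
        params = {k: v for k, v in rec.items() if k != "kind"}
        events[ev_id] = EventHazard(
            fail_prob=float(spec["fail_prob"]),
            recovery=RecoveryDist(kind=rec["kind"], params=params),
        )
    return HazardSpec(events=events, horizon=int(raw["horizon"]),
                      time_unit=raw.get("time_unit", "hours"))


def sample_scenario(tree: FaultTree, hazard: HazardSpec, seed: int = 0) -> ScenarioTimeline:
    """Draw one synthetic scenario: onset failures at t=0 plus recoveries.

    Each covered event consumes exactly two uniforms (failure, recovery) in
    sorted event order regardless of outcome, so scenarios under different
    hazard parameters but the same seed are coupled.  Recoveries past the
    horizon leave the event failed through the end ("not recovered").
    """
    basics = {e.id for e in tree.basic_events()}
    unknown = set(hazard.events) - basics
    if unknown:
        raise FaultTreeError("hazard covers unknown basic events: " + ", ".join(sorted(unknown)))
    rng = np.random.default_rng(seed)
    times = np.arange(hazard.horizon + 1, dtype=float)
    states: dict[str, np.ndarray] = {}
    for ev_id in sorted(hazard.events):
        h = hazard.events[ev_id]
        u_fail, u_rec = rng.random(), rng.random()
        series = np.zeros(len(times), dtype=bool)
        if u_fail < h.fail_prob:
            duration = h.recovery.draw(u_rec)
            series[: min(duration, len(times))] = True
        states[ev_id] = series
    return ScenarioTimeline(
        time_unit=hazard.time_unit,
        t0_label="hazard onset",
        times=times,
        states=states,
    )


@dataclass
class SimulationSummary:
    mean: float
    sd: float
    q05: float
    q50: float
    q95: float
    runs: np.ndarray
    contributions: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "mean_resilience": self.mean,
            "sd": self.sd,
            "quantiles": {"q05": self.q05, "q50": self.q50, "q95": self.q95},
            "n_runs": int(len(self.runs)),
            "contributions": self.contributions.to_dict(orient="records"),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _run_seed(seed: int, run: int) -> int:
    return int(np.random.SeedSequence([seed, run]).generate_state(1)[0] & 0x7FFFFFFF)


def simulate_resilience_distribution(
    tree: FaultTree,
    hazard: HazardSpec,
    n_runs: int,
    seed: int = 0,
    group: str | None = None,
    population_weighted: bool = False,
) -> SimulationSummary:
    """Distribution of the resilience index under repeated hazard draws.

    Each run samples a scenario, replays it through the tree (uncovered
    basics default to operational), and scores the top event's
    functionality curve over the full horizon.  The contribution table
    splits runs by whether each event failed at onset and reports the mean
    loss of R associated with its failure (observational, not causal).
    """
    if n_runs < 1:
        raise FaultTreeError("n_runs must be >= 1")
    top = tree.top_event.id
    r_values = np.empty(n_runs)
    failed_at_onset = {ev: np.zeros(n_runs, dtype=bool) for ev in sorted(hazard.events)}
    for run in range(n_runs):
        scn = sample_scenario(tree, hazard, seed=_run_seed(seed, run))
        if population_weighted:
            per_group = {
                g: evaluate_timeline(tree, scn, group=g, default_operational=True)[top]
                for g in tree.groups
            }
            curve = population_weighted_curve(
                scn.times, per_group,
                {g: grp.weight for g, grp in tree.groups.items()}, top,
            )
        else:
            failed = evaluate_timeline(tree, scn, group=group, default_operational=True)[top]
            curve = functionality_curve(scn.times, failed, top,
                                        group=group or "default")
        r_values[run] = resilience_index(curve)
        for ev in failed_at_onset:
            failed_at_onset[ev][run] = bool(scn.states[ev][0])

    rows = []
    for ev, mask in failed_at_onset.items():
        mean_failed = float(r_values[mask].mean()) if mask.any() else float("nan")
        mean_ok = float(r_values[~mask].mean()) if (~mask).any() else float("nan")
        rows.append({
            "event_id": ev,
            "n_failed": int(mask.sum()),
            "mean_r_when_failed": mean_failed,
            "mean_r_when_operational": mean_ok,
            "delta_r": mean_ok - mean_failed,
        })
    contributions = pd.DataFrame(rows)
    return SimulationSummary(
        mean=float(r_values.mean()),
        sd=float(r_values.std(ddof=0)),
        q05=float(np.quantile(r_values, 0.05)),
        q50=float(np.quantile(r_values, 0.50)),
        q95=float(np.quantile(r_values, 0.95)),
        runs=r_values,
        contributions=contributions,
    )
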