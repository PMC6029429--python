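"""Scenario timelines: time-indexed basic-event states and indicator values.

A scenario describes a hazard and its recovery as right-continuous step
series: each basic event carries either a Boolean state series (1 = failed)
or a numeric indicator series in the units of the event's indicator spec.
Values hold from each observation time until the next (zero-order hold).

On disk a scenario is a CSV whose first column is ``time`` (numeric, in the
scenario's time unit) and whose remaining columns are tagged per event:
``state:<event_id>``, ``indicator:<units>:<event_id>``, or
``affected:<event_id>``; a companion JSON header carries the time unit, the
t0 label, and nominal indicator values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import FaultTreeError

__all__ = ["ScenarioTimeline", "read_scenario", "write_scenario"]


@dataclass
class ScenarioTimeline:
    time_unit: str  # "hours" | "days" | "months"
    t0_label: str
    times: np.ndarray
    states: dict[str, np.ndarray] = field(default_factory=dict)
    indicators: dict[str, np.ndarray] = field(default_factory=dict)
    affected: dict[str, np.ndarray] = field(default_factory=dict)
    nominal: dict[str, float] = field(default_factory=dict)
    indicator_units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise FaultTreeError("scenario times must be strictly increasing")
        n = len(self.times)
        self.states = {k: np.asarray(v, dtype=bool) for k, v in self.states.items()}
        self.indicators = {k: np.asarray(v, dtype=float) for k, v in self.indicators.items()}
        self.affected = {k: np.asarray(v, dtype=float) for k, v in self.affected.items()}
        for name, series in {**self.states, **self.indicators, **self.affected}.items():
            if len(series) != n:
                raise FaultTreeError(
                    f"series {name!r} has {len(series)} points, expected {n}"
                )
        for name, series in self.indicators.items():
            if not np.all(np.isfinite(series)):
                raise FaultTreeError(f"non-finite indicator values in series {name!r}")
        overlap = set(self.states) & set(self.indicators)
        if overlap:
            raise FaultTreeError(
                "events with both state and indicator series: " + ", ".join(sorted(overlap))
            )

    def events(self) -> list[str]:
        return sorted(set(self.states) | set(self.indicators))

    def nominal_value(self, event_id: str) -> float:
        """Declared nominal indicator value (default: first observation)."""
        if event_id in self.nominal:
            return float(self.nominal[event_id])
        return float(self.indicators[event_id][0])

    def value_at(self, event_id: str, t: float):
        """Step (right-continuous) lookup of a series at time ``t``."""
        series = self.states.get(event_id)
        if series is None:
            series = self.indicators[event_id]
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        if idx < 0:
            raise FaultTreeError(f"time {t} precedes the scenario start")
        return series[idx]


def write_scenario(scenario: ScenarioTimeline, csv_path: str | Path) -> Path:
    """Write the scenario CSV plus its companion JSON header.

    Returns the header path (``<csv stem>.json`` next to the CSV).
    """
    csv_path = Path(csv_path)
    data: dict[str, np.ndarray] = {"time": scenario.times}
    for ev in sorted(scenario.states):
        data[f"state:{ev}"] = scenario.states[ev].astype(int)
    for ev in sorted(scenario.indicators):
        units = scenario.indicator_units.get(ev, "value")
        data[f"indicator:{units}:{ev}"] = scenario.indicators[ev]
    for ev in sorted(scenario.affected):
        data[f"affected:{ev}"] = scenario.affected[ev]
    pd.DataFrame(data).to_csv(csv_path, index=False)
    header = {
        "time_unit": scenario.time_unit,
        "t0_label": scenario.t0_label,
        "nominal": scenario.nominal,
    }
    header_path = csv_path.with_suffix(".json")
    header_path.write_text(json.dumps(header, indent=2, sort_keys=True) + "\n")
    return header_path


def read_scenario(csv_path: str | Path, header_path: str | Path | None = None) -> ScenarioTimeline:
    """Read a scenario CSV (and its JSON header when present)."""
    csv_path = Path(csv_path)
    if header_path is None:
        header_path = csv_path.with_suffix(".json")
    header = {}
    if Path(header_path).exists():
        header = json.loads(Path(header_path).read_text())
    df = pd.read_csv(csv_path)
    if "time" not in df.columns:
        raise FaultTreeError("scenario CSV must have a 'time' column")
    states, indicators, affected, units = {}, {}, {}, {}
    for col in df.columns:
        if col == "time":
            continue
        parts = col.split(":")
        if parts[0] == "state" and len(parts) == 2:
            states[parts[1]] = df[col].to_numpy(dtype=bool)
        elif parts[0] == "indicator" and len(parts) == 3:
            indicators[parts[2]] = df[col].to_numpy(dtype=float)
            units[parts[2]] = parts[1]
        elif parts[0] == "affected" and len(parts) == 2:
            affected[parts[1]] = df[col].to_numpy(dtype=float)
        else:
            raise FaultTreeError(f"unrecognized scenario column tag: {col!r}")
    return ScenarioTimeline(
        time_unit=header.get("time_unit", "hours"),
        t0_label=header.get("t0_label", "t0"),
        times=df["time"].to_numpy(dtype=float),
        states=states,
        indicators=indicators,
        affected=affected,
        nominal={k: float(v) for k, v in (header.get("nominal") or {}).items()},
        indicator_units=units,
    )
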