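"""Shipped model data and synthetic test-surface generators.

``load_food_system_tree`` returns the community food-system fault tree:
one top event ("food system failure") decomposed through accessibility,
availability and acceptability branches into 12 subtrees and two
population groups (general / donation-reliant).  Events carry a provenance
record (``provenance_table``) distinguishing text-attested events from
clearly flagged placeholders that complete subtree interiors the source
narrative leaves undescribed.

Two case-study scenario timelines ship alongside: an acute winter-storm
blizzard (hourly road-obstruction, transit and delivery series) and a
chronic multi-year drought (monthly water, farm-count and yield series).
``generate_random_tree`` produces seeded random AND/OR trees for
property-based testing.
"""

from __future__ import annotations

import random
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .model import EventNode, FaultTree, Gate, Subtree, parse_tree
from .scenario import ScenarioTimeline, read_scenario

__all__ = [
    "load_food_system_tree",
    "provenance_table",
    "jonas_scenario",
    "drought_scenario",
    "generate_random_tree",
    "data_path",
]


def data_path(name: str) -> Path:
    """Filesystem path of a shipped data file."""
    return Path(str(resources.files("foodfta").joinpath("data", name)))


def load_food_system_tree() -> FaultTree:
    """The community food-system fault tree (12 subtrees, 2 groups).

    Indicator thresholds are illustrative defaults (flagged in the tree
    metadata); placeholder events default to operational in the shipped
    scenarios.
    """
    return parse_tree(data_path("food_system_tree.yaml").read_text())


def provenance_table() -> pd.DataFrame:
    """Per-event provenance: attestation (text_attested|placeholder) + citation."""
    return pd.read_csv(data_path("provenance.csv"))


def jonas_scenario() -> ScenarioTimeline:
    """Acute blizzard scenario, hourly, t=0 at storm end, spanning -48..240 h.

    Covers road obstruction (1.00 at t=0, stepping to the 0.15 midpoint of
    the reported "80-90% passable" range at day 5, clear from 216 h),
    transit service (full shutdown through the 2-day storm, then a 96-h
    graded restoration), and delivery-truck access (blocked while side
    streets remain uncleared).  Values between anchors are stepwise
    constant — an encoding convention, not interpolated ground truth.
    """
    return read_scenario(data_path("jonas_scenario.csv"))


def drought_scenario(price_spike_variant: bool = False) -> ScenarioTimeline:
    """Chronic drought scenario, monthly, spanning a five-year period.

    During the declared-emergency window (months 12-50) the "decreased
    water" indicator exceeds its threshold and the extreme-weather basic
    event is failed, while the farm-count and seasonal-yield indicators
    stay below their thresholds throughout — so resource depletion and
    productivity decreases trigger but farm business failure, single season
    failure, and the community-level top event do not.

    ``price_spike_variant=True`` additionally fails the supply-chain cost
    basic event during the window, encoding the documented reading that
    food prices would react before production fails outright (the
    high-food-prices subtree fails while the production subtree stays
    operational).
    """
    scn = read_scenario(data_path("drought_scenario.csv"))
    if price_spike_variant:
        window = (scn.times >= 12) & (scn.times < 51)
        scn.states["supply_chain_cost_increase"] = window.astype(bool)
    return scn


# ---------------------------------------------------------------------------
# random tree generation


def generate_random_tree(
    n_basic: int,
    max_depth: int,
    and_fraction: float = 0.5,
    seed: int = 0,
) -> FaultTree:
    """Random valid AND/OR tree with exactly ``n_basic`` basic events.

    Gate depth never exceeds ``max_depth``; each gate's type is AND with
    probability ``and_fraction``; identical seeds yield identical trees.
    """
    if n_basic < 1:
        raise ValueError(f"n_basic must be >= 1, got {n_basic}")
    if max_depth < 1:
        raise ValueError(f"max_depth must be >= 1, got {max_depth}")
    rng = random.Random(seed)

    basics = [f"b{i}" for i in range(1, n_basic + 1)]
    events: list[EventNode] = [
        EventNode(id=b, label=f"basic event {b}", kind="basic", subtree_id="main")
        for b in basics
    ]
    counter = iter(range(1, 10_000))

    def gate_type() -> str:
        return "and" if rng.random() < and_fraction else "or"

    def gate_inputs(ids: list[str], levels_below: int) -> list[str]:
        """Inputs covering exactly ``ids``; may create intermediates."""
        if levels_below == 0 or len(ids) == 1:
            return list(ids)
        shuffled = rng.sample(ids, len(ids))
        k = rng.randint(1, min(3, len(ids)))
        # k split points -> k+1 contiguous parts (some may be empty; drop them)
        cuts = sorted(rng.sample(range(1, len(ids)), min(k, len(ids) - 1)))
        parts, prev = [], 0
        for c in cuts + [len(ids)]:
            if c > prev:
                parts.append(shuffled[prev:c])
                prev = c
        refs: list[str] = []
        for part in parts:
            if len(part) == 1 or rng.random() < 0.3:
                refs.extend(part)
            else:
                gid = f"g{next(counter)}"
                events.append(
                    EventNode(
                        id=gid, label=f"intermediate {gid}", kind="intermediate",
                        subtree_id="main",
                        gate=Gate(type=gate_type(),
                                  inputs=tuple(gate_inputs(part, levels_below - 1))),
                    )
                )
                refs.append(gid)
        return refs

    top_inputs = gate_inputs(basics, max_depth - 1)
    events.append(
        EventNode(
            id="top", label="system failure", kind="top", subtree_id="main",
            gate=Gate(type=gate_type(), inputs=tuple(top_inputs)),
        )
    )
    return FaultTree(
        id=f"random_{seed}",
        title="randomly generated test tree",
        version="1",
        events=events,
        subtrees=[Subtree(id="main", title="main", top_event_id="top")],
    )


def random_probabilities(tree: FaultTree, seed: int = 0) -> dict[str, float]:
    """Seeded uniform failure probabilities for every basic event."""
    rng = np.random.default_rng(seed)
    basics = sorted(e.id for e in tree.basic_events())
    return {b: float(p) for b, p in zip(basics, rng.random(len(basics)))}
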