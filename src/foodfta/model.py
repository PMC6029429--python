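"""Fault-tree domain model: events, gates, trees, validation and serialization.

A fault tree decomposes an undesired *top event* (here: failure of a
community food system) through AND/OR logic gates into intermediate events
and ultimately *basic events* — elementary component failures such as
"roads are obstructed".  Trees are partitioned into subtrees; a gate input
written as ``subtree:<id>`` is a *transfer reference* that substitutes the
top event of another subtree, so shared subsystems appear as genuinely
repeated events.

Gates may carry per-population-group overrides: the same structural gate
can combine its inputs with OR for one subpopulation (e.g. people who rely
on donated food, for whom failure of *either* the supply chain or the
donation system leaves them without food) and AND for the rest.

Basic events may be backed by a quantitative indicator with a failure
threshold, plus an optional "fraction of population affected" threshold —
an indicator crossing alone only counts as a system failure when enough
people are affected.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import yaml

__all__ = [
    "EventNode",
    "Gate",
    "TransferRef",
    "IndicatorSpec",
    "PopulationGroup",
    "Subtree",
    "FaultTree",
    "ValidationReport",
    "Finding",
    "FaultTreeError",
    "TreeParseError",
    "DuplicateIdError",
    "CycleError",
    "UnknownReferenceError",
    "ValidationFailedError",
    "parse_tree",
    "load_tree",
    "validate_tree",
    "serialize_tree",
    "save_tree",
    "export_dot",
]

_ID_RE = re.compile(r"^[a-z0-9_]+$")
_WEIGHT_TOL = 1e-9


# ---------------------------------------------------------------------------
# errors


class FaultTreeError(Exception):
    """Base class for all fault-tree errors."""


class TreeParseError(FaultTreeError):
    """Document does not conform to the tree schema; ``path`` names the spot."""

    def __init__(self, message: str, path: str = "$"):
        super().__init__(f"{path}: {message}")
        self.path = path


class DuplicateIdError(FaultTreeError):
    pass


class CycleError(FaultTreeError):
    """The gate-input relation (after transfer resolution) contains a cycle."""

    def __init__(self, cycle: Sequence[str]):
        super().__init__("cycle in gate-input relation: " + " -> ".join(cycle))
        self.cycle = list(cycle)


class UnknownReferenceError(FaultTreeError):
    pass


class ValidationFailedError(FaultTreeError):
    """Raised when an operation requires a valid tree; carries the report."""

    def __init__(self, report: "ValidationReport"):
        msgs = "; ".join(f"[{f.code}] {f.location}: {f.message}" for f in report.errors)
        super().__init__(f"tree failed validation: {msgs}")
        self.report = report


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class TransferRef:
    """Gate input that substitutes the top event of another subtree."""

    subtree_id: str

    def __str__(self) -> str:  # serialized form
        return f"subtree:{self.subtree_id}"


@dataclass(frozen=True)
class IndicatorSpec:
    """Quantitative indicator backing a basic event.

    The event is failed when the observed value crosses ``threshold`` in the
    ``fail_when`` direction (inclusive), and — when both are supplied — the
    fraction of the population affected reaches
    ``population_fraction_threshold``.
    """

    name: str
    units: str
    fail_when: str  # "ge" | "le"
    threshold: float
    population_fraction_threshold: float | None = None


@dataclass(frozen=True)
class Gate:
    """AND/OR combinator with optional per-population-group overrides."""

    type: str  # "and" | "or"
    inputs: tuple[str | TransferRef, ...]
    overrides: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "inputs", tuple(self.inputs))
        object.__setattr__(self, "overrides", dict(self.overrides))

    def __eq__(self, other):
        if not isinstance(other, Gate):
            return NotImplemented
        return (
            self.type == other.type
            and self.inputs == other.inputs
            and dict(self.overrides) == dict(other.overrides)
        )

    def __hash__(self):
        return hash((self.type, self.inputs, tuple(sorted(self.overrides.items()))))


@dataclass(frozen=True)
class EventNode:
    """One failure event: basic (leaf), intermediate, or the single top."""

    id: str
    label: str
    kind: str  # "basic" | "intermediate" | "top"
    subtree_id: str
    gate: Gate | None = None
    indicator: IndicatorSpec | None = None
    citation: str = ""

    @property
    def is_basic(self) -> bool:
        return self.kind == "basic"


@dataclass(frozen=True)
class PopulationGroup:
    """Subpopulation for which gate logic may differ; weights sum to 1."""

    id: str
    description: str
    weight: float


@dataclass(frozen=True)
class Subtree:
    id: str
    title: str
    top_event_id: str


@dataclass(frozen=True)
class Finding:
    code: str
    message: str
    location: str


@dataclass
class ValidationReport:
    errors: list[Finding] = field(default_factory=list)
    warnings: list[Finding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def sort(self) -> "ValidationReport":
        key = lambda f: (f.location, f.code, f.message)
        self.errors.sort(key=key)
        self.warnings.sort(key=key)
        return self


class FaultTree:
    """Validated-on-demand DAG of failure events partitioned into subtrees."""

    def __init__(
        self,
        id: str,
        title: str = "",
        version: str = "0",
        events: Iterable[EventNode] = (),
        subtrees: Iterable[Subtree] = (),
        groups: Iterable[PopulationGroup] = (),
        metadata: Mapping | None = None,
    ):
        self.id = id
        self.title = title
        self.version = version
        self.events: dict[str, EventNode] = {}
        for ev in events:
            if ev.id in self.events:
                raise DuplicateIdError(f"duplicate event id: {ev.id}")
            self.events[ev.id] = ev
        self.subtrees: dict[str, Subtree] = {}
        for st in subtrees:
            if st.id in self.subtrees:
                raise DuplicateIdError(f"duplicate subtree id: {st.id}")
            self.subtrees[st.id] = st
        self.groups: dict[str, PopulationGroup] = {}
        for g in groups:
            if g.id in self.groups:
                raise DuplicateIdError(f"duplicate group id: {g.id}")
            self.groups[g.id] = g
        self.metadata = dict(metadata or {})

    # -- structural helpers -------------------------------------------------

    @property
    def top_event(self) -> EventNode:
        tops = [e for e in self.events.values() if e.kind == "top"]
        if len(tops) != 1:
            raise FaultTreeError(f"expected exactly one top event, found {len(tops)}")
        return tops[0]

    def basic_events(self) -> list[EventNode]:
        return [e for e in self.events.values() if e.is_basic]

    def resolve_ref(self, ref: str | TransferRef) -> str:
        """Resolve a gate input to an event id (transfer -> subtree top)."""
        if isinstance(ref, TransferRef):
            st = self.subtrees.get(ref.subtree_id)
            if st is None:
                raise UnknownReferenceError(f"unknown subtree: {ref.subtree_id}")
            return st.top_event_id
        return ref

    def resolved_inputs(self, event: EventNode) -> list[str]:
        if event.gate is None:
            return []
        return [self.resolve_ref(r) for r in event.gate.inputs]

    def input_graph(self) -> nx.DiGraph:
        """Directed graph with an edge input -> event for every gate input."""
        g = nx.DiGraph()
        g.add_nodes_from(self.events)
        for ev in self.events.values():
            if ev.gate is not None:
                for ref in ev.gate.inputs:
                    try:
                        src = self.resolve_ref(ref)
                    except UnknownReferenceError:
                        continue  # reported by validate_tree
                    if src in self.events:
                        g.add_edge(src, ev.id)
        return g

    def topological_order(self) -> list[str]:
        """Event ids ordered so every gate input precedes its gate.

        Cached after the first call: trees are treated as immutable once
        constructed (rebuild rather than mutate in place).
        """
        cached = getattr(self, "_topo_cache", None)
        if cached is not None:
            return cached
        g = self.input_graph()
        try:
            order = list(nx.lexicographical_topological_sort(g))
        except nx.NetworkXUnfeasible:
            cyc = [u for u, _ in nx.find_cycle(g)]
            raise CycleError(cyc + [cyc[0]])
        self._topo_cache = order
        return order

    def structural_dict(self) -> dict:
        """Canonical plain-data form (used for serialization and equality)."""
        return _tree_to_dict(self)

    def __eq__(self, other):
        if not isinstance(other, FaultTree):
            return NotImplemented
        return self.structural_dict() == other.structural_dict()

    def __repr__(self):
        return (
            f"FaultTree(id={self.id!r}, events={len(self.events)}, "
            f"subtrees={len(self.subtrees)}, groups={len(self.groups)})"
        )


# ---------------------------------------------------------------------------
# validation


def validate_tree(tree: FaultTree) -> ValidationReport:
    """Check every structural invariant; violations become report entries.

    Never raises: a hand-built inconsistent tree yields a report whose
    ``ok`` is False.  Findings are deterministically ordered by location
    then code.
    """
    rep = ValidationReport()
    err = lambda code, msg, loc: rep.errors.append(Finding(code, msg, loc))
    warn = lambda code, msg, loc: rep.warnings.append(Finding(code, msg, loc))

    tops = [e.id for e in tree.events.values() if e.kind == "top"]
    if len(tops) != 1:
        err("top-count", f"expected exactly 1 top event, found {len(tops)}", "tree")

    for ev in tree.events.values():
        if ev.kind not in ("basic", "intermediate", "top"):
            err("bad-kind", f"unknown kind {ev.kind!r}", ev.id)
        if ev.is_basic and ev.gate is not None:
            err("gate-on-basic", "basic events must not carry a gate", ev.id)
        if not ev.is_basic and ev.gate is None:
            err("gate-missing", f"{ev.kind} event requires a gate", ev.id)
        if ev.indicator is not None and not ev.is_basic:
            err("indicator-on-nonbasic", "indicators attach to basic events only", ev.id)
        if ev.indicator is not None:
            ind = ev.indicator
            if not math.isfinite(ind.threshold):
                err("indicator-threshold", "threshold must be finite", ev.id)
            if ind.fail_when not in ("ge", "le"):
                err("indicator-fail-when", f"fail_when must be ge|le, got {ind.fail_when!r}", ev.id)
            pft = ind.population_fraction_threshold
            if pft is not None and not (0.0 <= pft <= 1.0):
                err("indicator-pft-range", "population_fraction_threshold must lie in [0,1]", ev.id)
        if ev.subtree_id not in tree.subtrees:
            err("unknown-subtree-id", f"event assigned to undeclared subtree {ev.subtree_id!r}", ev.id)
        if ev.gate is not None:
            if ev.gate.type not in ("and", "or"):
                err("bad-gate-type", f"gate type must be and|or, got {ev.gate.type!r}", ev.id)
            if len(ev.gate.inputs) < 1:
                err("gate-arity", "gates require at least one input", ev.id)
            for ref in ev.gate.inputs:
                if isinstance(ref, TransferRef):
                    if ref.subtree_id not in tree.subtrees:
                        err("unknown-subtree", f"transfer to undeclared subtree {ref.subtree_id!r}", ev.id)
                elif ref not in tree.events:
                    err("unknown-reference", f"gate input {ref!r} is not an event", ev.id)
            for grp, gtype in ev.gate.overrides.items():
                if grp not in tree.groups:
                    err("override-unknown-group", f"override for undeclared group {grp!r}", ev.id)
                if gtype not in ("and", "or"):
                    err("bad-gate-type", f"override type must be and|or, got {gtype!r}", ev.id)

    for st in tree.subtrees.values():
        top = tree.events.get(st.top_event_id)
        if top is None:
            err("subtree-top-missing", f"top_event_id {st.top_event_id!r} is not an event", st.id)
        elif top.subtree_id != st.id:
            err("subtree-top-outside", f"top event {top.id!r} lies in subtree {top.subtree_id!r}", st.id)

    if tree.groups:
        total = sum(g.weight for g in tree.groups.values())
        for g in tree.groups.values():
            if not (0.0 <= g.weight <= 1.0):
                err("weight-range", f"group weight {g.weight} outside [0,1]", g.id)
        if abs(total - 1.0) > _WEIGHT_TOL:
            err("weight-sum", f"group weights sum to {total}, expected 1", "tree")

    # cycle check on the resolved gate-input relation
    graph = tree.input_graph()
    if not nx.is_directed_acyclic_graph(graph):
        cyc = [u for u, _ in nx.find_cycle(graph)]
        err("cycle", "cycle: " + " -> ".join(cyc + [cyc[0]]), min(cyc))

    # reachability from the top event (warning only)
    elif len(tops) == 1:
        reachable = nx.ancestors(graph, tops[0]) | {tops[0]}
        for ev_id in tree.events:
            if ev_id not in reachable:
                warn("orphan", "event not reachable from the top event", ev_id)

    return rep.sort()


# ---------------------------------------------------------------------------
# parsing


def _expect(cond: bool, message: str, path: str):
    if not cond:
        raise TreeParseError(message, path)


def _parse_indicator(raw, path: str) -> IndicatorSpec:
    _expect(isinstance(raw, Mapping), "indicator must be a mapping", path)
    for key in ("name", "units", "fail_when", "threshold"):
        _expect(key in raw, f"indicator missing key {key!r}", path)
    pft = raw.get("population_fraction_threshold")
    return IndicatorSpec(
        name=str(raw["name"]),
        units=str(raw["units"]),
        fail_when=str(raw["fail_when"]),
        threshold=float(raw["threshold"]),
        population_fraction_threshold=None if pft is None else float(pft),
    )


def _parse_gate(raw, path: str) -> Gate:
    _expect(isinstance(raw, Mapping), "gate must be a mapping", path)
    _expect("type" in raw, "gate missing key 'type'", path)
    _expect("inputs" in raw, "gate missing key 'inputs'", path)
    _expect(isinstance(raw["inputs"], Sequence) and not isinstance(raw["inputs"], str),
            "gate inputs must be a list", path)
    inputs: list[str | TransferRef] = []
    for i, ref in enumerate(raw["inputs"]):
        _expect(isinstance(ref, str), "gate inputs must be strings", f"{path}.inputs[{i}]")
        if ref.startswith("subtree:"):
            inputs.append(TransferRef(ref.split(":", 1)[1]))
        else:
            inputs.append(ref)
    overrides = raw.get("overrides") or {}
    _expect(isinstance(overrides, Mapping), "overrides must be a mapping", path)
    return Gate(type=str(raw["type"]), inputs=tuple(inputs),
                overrides={str(k): str(v) for k, v in overrides.items()})


def _parse_event(raw, path: str) -> EventNode:
    _expect(isinstance(raw, Mapping), "event must be a mapping", path)
    for key in ("id", "label", "kind", "subtree"):
        _expect(key in raw, f"event missing key {key!r}", path)
    ev_id = str(raw["id"])
    _expect(bool(_ID_RE.match(ev_id)), f"event id {ev_id!r} is not a snake_case token", path)
    gate = _parse_gate(raw["gate"], f"{path}.gate") if raw.get("gate") is not None else None
    indicator = (
        _parse_indicator(raw["indicator"], f"{path}.indicator")
        if raw.get("indicator") is not None
        else None
    )
    return EventNode(
        id=ev_id,
        label=str(raw["label"]),
        kind=str(raw["kind"]),
        subtree_id=str(raw["subtree"]),
        gate=gate,
        indicator=indicator,
        citation=str(raw.get("citation", "")),
    )


def parse_tree(document: str | Mapping) -> FaultTree:
    """Parse a tree-definition document (YAML or JSON text, or a mapping).

    Returns a :class:`FaultTree` whose invariants all hold; structural
    problems raise typed errors (schema -> :class:`TreeParseError`,
    duplicate ids -> :class:`DuplicateIdError`, cycles ->
    :class:`CycleError`, dangling references ->
    :class:`UnknownReferenceError`, anything else ->
    :class:`ValidationFailedError`).
    """
    if isinstance(document, str):
        try:
            raw = yaml.safe_load(document)
        except yaml.YAMLError as exc:
            raise TreeParseError(f"document is not valid YAML/JSON: {exc}") from exc
    else:
        raw = document
    _expect(isinstance(raw, Mapping), "top level must be a mapping", "$")
    for key in ("id", "events"):
        _expect(key in raw, f"missing top-level key {key!r}", "$")

    events = [_parse_event(e, f"$.events[{i}]") for i, e in enumerate(raw["events"] or [])]
    subtrees = []
    for i, st in enumerate(raw.get("subtrees") or []):
        _expect(isinstance(st, Mapping), "subtree must be a mapping", f"$.subtrees[{i}]")
        for key in ("id", "top_event"):
            _expect(key in st, f"subtree missing key {key!r}", f"$.subtrees[{i}]")
        subtrees.append(Subtree(id=str(st["id"]), title=str(st.get("title", "")),
                                top_event_id=str(st["top_event"])))
    groups = []
    for i, g in enumerate(raw.get("groups") or []):
        _expect(isinstance(g, Mapping), "group must be a mapping", f"$.groups[{i}]")
        for key in ("id", "weight"):
            _expect(key in g, f"group missing key {key!r}", f"$.groups[{i}]")
        groups.append(PopulationGroup(id=str(g["id"]),
                                      description=str(g.get("description", "")),
                                      weight=float(g["weight"])))

    tree = FaultTree(
        id=str(raw["id"]),
        title=str(raw.get("title", "")),
        version=str(raw.get("version", "0")),
        events=events,
        subtrees=subtrees,
        groups=groups,
        metadata=raw.get("metadata") or {},
    )
    report = validate_tree(tree)
    if not report.ok:
        codes = {f.code for f in report.errors}
        if "cycle" in codes:
            cyc_msg = next(f for f in report.errors if f.code == "cycle")
            raise CycleError(cyc_msg.message.split(": ", 1)[1].split(" -> "))
        if codes & {"unknown-reference", "unknown-subtree"}:
            bad = [f for f in report.errors if f.code in ("unknown-reference", "unknown-subtree")]
            raise UnknownReferenceError("; ".join(f"{f.location}: {f.message}" for f in bad))
        raise ValidationFailedError(report)
    return tree


def load_tree(path: str | Path) -> FaultTree:
    """Read and parse a tree document from a file path."""
    return parse_tree(Path(path).read_text())


# ---------------------------------------------------------------------------
# serialization


def _gate_to_dict(gate: Gate) -> dict:
    d: dict = {"type": gate.type, "inputs": [str(r) for r in gate.inputs]}
    if gate.overrides:
        d["overrides"] = {k: gate.overrides[k] for k in sorted(gate.overrides)}
    return d


def _event_to_dict(ev: EventNode) -> dict:
    d: dict = {"id": ev.id, "label": ev.label, "kind": ev.kind, "subtree": ev.subtree_id}
    if ev.citation:
        d["citation"] = ev.citation
    if ev.gate is not None:
        d["gate"] = _gate_to_dict(ev.gate)
    if ev.indicator is not None:
        ind = {
            "name": ev.indicator.name,
            "units": ev.indicator.units,
            "fail_when": ev.indicator.fail_when,
            "threshold": ev.indicator.threshold,
        }
        if ev.indicator.population_fraction_threshold is not None:
            ind["population_fraction_threshold"] = ev.indicator.population_fraction_threshold
        d["indicator"] = ind
    return d


def _tree_to_dict(tree: FaultTree) -> dict:
    return {
        "id": tree.id,
        "title": tree.title,
        "version": tree.version,
        "groups": [
            {"id": g.id, "description": g.description, "weight": g.weight}
            for g in sorted(tree.groups.values(), key=lambda g: g.id)
        ],
        "subtrees": [
            {"id": s.id, "title": s.title, "top_event": s.top_event_id}
            for s in sorted(tree.subtrees.values(), key=lambda s: s.id)
        ],
        "events": [_event_to_dict(e) for e in sorted(tree.events.values(), key=lambda e: e.id)],
        "metadata": tree.metadata,
    }


def serialize_tree(tree: FaultTree) -> str:
    """Serialize to canonical JSON: sorted keys, events sorted by id.

    Two serializations of structurally equal trees are byte-identical, and
    ``parse_tree(serialize_tree(t))`` structurally equals ``t``.  Invalid
    trees are refused with the validation report attached.
    """
    report = validate_tree(tree)
    if not report.ok:
        raise ValidationFailedError(report)
    return json.dumps(_tree_to_dict(tree), indent=2, sort_keys=True) + "\n"


def save_tree(tree: FaultTree, path: str | Path) -> None:
    Path(path).write_text(serialize_tree(tree))


# ---------------------------------------------------------------------------
# DOT export

_KIND_SHAPE = {"basic": "circle", "intermediate": "box", "top": "doubleoctagon"}


def export_dot(tree: FaultTree, group: str | None = None) -> str:
    """Render the tree as Graphviz DOT text.

    One node per event (shape encodes kind), one node per gate labelled with
    its effective type for ``group`` (AND/OR), edges input -> gate -> event
    mirroring the gate-input relation.  Output is deterministic.
    """
    if group is not None and group not in tree.groups:
        raise UnknownReferenceError(f"unknown population group: {group}")
    report = validate_tree(tree)
    if not report.ok:
        raise ValidationFailedError(report)

    def q(s: str) -> str:
        return '"' + s.replace('"', r"\"") + '"'

    lines = [f"digraph {q(tree.id)} {{", "  rankdir=BT;"]
    for ev in sorted(tree.events.values(), key=lambda e: e.id):
        shape = _KIND_SHAPE[ev.kind]
        lines.append(f"  {q(ev.id)} [shape={shape}, label={q(ev.label)}];")
    for ev in sorted(tree.events.values(), key=lambda e: e.id):
        if ev.gate is None:
            continue
        eff = ev.gate.overrides.get(group, ev.gate.type) if group else ev.gate.type
        gid = f"gate_{ev.id}"
        lines.append(f"  {q(gid)} [shape=invtriangle, label={q(eff.upper())}];")
        lines.append(f"  {q(gid)} -> {q(ev.id)};")
        for ref in ev.gate.inputs:
            lines.append(f"  {q(tree.resolve_ref(ref))} -> {q(gid)};")
    lines.append("}")
    return "\n".join(lines) + "\n"
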