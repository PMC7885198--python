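"""Domain types for key-event networks and structural operations.

A key-event network (KEN) is a directed acyclic graph of key events (KEs)
joined by key event relationships (KERs), augmented with assays (linked to
events through typed measurements) and structure–activity prediction bases.
Events sit at a biological level of organization (the "swim lane") and play
a role: molecular initiating event (MIE), intermediate key event (KE) or
adverse outcome (AO).  Related events may be gathered into named key-event
groups which can be collapsed to a single node for display and reasoning at
a coarser granularity.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import networkx as nx

__all__ = [
    "StrengthLevel",
    "Grade",
    "Direction",
    "SignedStrength",
    "BALANCED",
    "OrgLevel",
    "EventRole",
    "AssayTier",
    "KeyEvent",
    "KeyEventRelationship",
    "KeyEventGroup",
    "Assay",
    "AssayEventLink",
    "PredictionLink",
    "PredictionBasis",
    "Network",
    "NetworkView",
    "Violation",
    "validate_network",
    "downstream_closure",
    "upstream_closure",
    "collapse_group",
    "expand_group",
]


# ---------------------------------------------------------------------------
# Ordered categorical scales
# ---------------------------------------------------------------------------

class StrengthLevel(enum.IntEnum):
    """Five-valued, totally ordered weight-of-evidence scale."""

    VERY_LOW = 0
    LOW = 1
    MEDIUM = 2
    HIGH = 3
    VERY_HIGH = 4

    @classmethod
    def from_text(cls, text: str) -> "StrengthLevel":
        return _STRENGTH_ALIASES[text.strip().lower().replace(" ", "_").replace("-", "_")]

    @property
    def label(self) -> str:
        return _STRENGTH_LABELS[self]


_STRENGTH_LABELS = {
    StrengthLevel.VERY_LOW: "VeryLow",
    StrengthLevel.LOW: "Low",
    StrengthLevel.MEDIUM: "Medium",
    StrengthLevel.HIGH: "High",
    StrengthLevel.VERY_HIGH: "VeryHigh",
}

_STRENGTH_ALIASES = {
    "verylow": StrengthLevel.VERY_LOW,
    "very_low": StrengthLevel.VERY_LOW,
    "vl": StrengthLevel.VERY_LOW,
    "low": StrengthLevel.LOW,
    "l": StrengthLevel.LOW,
    "medium": StrengthLevel.MEDIUM,
    "m": StrengthLevel.MEDIUM,
    "high": StrengthLevel.HIGH,
    "h": StrengthLevel.HIGH,
    "veryhigh": StrengthLevel.VERY_HIGH,
    "very_high": StrengthLevel.VERY_HIGH,
    "vh": StrengthLevel.VERY_HIGH,
}


class Grade(enum.IntEnum):
    """Three-valued grade used for both the convincingness of an argument
    and the reliability/consistency of the evidence behind it."""

    SMALL = 0
    MEDIUM = 1
    LARGE = 2

    @classmethod
    def from_text(cls, text: str) -> "Grade":
        return cls[text.strip().upper()]

    @property
    def label(self) -> str:
        return self.name.capitalize()


class Direction(enum.Enum):
    FOR = "For"
    AGAINST = "Against"
    NONE = "None"


@dataclass(frozen=True)
class SignedStrength:
    """A strength with a direction: the conclusion carrier.

    The carrier set has exactly 11 members: five For levels, five Against
    levels and the Balanced point (``magnitude is None``, direction NONE).
    """

    magnitude: StrengthLevel | None
    direction: Direction

    def __post_init__(self) -> None:
        if (self.magnitude is None) != (self.direction is Direction.NONE):
            raise ValueError("direction NONE iff magnitude is Balanced (None)")

    @property
    def balanced(self) -> bool:
        return self.magnitude is None

    def negate(self) -> "SignedStrength":
        if self.balanced:
            return self
        flip = Direction.AGAINST if self.direction is Direction.FOR else Direction.FOR
        return SignedStrength(self.magnitude, flip)

    def __str__(self) -> str:
        if self.balanced:
            return "Balanced"
        sign = "+" if self.direction is Direction.FOR else "-"
        return f"{sign}{self.magnitude.label}"

    @classmethod
    def carrier(cls) -> list["SignedStrength"]:
        """All 11 values, ascending from Against/VeryHigh to For/VeryHigh."""
        against = [cls(m, Direction.AGAINST) for m in reversed(StrengthLevel)]
        for_ = [cls(m, Direction.FOR) for m in StrengthLevel]
        return against + [BALANCED] + for_


BALANCED = SignedStrength(None, Direction.NONE)


class OrgLevel(enum.Enum):
    """Biological level of organization (the swim lane of an event)."""

    MOLECULAR = "molecular"
    CELLULAR = "cellular"
    TISSUE = "tissue"
    ORGAN = "organ"
    INDIVIDUAL = "individual"
    POPULATION = "population"


class EventRole(enum.Enum):
    MIE = "MIE"
    KE = "KE"
    AO = "AO"


class AssayTier(enum.Enum):
    HUMAN_OBSERVATION = "human_observation"
    IN_VIVO = "in_vivo"
    IN_VITRO = "in_vitro"
    IN_CHEMICO = "in_chemico"
    IN_SILICO = "in_silico"


# ---------------------------------------------------------------------------
# Network entities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KeyEvent:
    id: str
    name: str
    level: OrgLevel
    role: EventRole
    group_id: str | None = None


@dataclass(frozen=True)
class KeyEventRelationship:
    """Directed causal edge between two events with an innate weight of
    evidence (drawn as arrow thickness)."""

    upstream: str
    downstream: str
    strength: StrengthLevel


@dataclass(frozen=True)
class KeyEventGroup:
    """A named, collapsible cluster of events.  A member may itself be a
    group id, allowing nesting."""

    id: str
    name: str
    members: frozenset[str]


@dataclass(frozen=True)
class Assay:
    id: str
    name: str
    reliability: Grade
    tier: AssayTier
    measurements: tuple[str, ...]


@dataclass(frozen=True)
class AssayEventLink:
    """One measurement of one assay reporting for one event."""

    assay_id: str
    measurement_id: str
    event_id: str
    convincingness: Grade


@dataclass(frozen=True)
class PredictionLink:
    """A prediction–event (or -assay/-AO) relationship.  Both grades are
    carried so the relationship's own strength can be derived."""

    target_kind: str  # "event" | "assay" | "ao"
    target_id: str
    convincingness: Grade
    reliability: Grade = Grade.LARGE


@dataclass(frozen=True)
class PredictionBasis:
    """One basis for prediction of a SAR model (typically a structural
    alert).  Semantics are asymmetric: an absent basis is not a negative
    prediction unless the model emits explicit negatives."""

    model_id: str
    basis_id: str
    convincingness: Grade
    reliability: Grade
    links: tuple[PredictionLink, ...]

    @property
    def key(self) -> tuple[str, str]:
        return (self.model_id, self.basis_id)


@dataclass
class Network:
    """A key-event network with its assay and prediction knowledge."""

    events: dict[str, KeyEvent] = field(default_factory=dict)
    kers: list[KeyEventRelationship] = field(default_factory=list)
    groups: dict[str, KeyEventGroup] = field(default_factory=dict)
    assays: dict[str, Assay] = field(default_factory=dict)
    assay_event_links: list[AssayEventLink] = field(default_factory=list)
    prediction_bases: list[PredictionBasis] = field(default_factory=list)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.events)
        for ker in self.kers:
            g.add_edge(ker.upstream, ker.downstream, strength=ker.strength)
        return g

    def links_for_event(self, event_id: str) -> list[AssayEventLink]:
        return [l for l in self.assay_event_links if l.event_id == event_id]

    def links_for_assay(self, assay_id: str) -> list[AssayEventLink]:
        return [l for l in self.assay_event_links if l.assay_id == assay_id]

    def aos(self) -> set[str]:
        return {e.id for e in self.events.values() if e.role is EventRole.AO}


@dataclass(frozen=True)
class Violation:
    code: str
    message: str
    location: str = ""


def validate_network(net: Network) -> list[Violation]:
    """Check all structural invariants; violations are returned, not raised."""
    out: list[Violation] = []
    for eid, ev in net.events.items():
        if eid != ev.id:
            out.append(Violation("id-mismatch", f"event keyed {eid} has id {ev.id}", eid))
        if not isinstance(ev.level, OrgLevel):
            out.append(Violation("unknown-level", f"event {eid} has unknown level {ev.level!r}", eid))
        if not isinstance(ev.role, EventRole):
            out.append(Violation("unknown-role", f"event {eid} has unknown role {ev.role!r}", eid))
        if ev.group_id is not None and ev.group_id not in net.groups:
            out.append(Violation("dangling-group", f"event {eid} references group {ev.group_id}", eid))

    seen_edges: set[tuple[str, str]] = set()
    for ker in net.kers:
        loc = f"{ker.upstream}->{ker.downstream}"
        if ker.upstream == ker.downstream:
            out.append(Violation("self-loop", f"KER {loc} is a self-loop", loc))
            continue
        for end in (ker.upstream, ker.downstream):
            if end not in net.events:
                out.append(Violation("dangling-ker", f"KER {loc} references unknown event {end}", loc))
        if (ker.upstream, ker.downstream) in seen_edges:
            out.append(Violation("duplicate-ker", f"KER {loc} appears more than once", loc))
        seen_edges.add((ker.upstream, ker.downstream))

    g = nx.DiGraph(seen_edges)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        path = "->".join(u for u, _ in cycle) + "->" + cycle[-1][1]
        out.append(Violation("cycle", f"KERs contain a cycle: {path}", path))

    known = set(net.events) | set(net.groups)
    for gid, grp in net.groups.items():
        if not grp.members:
            out.append(Violation("empty-group", f"group {gid} has no members", gid))
        for m in grp.members:
            if m not in known:
                out.append(Violation("dangling-member", f"group {gid} member {m} unknown", gid))

    for assay in net.assays.values():
        if len(set(assay.measurements)) != len(assay.measurements):
            out.append(Violation("duplicate-measurement", f"assay {assay.id} repeats a measurement id", assay.id))

    seen_links: set[tuple[str, str, str]] = set()
    for link in net.assay_event_links:
        loc = f"{link.assay_id}/{link.measurement_id}->{link.event_id}"
        assay = net.assays.get(link.assay_id)
        if assay is None:
            out.append(Violation("dangling-link", f"link {loc} references unknown assay", loc))
        elif link.measurement_id not in assay.measurements:
            out.append(Violation("unknown-measurement", f"link {loc} uses undeclared measurement", loc))
        if link.event_id not in net.events:
            out.append(Violation("dangling-link", f"link {loc} references unknown event", loc))
        key = (link.assay_id, link.measurement_id, link.event_id)
        if key in seen_links:
            out.append(Violation("duplicate-link", f"link {loc} appears more than once", loc))
        seen_links.add(key)

    for basis in net.prediction_bases:
        for pl in basis.links:
            loc = f"{basis.model_id}:{basis.basis_id}->{pl.target_id}"
            if pl.target_kind in ("event", "ao"):
                if pl.target_id not in net.events:
                    out.append(Violation("dangling-prediction", f"prediction link {loc} targets unknown event", loc))
            elif pl.target_kind == "assay":
                if pl.target_id not in net.assays:
                    out.append(Violation("dangling-prediction", f"prediction link {loc} targets unknown assay", loc))
            else:
                out.append(Violation("unknown-target-kind", f"prediction link {loc} has kind {pl.target_kind!r}", loc))
    return out


# ---------------------------------------------------------------------------
# Closures
# ---------------------------------------------------------------------------

def downstream_closure(net: Network, event_id: str) -> set[str]:
    """All events reachable from ``event_id`` via KERs, excluding itself."""
    if event_id not in net.events:
        raise KeyError(f"unknown event id {event_id!r}")
    return set(nx.descendants(net.graph(), event_id))


def upstream_closure(net: Network, event_id: str) -> set[str]:
    """All events from which ``event_id`` is reachable, excluding itself."""
    if event_id not in net.events:
        raise KeyError(f"unknown event id {event_id!r}")
    return set(nx.ancestors(net.graph(), event_id))


# ---------------------------------------------------------------------------
# Group collapse / expand
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ViewNode:
    id: str
    name: str
    level: OrgLevel | None
    role: EventRole | None
    is_group: bool


@dataclass
class NetworkView:
    """A display of a network with a subset of its groups collapsed.

    The view is derived functionally from the base network and the set of
    collapsed group ids, so expand(collapse(net, g), g) restores the
    original node and edge sets exactly.
    """

    network: Network
    collapsed: frozenset[str] = frozenset()

    def _home(self, event_id: str) -> str:
        """Map a leaf event to the node representing it in this view."""
        gid = self._parent_group(event_id)
        seen = set()
        home = event_id
        # walk up the (acyclic) group-nesting chain; the outermost collapsed
        # group wins
        while gid is not None and gid not in seen:
            seen.add(gid)
            if gid in self.collapsed:
                home = gid
            gid = self._parent_group(gid)
        return home

    def _parent_group(self, member_id: str) -> str | None:
        for gid, grp in self.network.groups.items():
            if member_id in grp.members:
                return gid
        return None

    def member_events(self, group_id: str) -> set[str]:
        """Leaf events inside a group, through any nesting."""
        grp = self.network.groups[group_id]
        out: set[str] = set()
        for m in grp.members:
            if m in self.network.groups:
                out |= self.member_events(m)
            elif m in self.network.events:
                out.add(m)
        return out

    @property
    def nodes(self) -> dict[str, ViewNode]:
        out: dict[str, ViewNode] = {}
        for eid, ev in self.network.events.items():
            home = self._home(eid)
            if home == eid:
                out[eid] = ViewNode(eid, ev.name, ev.level, ev.role, False)
            elif home not in out:
                grp = self.network.groups[home]
                out[home] = ViewNode(home, grp.name, None, None, True)
        return out

    @property
    def edges(self) -> list[KeyEventRelationship]:
        """Edges with endpoints re-homed; parallel edges merged keeping the
        maximum KER strength; edges internal to a collapsed group dropped."""
        best: dict[tuple[str, str], StrengthLevel] = {}
        order: list[tuple[str, str]] = []
        for ker in self.network.kers:
            u, v = self._home(ker.upstream), self._home(ker.downstream)
            if u == v:
                continue
            if (u, v) not in best:
                best[(u, v)] = ker.strength
                order.append((u, v))
            else:
                best[(u, v)] = max(best[(u, v)], ker.strength)
        return [KeyEventRelationship(u, v, best[(u, v)]) for u, v in order]

    def collapse(self, group_id: str) -> "NetworkView":
        if group_id not in self.network.groups:
            raise KeyError(f"unknown group id {group_id!r}")
        return replace(self, collapsed=self.collapsed | {group_id})

    def expand(self, group_id: str) -> "NetworkView":
        if group_id not in self.collapsed:
            raise ValueError(f"group {group_id!r} is not collapsed in this view")
        return replace(self, collapsed=self.collapsed - {group_id})


def collapse_group(net: Network | NetworkView, group_id: str) -> NetworkView:
    """Collapse a group's member events into a single node."""
    view = net if isinstance(net, NetworkView) else NetworkView(net)
    return view.collapse(group_id)


def expand_group(view: NetworkView, group_id: str) -> NetworkView:
    """Undo a collapse; raises if the group is not currently collapsed."""
    return view.expand(group_id)
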