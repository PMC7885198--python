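"""Curation and I/O: call-vocabulary normalization, overall-call
aggregation, knowledge-file (YAML/JSON) round-trip and graph export.

The call vocabulary is three-valued: Positive, Negative, Conflicted.
Raw result text from heterogeneous sources is normalized through a
case-insensitive synonym table; anything unmapped is rejected rather than
guessed at.  Repeated results under one assay definition (assay id plus
the canonicalized variable map — exposure time, metabolising system, ...)
aggregate to a single overall call: any disagreement is Conflicted.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .core import (
    Assay,
    AssayEventLink,
    AssayTier,
    EventRole,
    Grade,
    KeyEvent,
    KeyEventGroup,
    KeyEventRelationship,
    Network,
    NetworkView,
    OrgLevel,
    PredictionBasis,
    PredictionLink,
    StrengthLevel,
    validate_network,
)
from .reasoning import ConcernState

__all__ = [
    "Call",
    "RawResultRecord",
    "Rejection",
    "normalize_call",
    "overall_call",
    "canonical_variables",
    "group_results",
    "load_knowledge",
    "save_knowledge",
    "load_calls_csv",
    "calls_to_wide",
    "export_graph",
    "SchemaError",
]


class Call(enum.Enum):
    POSITIVE = "Positive"
    NEGATIVE = "Negative"
    CONFLICTED = "Conflicted"


_CALL_SYNONYMS = {
    "positive": Call.POSITIVE,
    "active": Call.POSITIVE,
    "pos": Call.POSITIVE,
    "p": Call.POSITIVE,
    "+": Call.POSITIVE,
    "negative": Call.NEGATIVE,
    "inactive": Call.NEGATIVE,
    "neg": Call.NEGATIVE,
    "n": Call.NEGATIVE,
    "-": Call.NEGATIVE,
    "−": Call.NEGATIVE,  # minus sign
    "conflicted": Call.CONFLICTED,
    "equivocal-conflict": Call.CONFLICTED,
}


@dataclass(frozen=True)
class Rejection:
    """An excluded raw result: unmapped vocabulary, with the offending text."""

    text: str
    reason: str = "unmapped call vocabulary"


def normalize_call(raw: str) -> Call | Rejection:
    """Map raw result text onto {Positive, Negative, Conflicted}."""
    call = _CALL_SYNONYMS.get(str(raw).strip().lower())
    return call if call is not None else Rejection(str(raw))


def overall_call(calls: list[Call]) -> Call:
    """Aggregate repeated normalized results under one assay definition."""
    if not calls:
        raise ValueError("overall_call requires at least one call")
    distinct = set(calls)
    if len(distinct) > 1:
        return Call.CONFLICTED
    return distinct.pop()


@dataclass(frozen=True)
class RawResultRecord:
    compound_id: str
    assay_id: str
    variables: dict[str, str] = field(default_factory=dict)
    measurement_id: str = "overall_call"
    raw_call: str = ""
    source: str = ""


def canonical_variables(variables: dict[str, str]) -> tuple[tuple[str, str], ...]:
    """Canonicalize a variable map: case-fold and token-sort values so
    'Rat S9' and 'S9 Rat' compare equal; keys sorted."""
    out = []
    for k in sorted(variables):
        tokens = sorted(str(variables[k]).lower().split())
        out.append((k.strip().lower(), " ".join(tokens)))
    return tuple(out)


AssayDefinitionKey = tuple[str, str, str, tuple[tuple[str, str], ...]]


def group_results(
    records: list[RawResultRecord],
) -> tuple[dict[AssayDefinitionKey, Call], list[Rejection]]:
    """Normalize, group by (compound, assay, measurement, canonical
    variables) and aggregate each group to its overall call."""
    grouped: dict[AssayDefinitionKey, list[Call]] = {}
    rejections: list[Rejection] = []
    for rec in records:
        call = normalize_call(rec.raw_call)
        if isinstance(call, Rejection):
            rejections.append(call)
            continue
        key = (rec.compound_id, rec.assay_id, rec.measurement_id, canonical_variables(rec.variables))
        grouped.setdefault(key, []).append(call)
    return {k: overall_call(v) for k, v in sorted(grouped.items())}, rejections


# ---------------------------------------------------------------------------
# Knowledge files
# ---------------------------------------------------------------------------

class SchemaError(ValueError):
    """Raised on malformed knowledge files, with located messages."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("; ".join(problems))


def _network_to_dict(net: Network) -> dict:
    return {
        "events": [
            {
                "id": e.id,
                "name": e.name,
                "level": e.level.value,
                "role": e.role.value,
                **({"group_id": e.group_id} if e.group_id else {}),
            }
            for e in net.events.values()
        ],
        "kers": [
            {"upstream": k.upstream, "downstream": k.downstream, "strength": k.strength.label}
            for k in net.kers
        ],
        "groups": [
            {"id": g.id, "name": g.name, "members": sorted(g.members)}
            for g in net.groups.values()
        ],
        "assays": [
            {
                "id": a.id,
                "name": a.name,
                "reliability": a.reliability.label,
                "tier": a.tier.value,
                "measurements": list(a.measurements),
            }
            for a in net.assays.values()
        ],
        "assay_event_links": [
            {
                "assay_id": l.assay_id,
                "measurement_id": l.measurement_id,
                "event_id": l.event_id,
                "convincingness": l.convincingness.label,
            }
            for l in net.assay_event_links
        ],
        "prediction_bases": [
            {
                "model_id": b.model_id,
                "basis_id": b.basis_id,
                "convincingness": b.convincingness.label,
                "reliability": b.reliability.label,
                "links": [
                    {
                        "target_kind": pl.target_kind,
                        "target_id": pl.target_id,
                        "convincingness": pl.convincingness.label,
                        "reliability": pl.reliability.label,
                    }
                    for pl in b.links
                ],
            }
            for b in net.prediction_bases
        ],
    }


def _network_from_dict(doc: dict) -> Network:
    problems: list[str] = []
    net = Network()

    def grade(text, loc):
        try:
            return Grade.from_text(text)
        except KeyError:
            problems.append(f"{loc}: unknown grade {text!r}")
            return Grade.SMALL

    def strength(text, loc):
        try:
            return StrengthLevel.from_text(text)
        except KeyError:
            problems.append(f"{loc}: unknown strength {text!r}")
            return StrengthLevel.VERY_LOW

    for i, e in enumerate(doc.get("events", [])):
        loc = f"events[{i}]"
        try:
            level = OrgLevel(e["level"])
        except ValueError:
            problems.append(f"{loc}: unknown organization level {e['level']!r}")
            continue
        try:
            role = EventRole(e["role"])
        except ValueError:
            problems.append(f"{loc}: unknown role {e['role']!r}")
            continue
        net.events[e["id"]] = KeyEvent(e["id"], e.get("name", e["id"]), level, role, e.get("group_id"))

    for i, k in enumerate(doc.get("kers", [])):
        net.kers.append(
            KeyEventRelationship(k["upstream"], k["downstream"], strength(k["strength"], f"kers[{i}]"))
        )

    for g in doc.get("groups", []):
        net.groups[g["id"]] = KeyEventGroup(g["id"], g.get("name", g["id"]), frozenset(g["members"]))

    for i, a in enumerate(doc.get("assays", [])):
        loc = f"assays[{i}]"
        try:
            tier = AssayTier(a["tier"])
        except ValueError:
            problems.append(f"{loc}: unknown tier {a['tier']!r}")
            continue
        net.assays[a["id"]] = Assay(
            a["id"], a.get("name", a["id"]), grade(a["reliability"], loc), tier, tuple(a["measurements"])
        )

    for i, l in enumerate(doc.get("assay_event_links", [])):
        net.assay_event_links.append(
            AssayEventLink(
                l["assay_id"], l["measurement_id"], l["event_id"],
                grade(l["convincingness"], f"assay_event_links[{i}]"),
            )
        )

    for i, b in enumerate(doc.get("prediction_bases", [])):
        loc = f"prediction_bases[{i}]"
        links = tuple(
            PredictionLink(
                pl["target_kind"], pl["target_id"],
                grade(pl["convincingness"], loc), grade(pl.get("reliability", "Large"), loc),
            )
            for pl in b.get("links", [])
        )
        net.prediction_bases.append(
            PredictionBasis(
                b["model_id"], b["basis_id"],
                grade(b["convincingness"], loc), grade(b["reliability"], loc), links,
            )
        )

    if problems:
        raise SchemaError(problems)
    violations = validate_network(net)
    if violations:
        raise SchemaError([f"{v.code} at {v.location}: {v.message}" for v in violations])
    return net


def save_knowledge(net: Network, path: str | Path) -> None:
    """Write a network to YAML or JSON (chosen by extension)."""
    path = Path(path)
    doc = _network_to_dict(net)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2, sort_keys=False) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def load_knowledge(path: str | Path) -> Network:
    """Read and schema-validate a knowledge file (YAML or JSON)."""
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise SchemaError([f"{path}: top level must be a mapping"])
    return _network_from_dict(doc)


# ---------------------------------------------------------------------------
# Call CSV
# ---------------------------------------------------------------------------

#: One CSV dialect only: compound_id, assay_id, measurement_id,
#: variables (semicolon-separated key=value), call, source.
CALLS_COLUMNS = ["compound_id", "assay_id", "measurement_id", "variables", "call", "source"]


def load_calls_csv(path: str | Path) -> tuple[list[RawResultRecord], list[Rejection]]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ("compound_id", "assay_id", "call") if c not in df.columns]
    if missing:
        raise SchemaError([f"calls CSV missing columns: {', '.join(missing)}"])
    records = []
    for row in df.itertuples(index=False):
        variables = {}
        raw_vars = getattr(row, "variables", "") or ""
        for pair in str(raw_vars).split(";"):
            if "=" in pair:
                k, v = pair.split("=", 1)
                variables[k.strip()] = v.strip()
        records.append(
            RawResultRecord(
                compound_id=row.compound_id,
                assay_id=row.assay_id,
                variables=variables,
                measurement_id=getattr(row, "measurement_id", "overall_call") or "overall_call",
                raw_call=row.call,
                source=getattr(row, "source", "") or "",
            )
        )
    _, rejections = group_results(records)
    return records, rejections


def calls_to_wide(records: list[RawResultRecord]) -> pd.DataFrame:
    """Pivot normalized overall calls to a compound x assay table of call
    text (NaN where untested), using only overall_call measurements."""
    grouped, _ = group_results(records)
    rows = {}
    for (compound, assay, measurement, _vars), call in grouped.items():
        if measurement != "overall_call":
            continue
        rows.setdefault(compound, {})[assay] = call.value
    wide = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    return wide.reindex(sorted(wide.columns), axis=1)


# ---------------------------------------------------------------------------
# Graph export
# ---------------------------------------------------------------------------

_WIDTH_CLASS = {
    StrengthLevel.VERY_LOW: 1,
    StrengthLevel.LOW: 2,
    StrengthLevel.MEDIUM: 3,
    StrengthLevel.HIGH: 4,
    StrengthLevel.VERY_HIGH: 5,
}

_STATE_COLOR = {
    ConcernState.CONCERN: "red",
    ConcernState.NO_CONCERN: "green",
    ConcernState.UNKNOWN: "grey",
}


def _layers(view: NetworkView) -> dict[str, int]:
    """Deterministic layer assignment: longest path from a source, ties
    broken by node id through sorted iteration."""
    nodes = view.nodes
    edges = view.edges
    preds: dict[str, list[str]] = {n: [] for n in nodes}
    for e in edges:
        preds[e.downstream].append(e.upstream)
    layer: dict[str, int] = {}

    def depth(n: str, seen: frozenset[str] = frozenset()) -> int:
        if n in layer:
            return layer[n]
        if n in seen:  # cycle guard: malformed views export at layer 0
            return 0
        d = 0 if not preds[n] else 1 + max(depth(p, seen | {n}) for p in sorted(preds[n]))
        layer[n] = d
        return d

    for n in sorted(nodes):
        depth(n)
    return layer


def export_graph(
    view: Network | NetworkView,
    path: str | Path,
    format: str = "dot",
    states: dict[str, ConcernState] | None = None,
) -> None:
    """Write a deterministic DOT or GraphML rendering of a network view.

    Nodes carry their organization level (swim lane), role, layer and —
    when ``states`` is given — a traffic-light color; edges carry the KER
    strength as a width class.
    """
    if isinstance(view, Network):
        view = NetworkView(view)
    fmt = format.lower()
    if fmt not in ("dot", "graphml"):
        raise ValueError(f"unknown export format {format!r}")
    states = states or {}
    nodes = view.nodes
    edges = view.edges
    layers = _layers(view)

    path = Path(path)
    if fmt == "dot":
        lines = ["digraph ken {", "  rankdir=LR;"]
        for nid in sorted(nodes):
            node = nodes[nid]
            attrs = [
                f'label="{node.name}"',
                "shape=box" if not node.is_group else "shape=folder",
                "style=rounded" if not node.is_group else "style=solid",
                f'layer="{layers[nid]}"',
            ]
            if node.level is not None:
                attrs.append(f'level="{node.level.value}"')
            if node.role is not None:
                attrs.append(f'role="{node.role.value}"')
            if nid in states:
                attrs.append(f'color="{_STATE_COLOR[states[nid]]}"')
            lines.append(f'  "{nid}" [{", ".join(attrs)}];')
        for e in sorted(edges, key=lambda e: (e.upstream, e.downstream)):
            lines.append(
                f'  "{e.upstream}" -> "{e.downstream}" '
                f'[penwidth={_WIDTH_CLASS[e.strength]}, strength="{e.strength.label}"];'
            )
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    else:
        import networkx as nx

        g = nx.DiGraph()
        for nid in sorted(nodes):
            node = nodes[nid]
            g.add_node(
                nid,
                name=node.name,
                layer=layers[nid],
                is_group=str(node.is_group),
                level=node.level.value if node.level else "",
                role=node.role.value if node.role else "",
                state=states[nid].value if nid in states else "",
            )
        for e in sorted(edges, key=lambda e: (e.upstream, e.downstream)):
            g.add_edge(e.upstream, e.downstream, strength=e.strength.label, width=_WIDTH_CLASS[e.strength])
        nx.write_graphml(g, path)
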