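"""Hazard propagation: applying a reasoning paradigm to one compound's
evidence over a key-event network.

Events are processed in topological order.  At each event the local
evidence — assay overall calls linked through measurements, and fired (or
explicitly negative) prediction bases — is merged with the contributions
of upstream events transmitted along their KERs.  Three paradigms are
offered:

``conservative``
    any cause for concern wins; a red state cascades downstream, a green
    state is a local statement about an assay and does not propagate
    (a negative protein-binding assay does not prove the pathway blocked).

``tiered``
    measured results overrule predicted ones: the highest biological
    tier with informative evidence decides (human observation > in vivo >
    in vitro = in chemico > in silico); upstream inference ranks below
    all of them.  Within the deciding tier the merge is conservative.

``calculus``
    the categorical argumentation calculus: every input becomes a signed
    strength, upstream contributions are resolved first into a single
    "likelihood of preceding events" argument, transmitted through each
    KER by taking the lower value, and the whole pool is resolved to one
    signed conclusion per event.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .concordance import ConcordanceCell, condition_subset, phi, similarity_subset
from .core import (
    BALANCED,
    AssayTier,
    Direction,
    Grade,
    Network,
    SignedStrength,
    StrengthLevel,
    downstream_closure,
)
from .io import Call
from .reasoning import (
    INFERRED_TIER,
    ConcernState,
    Calculus,
    DEFAULT_CALCULUS,
    conservative_merge,
    tiered_merge,
)
from .similarity import Compound

__all__ = [
    "CompoundEvidence",
    "PropagationResult",
    "propagate",
    "alerted_aos",
    "CallDataset",
    "SuggestedAssay",
    "suggest_next",
    "PARADIGMS",
]

PARADIGMS = ("conservative", "tiered", "calculus")

_CALL_STATE = {
    Call.POSITIVE: ConcernState.CONCERN,
    Call.NEGATIVE: ConcernState.NO_CONCERN,
    # the traffic-light paradigms treat disagreement as a cause for concern
    Call.CONFLICTED: ConcernState.CONCERN,
}


@dataclass
class CompoundEvidence:
    """One compound's recorded calls and prediction outcomes.

    ``calls`` maps (assay_id, measurement_id) to a Call; ``predictions``
    maps (model_id, basis_id) to "positive" (basis fired) or "negative"
    (an explicit negative prediction).  Absent bases contribute nothing.
    """

    compound_id: str
    calls: dict[tuple[str, str], Call] = field(default_factory=dict)
    predictions: dict[tuple[str, str], str] = field(default_factory=dict)


@dataclass
class PropagationResult:
    paradigm: str
    states: dict[str, ConcernState]
    signed: dict[str, SignedStrength]
    provenance: dict[str, list[str]]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["event_id", "state", "signed_strength", "provenance"])
            for eid in sorted(self.states):
                writer.writerow(
                    [
                        eid,
                        self.states[eid].value,
                        str(self.signed[eid]) if eid in self.signed else "",
                        "|".join(self.provenance.get(eid, [])),
                    ]
                )


def _check_evidence(net: Network, evidence: CompoundEvidence) -> None:
    declared = {(l.assay_id, l.measurement_id) for l in net.assay_event_links}
    for key in evidence.calls:
        if key not in declared:
            raise KeyError(f"evidence references undeclared measurement {key!r}")
    known_bases = {b.key for b in net.prediction_bases}
    for key in evidence.predictions:
        if key not in known_bases:
            raise KeyError(f"evidence references unknown prediction basis {key!r}")


def _assay_inputs(net: Network, evidence: CompoundEvidence, event_id: str):
    """Per-assay contributions at an event: (assay, call, convincingness).

    The assay's overall call stands for the assay when recorded; otherwise
    the conservative merge of the event-linked measurement calls does.
    """
    links = net.links_for_event(event_id)
    by_assay: dict[str, list] = {}
    for l in links:
        by_assay.setdefault(l.assay_id, []).append(l)
    out = []
    for assay_id in sorted(by_assay):
        assay = net.assays[assay_id]
        alinks = by_assay[assay_id]
        overall = evidence.calls.get((assay_id, "overall_call"))
        if overall is not None:
            conv = max(
                (l.convincingness for l in alinks if l.measurement_id == "overall_call"),
                default=max(l.convincingness for l in alinks),
            )
            out.append((assay, overall, conv))
            continue
        measured = [
            (l, evidence.calls[(assay_id, l.measurement_id)])
            for l in alinks
            if (assay_id, l.measurement_id) in evidence.calls
        ]
        if measured:
            merged = conservative_merge([_CALL_STATE[c] for _, c in measured])
            call = {
                ConcernState.CONCERN: Call.POSITIVE,
                ConcernState.NO_CONCERN: Call.NEGATIVE,
            }[merged]
            conv = max(l.convincingness for l, _ in measured)
            out.append((assay, call, conv))
    return out


def _prediction_inputs(net: Network, evidence: CompoundEvidence, event_id: str):
    """Prediction contributions at an event: (basis, link, outcome)."""
    out = []
    for basis in net.prediction_bases:
        outcome = evidence.predictions.get(basis.key)
        if outcome is None:
            continue
        for link in basis.links:
            if link.target_kind in ("event", "ao") and link.target_id == event_id:
                out.append((basis, link, outcome))
    return out


def propagate(
    net: Network,
    evidence: CompoundEvidence,
    paradigm: str = "conservative",
    calculus: Calculus | None = None,
) -> PropagationResult:
    """Propagate one compound's evidence through the network."""
    if paradigm not in PARADIGMS:
        raise ValueError(f"unknown paradigm {paradigm!r}; expected one of {PARADIGMS}")
    _check_evidence(net, evidence)
    calc = calculus or DEFAULT_CALCULUS
    graph = net.graph()

    states: dict[str, ConcernState] = {}
    signed: dict[str, SignedStrength] = {}
    provenance: dict[str, list[str]] = {}

    for event_id in nx.topological_sort(graph):
        prov: list[str] = []
        assay_in = _assay_inputs(net, evidence, event_id)
        pred_in = _prediction_inputs(net, evidence, event_id)
        upstream = [
            (u, graph.edges[u, event_id]["strength"]) for u in sorted(graph.predecessors(event_id))
        ]

        if paradigm == "calculus":
            pool: list[SignedStrength] = []
            for assay, call, conv in assay_in:
                if call is Call.CONFLICTED:
                    # disagreement: a very weak argument for concern
                    mag = calc.strength_of(Grade.SMALL, Grade.SMALL)
                    pool.append(SignedStrength(mag, Direction.FOR))
                else:
                    mag = calc.strength_of(conv, assay.reliability)
                    direction = Direction.FOR if call is Call.POSITIVE else Direction.AGAINST
                    pool.append(SignedStrength(mag, direction))
                prov.append(f"assay:{assay.id}={call.value}")
            for basis, link, outcome in pred_in:
                arg = calc.strength_of(basis.convincingness, basis.reliability)
                per = calc.strength_of(link.convincingness, link.reliability)
                mag = calc.transmit(arg, per)
                direction = Direction.FOR if outcome == "positive" else Direction.AGAINST
                pool.append(SignedStrength(mag, direction))
                prov.append(f"prediction:{basis.model_id}:{basis.basis_id}={outcome}")
            transmitted = []
            for u, ker_strength in upstream:
                s = signed[u]
                if s.balanced:
                    continue
                transmitted.append(
                    SignedStrength(calc.transmit(s.magnitude, ker_strength), s.direction)
                )
            if transmitted:
                agg = calc.resolve_signed(transmitted)
                if not agg.balanced:
                    pool.append(agg)
                    prov.append(f"upstream:{agg}")
            conclusion = calc.resolve_signed(pool)
            signed[event_id] = conclusion
            if conclusion.balanced:
                states[event_id] = ConcernState.UNKNOWN
            elif conclusion.direction is Direction.FOR:
                states[event_id] = ConcernState.CONCERN
            else:
                states[event_id] = ConcernState.NO_CONCERN
        else:
            tiered_pool: list[tuple] = []
            for assay, call, _conv in assay_in:
                tiered_pool.append((assay.tier, _CALL_STATE[call]))
                prov.append(f"assay:{assay.id}={call.value}")
            for basis, _link, outcome in pred_in:
                state = ConcernState.CONCERN if outcome == "positive" else ConcernState.NO_CONCERN
                tiered_pool.append((AssayTier.IN_SILICO, state))
                prov.append(f"prediction:{basis.model_id}:{basis.basis_id}={outcome}")
            # only Concern travels downstream in the categorical paradigms
            for u, _ker in upstream:
                if states[u] is ConcernState.CONCERN:
                    tiered_pool.append((INFERRED_TIER, ConcernState.CONCERN))
                    prov.append(f"upstream:{u}")
            if paradigm == "conservative":
                states[event_id] = conservative_merge([s for _, s in tiered_pool])
            else:
                states[event_id] = tiered_merge(tiered_pool)
        provenance[event_id] = prov

    return PropagationResult(paradigm, states, signed, provenance)


# ---------------------------------------------------------------------------
# Use case 2: alerted adverse outcomes
# ---------------------------------------------------------------------------

def alerted_aos(
    net: Network,
    source_id: str,
    call: Call | ConcernState = Call.POSITIVE,
) -> set[tuple[str, tuple[str, ...]]]:
    """Adverse outcomes downstream of a positive assay result (or a
    concerning event), each with one shortest supporting path.  A
    negative call alerts nothing: the semantics are hazard-only."""
    positive = call in (Call.POSITIVE, Call.CONFLICTED, ConcernState.CONCERN)
    if not positive:
        return set()
    if source_id in net.assays:
        starts = sorted({l.event_id for l in net.links_for_assay(source_id)})
    elif source_id in net.events:
        starts = [source_id]
    else:
        raise KeyError(f"unknown assay or event id {source_id!r}")

    graph = net.graph()
    aos = net.aos()
    out: set[tuple[str, tuple[str, ...]]] = set()
    for start in starts:
        reach = downstream_closure(net, start) | {start}
        for ao in sorted(reach & aos):
            path = nx.shortest_path(graph, start, ao)
            out.add((ao, tuple(path)))
    return out


# ---------------------------------------------------------------------------
# Use case 3: next-assay suggestion
# ---------------------------------------------------------------------------

@dataclass
class CallDataset:
    """A compound x assay overall-call table plus the structures (and,
    optionally, fired alerts) of the compounds in it."""

    calls: pd.DataFrame
    compounds: list[Compound]
    alerts: dict[str, set[str]] = field(default_factory=dict)

    def compound(self, compound_id: str) -> Compound:
        for c in self.compounds:
            if c.id == compound_id:
                return c
        raise KeyError(f"unknown compound {compound_id!r}")


@dataclass(frozen=True)
class SuggestedAssay:
    assay_id: str
    phi_abs: float | None  # None when every pairing was masked
    n: int
    hops: int  # fewest KERs from the assay's event to the target


def suggest_next(
    net: Network,
    dataset: CallDataset,
    compound_id: str,
    target_event: str,
    min_n: int = 5,
    similarity_cutoff: float = 0.5,
    scheme: str = "path_default",
) -> list[SuggestedAssay]:
    """Rank the compound's unmeasured assays on the paths to a target
    event by how strongly their calls track the target-linked assays
    among chemically similar compounds.

    The neighborhood is the Tanimoto ball around the compound; it is
    further conditioned on each of the compound's own existing calls
    whenever the conditioned subset keeps >= min_n members.  Candidates
    whose concordance is everywhere masked fall back to a fewest-KER-hops
    ranking.
    """
    if target_event not in net.events:
        raise KeyError(f"unknown event {target_event!r}")
    query = dataset.compound(compound_id)
    row = dataset.calls.loc[compound_id] if compound_id in dataset.calls.index else pd.Series(dtype=object)
    measured = {a for a, v in row.items() if isinstance(v, str) and v}
    if not measured:
        raise ValueError(f"compound {compound_id!r} has no recorded calls")

    from .core import upstream_closure

    relevant_events = upstream_closure(net, target_event) | {target_event}
    relevant_assays = sorted(
        {l.assay_id for l in net.assay_event_links if l.event_id in relevant_events}
    )
    target_assays = sorted({l.assay_id for l in net.links_for_event(target_event)})
    candidates = [a for a in relevant_assays if a not in measured]
    if not candidates:
        raise ValueError("no candidate assays: all relevant assays are measured")

    subset = similarity_subset(
        dataset.calls, dataset.compounds, query, scheme, similarity_cutoff, alerts=dataset.alerts
    )
    # condition on the compound's own calls where enough compounds remain
    for assay in sorted(measured):
        call = row[assay]
        if call not in ("Positive", "Negative") or assay not in subset.columns:
            continue
        narrowed = condition_subset(subset, assay, call)
        if len(narrowed) >= min_n:
            subset = narrowed

    graph = net.graph().to_undirected()

    def hops(assay_id: str) -> int:
        best = len(net.events)
        for l in net.links_for_assay(assay_id):
            if l.event_id in relevant_events:
                try:
                    best = min(best, nx.shortest_path_length(graph, l.event_id, target_event))
                except nx.NetworkXNoPath:
                    pass
        return best

    scored: list[SuggestedAssay] = []
    for cand in candidates:
        best: ConcordanceCell | None = None
        for ta in target_assays:
            if cand not in subset.columns or ta not in subset.columns or cand == ta:
                continue
            cell = phi(subset[cand], subset[ta])
            if cell.masked or cell.n < min_n:
                continue
            if best is None or abs(cell.phi) > abs(best.phi):
                best = cell
        if best is None:
            scored.append(SuggestedAssay(cand, None, 0, hops(cand)))
        else:
            scored.append(SuggestedAssay(cand, abs(best.phi), best.n, hops(cand)))

    def key(s: SuggestedAssay):
        # scored candidates first (higher |phi|, then larger n); masked
        # candidates fall back to fewest hops
        if s.phi_abs is not None:
            return (0, -s.phi_abs, -s.n, s.assay_id)
        return (1, s.hops, 0, s.assay_id)

    return sorted(scored, key=key)
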