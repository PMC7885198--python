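"""Evidence propagation over networks, alerted AOs and next-assay ranking."""

import pandas as pd
import pytest

from aopnet import (
    AssayTier,
    Call,
    CallDataset,
    Compound,
    CompoundEvidence,
    ConcernState,
    Direction,
    SignedStrength,
    StrengthLevel,
    alerted_aos,
    propagate,
    suggest_next,
    transmit,
)
from conftest import attach_assay, make_chain


def evidence(compound="c", **calls):
    return CompoundEvidence(
        compound, {(assay, "overall_call"): call for assay, call in calls.items()}
    )


class TestConservative:
    def test_positive_ames_cascades_to_both_aos(self, genotox_net):
        ev = evidence(ames=Call.POSITIVE)
        result = propagate(genotox_net, ev, "conservative")
        assert result.states["inherited_dna_mutation"] == ConcernState.CONCERN
        assert result.states["genetic_instability"] == ConcernState.CONCERN
        assert result.states["cancer"] == ConcernState.CONCERN
        assert result.states["dna_damage"] == ConcernState.UNKNOWN

    def test_linalool_pattern(self, linalool):
        result = propagate(linalool.network, linalool.evidence, "conservative")
        assert result.states["covalent_protein_binding"] == ConcernState.NO_CONCERN
        assert result.states["keratinocyte_activation"] == ConcernState.NO_CONCERN
        assert result.states["t_cell_activation"] == ConcernState.CONCERN
        assert result.states["skin_sensitization"] == ConcernState.CONCERN

    def test_empty_evidence_all_unknown(self, skin_net):
        result = propagate(skin_net, CompoundEvidence("c"), "conservative")
        assert set(result.states.values()) == {ConcernState.UNKNOWN}
        assert set(result.states) == set(skin_net.events)

    def test_no_concern_does_not_propagate_downstream(self):
        net = make_chain("a", "b", "c")
        attach_assay(net, "assay_a", "a")
        result = propagate(net, evidence(assay_a=Call.NEGATIVE), "conservative")
        assert result.states["a"] == ConcernState.NO_CONCERN
        assert result.states["b"] == ConcernState.UNKNOWN

    def test_monotone_in_added_concern(self, linalool):
        base = propagate(linalool.network, linalool.evidence, "conservative")
        extra = CompoundEvidence(
            "linalool",
            {**linalool.evidence.calls, ("hclat", "overall_call"): Call.POSITIVE},
            dict(linalool.evidence.predictions),
        )
        more = propagate(linalool.network, extra, "conservative")
        for eid, state in base.states.items():
            if state == ConcernState.CONCERN:
                assert more.states[eid] == ConcernState.CONCERN

    def test_concern_implies_concern_at_downstream_aos(self, genotox_net):
        from aopnet import downstream_closure

        result = propagate(genotox_net, evidence(ames=Call.POSITIVE), "conservative")
        for eid, state in result.states.items():
            if state != ConcernState.CONCERN:
                continue
            for ao in genotox_net.aos() & downstream_closure(genotox_net, eid):
                assert result.states[ao] == ConcernState.CONCERN

    def test_conflicted_counts_as_concern(self):
        net = make_chain("a", "b")
        attach_assay(net, "assay_a", "a")
        result = propagate(net, evidence(assay_a=Call.CONFLICTED), "conservative")
        assert result.states["a"] == ConcernState.CONCERN


class TestTiered:
    def test_assay_overrules_prediction_at_the_ao(self, skin_net):
        ev = CompoundEvidence(
            "c",
            {("human_observation", "overall_call"): Call.NEGATIVE},
            {("sar_model", "skin_sensitization_alert"): "positive"},
        )
        result = propagate(skin_net, ev, "tiered")
        assert result.states["skin_sensitization"] == ConcernState.NO_CONCERN
        # the same scenario is a Concern under the conservative paradigm
        conservative = propagate(skin_net, ev, "conservative")
        assert conservative.states["skin_sensitization"] == ConcernState.CONCERN

    def test_local_assay_overrules_upstream_inference(self):
        net = make_chain("a", "b")
        attach_assay(net, "assay_a", "a")
        attach_assay(net, "assay_b", "b")
        ev = evidence(assay_a=Call.POSITIVE, assay_b=Call.NEGATIVE)
        result = propagate(net, ev, "tiered")
        assert result.states["a"] == ConcernState.CONCERN
        assert result.states["b"] == ConcernState.NO_CONCERN

    def test_upstream_concern_inherited_when_no_local_evidence(self):
        net = make_chain("a", "b")
        attach_assay(net, "assay_a", "a")
        result = propagate(net, evidence(assay_a=Call.POSITIVE), "tiered")
        assert result.states["b"] == ConcernState.CONCERN


class TestCalculus:
    def test_linear_chain_equals_folded_transmit(self):
        strengths = [StrengthLevel.HIGH, StrengthLevel.MEDIUM, StrengthLevel.HIGH]
        net = make_chain("a", "b", "c", "d", strengths=strengths)
        attach_assay(net, "assay_a", "a")  # Medium conv x Large rel -> High
        result = propagate(net, evidence(assay_a=Call.POSITIVE), "calculus")
        expected = StrengthLevel.HIGH
        for ker in strengths:
            expected = transmit(expected, ker)
        assert result.signed["d"] == SignedStrength(expected, Direction.FOR)

    def test_empty_evidence_all_balanced(self, skin_net):
        result = propagate(skin_net, CompoundEvidence("c"), "calculus")
        assert all(s.balanced for s in result.signed.values())

    def test_in_silico_argument_transmits_as_low(self, skin_net):
        # prediction argument Medium, prediction-event relationship Low:
        # the transmitted in-silico contribution is Low
        ev = CompoundEvidence("c", {}, {("sar_model", "skin_sensitization_alert"): "positive"})
        result = propagate(skin_net, ev, "calculus")
        assert result.signed["skin_sensitization"] == SignedStrength(
            StrengthLevel.LOW, Direction.FOR
        )

    def test_order_independent_across_insertion_orders(self, linalool):
        from aopnet import Network

        net = linalool.network
        reordered = Network(
            events=dict(reversed(list(net.events.items()))),
            kers=list(reversed(net.kers)),
            groups=net.groups,
            assays=net.assays,
            assay_event_links=list(reversed(net.assay_event_links)),
            prediction_bases=net.prediction_bases,
        )
        for paradigm in ("conservative", "tiered", "calculus"):
            a = propagate(net, linalool.evidence, paradigm)
            b = propagate(reordered, linalool.evidence, paradigm)
            assert a.states == b.states
            assert a.signed == b.signed


class TestEvidenceChecks:
    def test_unknown_paradigm_rejected(self, skin_net):
        with pytest.raises(ValueError):
            propagate(skin_net, CompoundEvidence("c"), "bayesian")

    def test_dangling_measurement_rejected(self, skin_net):
        ev = CompoundEvidence("c", {("dpra", "no_such_measurement"): Call.POSITIVE})
        with pytest.raises(KeyError):
            propagate(skin_net, ev)

    def test_measurement_calls_stand_in_without_overall(self, skin_net):
        ev = CompoundEvidence("c", {("dpra", "cysteine_depletion"): Call.POSITIVE})
        result = propagate(skin_net, ev, "conservative")
        assert result.states["covalent_protein_binding"] == ConcernState.CONCERN


class TestAlertedAos:
    def test_positive_ames_alerts_both_aos(self, genotox_net):
        hits = alerted_aos(genotox_net, "ames", Call.POSITIVE)
        assert {ao for ao, _ in hits} == {"genetic_instability", "cancer"}
        for _, path in hits:
            assert path[0] == "inherited_dna_mutation"

    def test_negative_call_alerts_nothing(self, genotox_net):
        assert alerted_aos(genotox_net, "ames", Call.NEGATIVE) == set()

    def test_call_on_terminal_ao_returns_itself(self, genotox_net):
        hits = alerted_aos(genotox_net, "cancer", Call.POSITIVE)
        assert hits == {("cancer", ("cancer",))}

    def test_unknown_source_raises(self, genotox_net):
        with pytest.raises(KeyError):
            alerted_aos(genotox_net, "nope", Call.POSITIVE)


class TestSuggestNext:
    def _dataset(self, net):
        """Planted dataset: candidate assay_b perfectly tracks the
        AO-linked assay_t among neighbors; assay_c is independent."""
        rows = []
        for i in range(12):
            t = "Positive" if i % 2 else "Negative"
            b = t  # phi(b, t) = 1
            c = "Positive" if i % 3 == 0 else "Negative"  # decorrelated
            rows.append({"assay_t": t, "assay_b": b, "assay_c": c})
        calls = pd.DataFrame(rows, index=[f"m{i}" for i in range(12)])
        calls.loc["query"] = {"assay_t": None, "assay_b": None, "assay_c": None}
        calls.loc["query", "assay_q"] = "Positive"
        compounds = [Compound(f"m{i}", "CCO") for i in range(12)] + [Compound("query", "CCO")]
        return CallDataset(calls=calls, compounds=compounds)

    def _net(self):
        net = make_chain("a", "b", "ao")
        attach_assay(net, "assay_q", "a")
        attach_assay(net, "assay_b", "b")
        attach_assay(net, "assay_c", "b")
        attach_assay(net, "assay_t", "ao")
        return net

    def test_planted_concordance_ranks_first(self):
        net = self._net()
        ranked = suggest_next(net, self._dataset(net), "query", "ao", min_n=5, similarity_cutoff=0.0)
        assert ranked[0].assay_id == "assay_b"
        assert ranked[0].phi_abs == pytest.approx(1.0)
        order = [s.assay_id for s in ranked]
        assert order.index("assay_b") < order.index("assay_c")

    def test_all_measured_is_an_error(self):
        net = self._net()
        ds = self._dataset(net)
        ds.calls.loc["query"] = {
            "assay_t": "Positive", "assay_b": "Positive", "assay_c": "Positive", "assay_q": "Positive",
        }
        with pytest.raises(ValueError, match="no candidate"):
            suggest_next(net, ds, "query", "ao", min_n=5, similarity_cutoff=0.0)

    def test_mask_all_falls_back_to_hop_ranking(self):
        net = self._net()
        ranked = suggest_next(
            net, self._dataset(net), "query", "ao", min_n=100, similarity_cutoff=0.0
        )
        assert all(s.phi_abs is None for s in ranked)
        hops = [s.hops for s in ranked]
        assert hops == sorted(hops)

    def test_compound_without_calls_rejected(self):
        net = self._net()
        ds = self._dataset(net)
        ds.calls.loc["query"] = None
        with pytest.raises(ValueError, match="no recorded calls"):
            suggest_next(net, ds, "query", "ao", min_n=5, similarity_cutoff=0.0)
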