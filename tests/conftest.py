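import pytest

from aopnet import (
    Assay,
    AssayEventLink,
    AssayTier,
    EventRole,
    Grade,
    KeyEvent,
    KeyEventGroup,
    KeyEventRelationship,
    Network,
    OrgLevel,
    StrengthLevel,
    fixture,
)


def make_event(eid, role=EventRole.KE, level=OrgLevel.CELLULAR, group=None):
    return KeyEvent(eid, eid.replace("_", " "), level, role, group)


def make_chain(*ids, strengths=None):
    """Linear network id0 -> id1 -> ... with given KER strengths."""
    net = Network()
    for i, eid in enumerate(ids):
        role = EventRole.MIE if i == 0 else (EventRole.AO if i == len(ids) - 1 else EventRole.KE)
        net.events[eid] = make_event(eid, role)
    strengths = strengths or [StrengthLevel.HIGH] * (len(ids) - 1)
    for (u, v), s in zip(zip(ids, ids[1:]), strengths):
        net.kers.append(KeyEventRelationship(u, v, s))
    return net


def attach_assay(net, assay_id, event_id, tier=AssayTier.IN_VITRO,
                 reliability=Grade.LARGE, convincingness=Grade.MEDIUM):
    net.assays[assay_id] = Assay(assay_id, assay_id, reliability, tier, ("overall_call",))
    net.assay_event_links.append(
        AssayEventLink(assay_id, "overall_call", event_id, convincingness)
    )
    return net


@pytest.fixture(scope="session")
def skin_net():
    return fixture("skin_sensitization").network


@pytest.fixture(scope="session")
def linalool():
    return fixture("linalool_evidence")


@pytest.fixture(scope="session")
def genotox_net():
    return fixture("genotoxicity").network


@pytest.fixture(scope="session")
def rxr_net():
    return fixture("rxr_carcinogenicity").network


@pytest.fixture(scope="session")
def scenario():
    return fixture("dihydroxyaniline_scenario")


@pytest.fixture(scope="session")
def oestrogen():
    return fixture("oestrogen_ontology")
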