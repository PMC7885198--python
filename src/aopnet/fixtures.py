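"""Packaged example networks and seeded random generators.

The catalog encodes the worked examples this package is organised
around: the skin-sensitization AOP with its seven assays, a two-MIE
reproductive-toxicity network, a genotoxicity network for the
alerted-AO query, the retinoid X receptor carcinogenicity network with
its key-event groups, an oestrogen-receptor ontology with assay
groupings, a full evidence record for (+/-)-linalool, and a compound
panel around 2,4-dihydroxyaniline for the concordance/next-assay
scenario.  Alongside the catalog sit two generators: layered random
DAGs for property testing and call datasets with planted pairwise phi
(latent Gaussian thresholding), for exercising the concordance
machinery at scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    EventRole,
    KeyEvent,
    KeyEventRelationship,
    Network,
    OrgLevel,
    StrengthLevel,
)
from .io import Call, load_knowledge
from .ontology import Ontology, TermMapping, load_mapping_tsv, load_ontology_tsv
from .propagation import CallDataset, CompoundEvidence
from .similarity import Compound, load_smiles

__all__ = [
    "FIXTURE_NAMES",
    "Fixture",
    "fixture",
    "random_ken",
    "random_calls",
]

FIXTURE_NAMES = (
    "skin_sensitization",
    "reprotoxicity",
    "genotoxicity",
    "rxr_carcinogenicity",
    "oestrogen_ontology",
    "linalool_evidence",
    "dihydroxyaniline_scenario",
)


@dataclass
class Fixture:
    name: str
    network: Network
    evidence: CompoundEvidence | None = None
    compound: Compound | None = None
    ontology: Ontology | None = None
    mapping: TermMapping | None = None
    dataset: CallDataset | None = None


def _data_path(filename: str) -> Path:
    ref = resources.files("aopnet.data").joinpath("fixtures").joinpath(filename)
    with resources.as_file(ref) as p:
        return Path(p)


def _load_network(filename: str) -> Network:
    return load_knowledge(_data_path(filename))


LINALOOL = Compound("linalool", "CC(C)=CCCC(C)(O)C=C", "(+/-)-linalool")
DIHYDROXYANILINE = Compound("dihydroxyaniline_24", "Nc1ccc(O)cc1O", "2,4-dihydroxyaniline")


def _linalool_evidence() -> CompoundEvidence:
    """The Fig-11-style pattern: protein-reactivity and keratinocyte
    assays negative, the in vivo and human results positive, and the
    structural alert firing.  Dendritic-cell assays are untested."""
    return CompoundEvidence(
        compound_id="linalool",
        calls={
            ("dpra", "overall_call"): Call.NEGATIVE,
            ("keratinosens", "overall_call"): Call.NEGATIVE,
            ("lusens", "overall_call"): Call.NEGATIVE,
            ("llna", "overall_call"): Call.POSITIVE,
            ("human_observation", "overall_call"): Call.POSITIVE,
        },
        predictions={("sar_model", "skin_sensitization_alert"): "positive"},
    )


#: Planted assay-call concordance for the dihydroxyaniline scenario: a
#: one-factor sensitization axis, with the protein-reactivity assays
#: loading most strongly.  Deriving the pairwise phi targets from factor
#: loadings keeps the implied latent correlation matrix feasible (PSD).
_SCENARIO_LOADINGS = {
    "dpra": 0.90,
    "keratinosens": 0.85,
    "lusens": 0.80,
    "hclat": 0.65,
    "usens": 0.65,
    "llna": 0.80,
    "human_observation": 0.80,
}


def _scenario_phi() -> dict[tuple[str, str], float]:
    names = list(_SCENARIO_LOADINGS)
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            rho = _SCENARIO_LOADINGS[a] * _SCENARIO_LOADINGS[b]
            out[(a, b)] = float(2.0 / np.pi * np.arcsin(rho))
    return out


_SCENARIO_SEED = 20210122  # date-derived, fixed once


def _dihydroxyaniline_dataset() -> CallDataset:
    compounds = load_smiles(_data_path("dihydroxyaniline_compounds.smi"))
    assays = ["dpra", "keratinosens", "lusens", "hclat", "usens", "llna", "human_observation"]
    calls = random_calls(
        seed=_SCENARIO_SEED,
        compounds=[c.id for c in compounds],
        assays=assays,
        concordance_spec=_scenario_phi(),
    )
    # the compound under study has early-pathway calls but no h-CLAT,
    # U-SENS, LLNA or human result yet
    for missing in ("hclat", "usens", "llna", "human_observation"):
        calls.loc["dihydroxyaniline_24", missing] = float("nan")
    return CallDataset(calls=calls, compounds=compounds)


def fixture(name: str) -> Fixture:
    """Load a packaged fixture by name; content is deterministic and
    passes validate_network."""
    if name == "skin_sensitization":
        return Fixture(name, _load_network("skin_sensitization.yaml"))
    if name == "reprotoxicity":
        return Fixture(name, _load_network("reprotoxicity.yaml"))
    if name == "genotoxicity":
        return Fixture(name, _load_network("genotoxicity.yaml"))
    if name == "rxr_carcinogenicity":
        return Fixture(name, _load_network("rxr_carcinogenicity.yaml"))
    if name == "oestrogen_ontology":
        return Fixture(
            name,
            _load_network("oestrogen_network.yaml"),
            ontology=load_ontology_tsv(_data_path("oestrogen_ontology.tsv")),
            mapping=load_mapping_tsv(_data_path("oestrogen_mapping.tsv")),
        )
    if name == "linalool_evidence":
        return Fixture(
            name,
            _load_network("skin_sensitization.yaml"),
            evidence=_linalool_evidence(),
            compound=LINALOOL,
        )
    if name == "dihydroxyaniline_scenario":
        return Fixture(
            name,
            _load_network("skin_sensitization.yaml"),
            compound=DIHYDROXYANILINE,
            dataset=_dihydroxyaniline_dataset(),
        )
    raise KeyError(f"unknown fixture {name!r}; known: {', '.join(FIXTURE_NAMES)}")


# ---------------------------------------------------------------------------
# Random generators
# ---------------------------------------------------------------------------

_LEVEL_CYCLE = [
    OrgLevel.MOLECULAR,
    OrgLevel.CELLULAR,
    OrgLevel.TISSUE,
    OrgLevel.ORGAN,
    OrgLevel.INDIVIDUAL,
    OrgLevel.POPULATION,
]


def random_ken(
    seed: int,
    n_events: int = 12,
    n_layers: int = 4,
    edge_density: float = 0.3,
) -> Network:
    """A seeded, layered random key-event network.

    Events are spread over layers (layer 0 = MIEs, last layer = AOs) and
    KERs only run forward between layers, so the result is a DAG by
    construction; every non-source event gets at least one upstream
    parent so the network is connected from the MIEs.
    """
    if n_events < 2 or n_layers < 2 or n_layers > n_events:
        raise ValueError("need n_events >= 2 and 2 <= n_layers <= n_events")
    if not 0.0 < edge_density <= 1.0:
        raise ValueError("edge_density must lie in (0, 1]")
    rng = np.random.default_rng(seed)

    layer_of = sorted(rng.integers(0, n_layers, size=n_events - n_layers).tolist() + list(range(n_layers)))
    net = Network()
    ids: list[str] = []
    last_layer = max(layer_of)
    for i, layer in enumerate(layer_of):
        eid = f"e{i:03d}"
        ids.append(eid)
        role = EventRole.MIE if layer == 0 else (EventRole.AO if layer == last_layer else EventRole.KE)
        level = _LEVEL_CYCLE[min(layer, len(_LEVEL_CYCLE) - 1)]
        net.events[eid] = KeyEvent(eid, f"Event {i}", level, role)

    strengths = list(StrengthLevel)
    edges: set[tuple[str, str]] = set()
    for j, lj in enumerate(layer_of):
        if lj == 0:
            continue
        earlier = [i for i, li in enumerate(layer_of) if li < lj]
        parent = int(rng.choice(earlier))
        edges.add((ids[parent], ids[j]))
        for i in earlier:
            if rng.random() < edge_density:
                edges.add((ids[i], ids[j]))
    for u, v in sorted(edges):
        net.kers.append(KeyEventRelationship(u, v, strengths[int(rng.integers(0, 5))]))
    return net


def random_calls(
    seed: int,
    compounds: list[str] | int,
    assays: list[str],
    concordance_spec: dict[tuple[str, str], float] | None = None,
) -> pd.DataFrame:
    """Binary call dataset with planted pairwise phi.

    Calls are thresholded latent Gaussians: with balanced margins the phi
    of two dichotomized standard normals with latent correlation rho is
    (2/pi) arcsin(rho), so a target phi t is planted with
    rho = sin(pi t / 2) and the empirical phi converges to t as the
    number of compounds grows.
    """
    if isinstance(compounds, int):
        compounds = [f"c{i:04d}" for i in range(compounds)]
    spec = concordance_spec or {}
    k = len(assays)
    index = {a: i for i, a in enumerate(assays)}
    rho = np.eye(k)
    for (a, b), t in spec.items():
        if not -1.0 <= t <= 1.0:
            raise ValueError(f"target phi for ({a}, {b}) outside [-1, 1]")
        r = float(np.sin(np.pi * t / 2.0))
        rho[index[a], index[b]] = rho[index[b], index[a]] = r
    w, v = np.linalg.eigh(rho)
    if w.min() < -1e-9:
        raise ValueError("infeasible concordance_spec: latent correlation matrix is not PSD")

    rng = np.random.default_rng(seed)
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((len(compounds), k)) @ factor.T
    data = np.where(z > 0, Call.POSITIVE.value, Call.NEGATIVE.value)
    return pd.DataFrame(data, index=list(compounds), columns=list(assays))
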