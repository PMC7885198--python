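"""Is-a ontologies over key events and assays.

A small DAG of terms with multiple parents allowed (e.g. "oestrogen
receptor alpha binding" is-a both "oestrogen receptor alpha event" and
"oestrogen receptor binding").  Terms map onto key events and assays, and
a query for a term selects everything mapped to the term or any of its
descendants.  Input is a parent-child TSV plus a mapping TSV; richer OBO
import is an extension point, not implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

__all__ = [
    "OntologyTerm",
    "Ontology",
    "TermMapping",
    "descendants",
    "events_for_term",
    "assays_for_term",
    "load_ontology_tsv",
    "load_mapping_tsv",
]


@dataclass(frozen=True)
class OntologyTerm:
    id: str
    name: str
    parents: frozenset[str] = frozenset()


@dataclass
class Ontology:
    terms: dict[str, OntologyTerm] = field(default_factory=dict)

    def graph(self) -> nx.DiGraph:
        """Parent -> child edges."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for term in self.terms.values():
            for parent in term.parents:
                g.add_edge(parent, term.id)
        return g

    def validate(self) -> None:
        for term in self.terms.values():
            for parent in term.parents:
                if parent not in self.terms:
                    raise ValueError(f"term {term.id!r} has unknown parent {parent!r}")
        if not nx.is_directed_acyclic_graph(self.graph()):
            raise ValueError("ontology contains an is-a cycle")


@dataclass
class TermMapping:
    """term id -> the key events / assays annotated with it."""

    events: dict[str, set[str]] = field(default_factory=dict)
    assays: dict[str, set[str]] = field(default_factory=dict)


def descendants(ontology: Ontology, term_id: str) -> set[str]:
    """All terms below ``term_id`` through is-a links, excluding itself."""
    if term_id not in ontology.terms:
        raise KeyError(f"unknown ontology term {term_id!r}")
    return set(nx.descendants(ontology.graph(), term_id))


def _union_below(mapping: dict[str, set[str]], ontology: Ontology, term_id: str) -> set[str]:
    out: set[str] = set()
    for t in descendants(ontology, term_id) | {term_id}:
        out |= mapping.get(t, set())
    return out


def events_for_term(ontology: Ontology, mapping: TermMapping, term_id: str) -> set[str]:
    """Key events mapped to the term or any descendant term."""
    return _union_below(mapping.events, ontology, term_id)


def assays_for_term(ontology: Ontology, mapping: TermMapping, term_id: str) -> set[str]:
    """Assays mapped to the term or any descendant term."""
    return _union_below(mapping.assays, ontology, term_id)


def load_ontology_tsv(path: str | Path) -> Ontology:
    """TSV columns: term_id, term_name, parent_id (empty for roots; a term
    with several parents repeats its row)."""
    names: dict[str, str] = {}
    parents: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        term_id = cols[0].strip()
        names.setdefault(term_id, cols[1].strip() if len(cols) > 1 and cols[1].strip() else term_id)
        parent = cols[2].strip() if len(cols) > 2 else ""
        parents.setdefault(term_id, set())
        if parent:
            parents[term_id].add(parent)
    ont = Ontology(
        {t: OntologyTerm(t, names[t], frozenset(parents[t])) for t in names}
    )
    ont.validate()
    return ont


def load_mapping_tsv(path: str | Path) -> TermMapping:
    """TSV columns: term_id, target_kind (event|assay), target_id."""
    mapping = TermMapping()
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        term_id, kind, target = (c.strip() for c in line.split("\t")[:3])
        if kind == "event":
            mapping.events.setdefault(term_id, set()).add(target)
        elif kind == "assay":
            mapping.assays.setdefault(term_id, set()).add(target)
        else:
            raise ValueError(f"unknown mapping target kind {kind!r}")
    return mapping
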