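"""Compound neighborhoods: fingerprints, Tanimoto similarity, activity
profiles and neighbor-set comparison.

Similarity is measure dependent, and the measure is therefore pluggable:
the default ``path_default`` scheme hashes linear atom/bond paths of
1..7 atoms over the hydrogen-suppressed molecular graph (aromaticity
aware), while ``alert_based`` is a biological fingerprint — two compounds
are similar if they fire the same structure–activity alerts.  Additional
schemes (e.g. a chemistry toolkit's own circular fingerprints) can be
registered at run time.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable, Iterable

from rdkit import Chem

__all__ = [
    "Compound",
    "Fingerprint",
    "fingerprint",
    "register_scheme",
    "tanimoto",
    "neighbors",
    "activity_profile",
    "compare_neighbor_sets",
    "load_smiles",
]

MAX_PATH_ATOMS = 7

_BOND_TOKEN = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}


@dataclass(frozen=True)
class Compound:
    id: str
    smiles: str
    name: str | None = None


@dataclass(frozen=True)
class Fingerprint:
    bits: frozenset[int]
    scheme: str


def _hash_bit(token: str) -> int:
    return int.from_bytes(hashlib.sha1(token.encode()).digest()[:4], "big")


def _atom_token(atom: Chem.Atom) -> str:
    sym = atom.GetSymbol()
    return sym.lower() if atom.GetIsAromatic() else sym


def _path_tokens(mol: Chem.Mol) -> set[str]:
    """Canonical strings of all linear paths of 1..MAX_PATH_ATOMS atoms."""
    tokens: set[str] = set()
    n = mol.GetNumAtoms()
    adjacency: list[list[tuple[int, str]]] = [[] for _ in range(n)]
    for bond in mol.GetBonds():
        t = _BOND_TOKEN.get(bond.GetBondType(), "~")
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adjacency[i].append((j, t))
        adjacency[j].append((i, t))
    atom_tok = [_atom_token(a) for a in mol.GetAtoms()]

    def walk(path: list[int], text: str) -> None:
        rev = _reverse_path_text(path, text)
        tokens.add(min(text, rev))
        if len(path) == MAX_PATH_ATOMS:
            return
        last = path[-1]
        for nxt, bond_tok in adjacency[last]:
            if nxt not in path:
                walk(path + [nxt], text + bond_tok + atom_tok[nxt])

    def _reverse_path_text(path: list[int], text: str) -> str:
        # rebuild the token string from the reversed atom sequence
        if len(path) == 1:
            return text
        parts = [atom_tok[path[-1]]]
        for a, b in zip(reversed(path[1:]), reversed(path[:-1])):
            tok = next(t for nb, t in adjacency[a] if nb == b)
            parts.append(tok + atom_tok[b])
        return "".join(parts)

    for start in range(n):
        walk([start], atom_tok[start])
    return tokens


def _path_fingerprint(compound: Compound) -> Fingerprint:
    mol = Chem.MolFromSmiles(compound.smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES for {compound.id}: {compound.smiles!r}")
    bits = frozenset(_hash_bit(t) for t in _path_tokens(mol))
    return Fingerprint(bits, "path_default")


_SCHEMES: dict[str, Callable[..., Fingerprint]] = {}


def register_scheme(name: str, fn: Callable[..., Fingerprint]) -> None:
    """Register a fingerprint scheme; ``fn(compound, **kw) -> Fingerprint``."""
    _SCHEMES[name] = fn


register_scheme("path_default", _path_fingerprint)


def _alert_fingerprint(compound: Compound, fired_alerts: Iterable[str] | None = None) -> Fingerprint:
    if fired_alerts is None:
        raise ValueError("alert_based fingerprint needs the compound's fired alert ids")
    bits = frozenset(_hash_bit(a) for a in sorted(set(fired_alerts)))
    return Fingerprint(bits, "alert_based")


register_scheme("alert_based", _alert_fingerprint)


def fingerprint(compound: Compound, scheme: str = "path_default", **kwargs) -> Fingerprint:
    """Compute a compound's fingerprint under a registered scheme."""
    try:
        fn = _SCHEMES[scheme]
    except KeyError:
        raise ValueError(f"unknown fingerprint scheme {scheme!r}") from None
    return fn(compound, **kwargs)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|A n B| / |A u B|; 1.0 when both fingerprints are empty."""
    if a.scheme != b.scheme:
        raise ValueError(f"fingerprint scheme mismatch: {a.scheme} vs {b.scheme}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 1.0
    return len(a.bits & b.bits) / union


def neighbors(
    query: Compound,
    dataset: Iterable[Compound],
    scheme: str = "path_default",
    cutoff: float = 0.5,
    alerts: dict[str, set[str]] | None = None,
) -> list[tuple[Compound, float]]:
    """All dataset compounds with similarity >= cutoff, most similar
    first; ties broken by compound id.  ``alerts`` maps compound id ->
    fired alert ids for the alert_based scheme."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")

    def fp(c: Compound) -> Fingerprint:
        if scheme == "alert_based":
            return fingerprint(c, scheme, fired_alerts=(alerts or {}).get(c.id, set()))
        return fingerprint(c, scheme)

    qfp = fp(query)
    scored = []
    for comp in dataset:
        sim = tanimoto(qfp, fp(comp))
        if sim >= cutoff:
            scored.append((comp, sim))
    scored.sort(key=lambda cs: (-cs[1], cs[0].id))
    return scored


def activity_profile(
    compound_ids: Iterable[str],
    calls_wide,
    assays: Iterable[str],
) -> dict[str, tuple[int, int, float | None]]:
    """Per-assay (n_positive, n_negative, proportion_positive) over a
    compound set.  ``calls_wide`` is a compound x assay table of call text
    ("Positive"/"Negative"/"Conflicted"/NaN); Conflicted and missing calls
    are excluded from both counts, and the proportion is None when no
    informative call exists."""
    ids = [c for c in compound_ids if c in calls_wide.index]
    out: dict[str, tuple[int, int, float | None]] = {}
    for assay in assays:
        if assay in calls_wide.columns and ids:
            col = calls_wide.loc[ids, assay]
            n_pos = int((col == "Positive").sum())
            n_neg = int((col == "Negative").sum())
        else:
            n_pos = n_neg = 0
        total = n_pos + n_neg
        out[assay] = (n_pos, n_neg, n_pos / total if total else None)
    return out


def compare_neighbor_sets(set_a: set[str], set_b: set[str]) -> tuple[int, int, int, int]:
    """(|A only|, |B only|, |A n B|, |A u B|) — the Venn-diagram counts for
    two similarity selections."""
    return (
        len(set_a - set_b),
        len(set_b - set_a),
        len(set_a & set_b),
        len(set_a | set_b),
    )


def load_smiles(path) -> list[Compound]:
    """Read a .smi file: 'SMILES whitespace id' per line, '#' comments."""
    compounds = []
    from pathlib import Path

    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 2)
        smiles = parts[0]
        cid = parts[1] if len(parts) > 1 else smiles
        name = parts[2] if len(parts) > 2 else None
        compounds.append(Compound(cid, smiles, name))
    return compounds
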