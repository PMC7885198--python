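"""The categorical weight-of-evidence argumentation calculus.

Arguments for or against a conclusion carry two three-valued grades: the
intrinsic *convincingness* of the line of argument and the *reliability*
(consistency) of the evidence behind it.  The two grades reduce to a
five-valued argument *strength* (VeryLow .. VeryHigh).  Same-direction
strengths combine through a 5x5 table — weak arguments can reinforce each
other, but only so far — and opposing strengths resolve through a signed
5x5 table in which equally strong opposition balances out; there are no
irrefutable arguments.  Transmission along a key-event relationship takes
the lower of the argument and the connection.

The three lookup tables ship as JSON (``data/calculus_tables.json``) so an
alternative calculus can be loaded; the packaged default is the normative
one, and all operations here are exact table lookups — no numeric scoring
is smuggled in.

Combination of more than two same-direction strengths is *order
sensitive* (the pair table is not associative), so the normative order is
fixed: sort ascending, then fold left.  ``combine_sorted`` implements
exactly that and is the only sanctioned way to reduce an argument list.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .core import BALANCED, AssayTier, Direction, Grade, SignedStrength, StrengthLevel

__all__ = [
    "Argument",
    "ConcernState",
    "WeightedArgument",
    "Calculus",
    "DEFAULT_CALCULUS",
    "strength_of",
    "combine_pair",
    "combine_sorted",
    "oppose",
    "resolve",
    "resolve_signed",
    "transmit",
    "conservative_merge",
    "tiered_merge",
    "weighted_score",
    "TIER_RANK",
    "INFERRED_TIER",
]


# ---------------------------------------------------------------------------
# Argument types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Argument:
    """A signed evidence item.  Strength is always derived from the two
    grades, never stored independently."""

    direction: Direction
    convincingness: Grade
    reliability: Grade
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.direction is Direction.NONE:
            raise ValueError("an argument must point For or Against")


class ConcernState(enum.Enum):
    """Traffic-light call at an event: red / green / grey."""

    CONCERN = "Concern"
    NO_CONCERN = "NoConcern"
    UNKNOWN = "Unknown"


@dataclass(frozen=True)
class WeightedArgument:
    """An expert-weighted argument on a continuous concern scale,
    score -1 (no concern) .. +1 (great concern)."""

    weight: float
    score: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("weight must be nonnegative")
        if not -1.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [-1, +1]")


# ---------------------------------------------------------------------------
# The calculus: three lookup tables
# ---------------------------------------------------------------------------

def _parse_signed(text: str) -> SignedStrength:
    if text == "0":
        return BALANCED
    if text.startswith("-"):
        return SignedStrength(StrengthLevel.from_text(text[1:]), Direction.AGAINST)
    return SignedStrength(StrengthLevel.from_text(text), Direction.FOR)


@dataclass(frozen=True)
class Calculus:
    """An argumentation calculus defined by its three lookup tables."""

    strength_table: dict[tuple[Grade, Grade], StrengthLevel]
    combine_table: dict[tuple[StrengthLevel, StrengthLevel], StrengthLevel]
    oppose_table: dict[tuple[StrengthLevel, StrengthLevel], SignedStrength]

    @classmethod
    def from_dict(cls, spec: dict) -> "Calculus":
        strength = {
            (Grade.from_text(conv), Grade.from_text(rel)): StrengthLevel.from_text(res)
            for rel, row in spec["strength"].items()
            for conv, res in row.items()
        }
        combine = {
            (StrengthLevel.from_text(a), StrengthLevel.from_text(b)): StrengthLevel.from_text(res)
            for a, row in spec["combine"].items()
            for b, res in row.items()
        }
        oppose = {
            (StrengthLevel.from_text(neg), StrengthLevel.from_text(pos)): _parse_signed(res)
            for neg, row in spec["oppose"].items()
            for pos, res in row.items()
        }
        return cls(strength, combine, oppose)

    @classmethod
    def load(cls, path: str | Path | None = None) -> "Calculus":
        if path is None:
            text = resources.files("aopnet.data").joinpath("calculus_tables.json").read_text()
        else:
            text = Path(path).read_text()
        return cls.from_dict(json.loads(text))

    # -- elementary operations ------------------------------------------------

    def strength_of(self, convincingness: Grade, reliability: Grade) -> StrengthLevel:
        return self.strength_table[(convincingness, reliability)]

    def combine_pair(self, a: StrengthLevel, b: StrengthLevel) -> StrengthLevel:
        return self.combine_table[(a, b)]

    def combine_sorted(self, strengths: list[StrengthLevel]) -> StrengthLevel:
        if not strengths:
            raise ValueError("cannot combine an empty list of strengths")
        ordered = sorted(strengths)
        acc = ordered[0]
        for s in ordered[1:]:
            acc = self.combine_pair(acc, s)
        return acc

    def oppose(self, neg: StrengthLevel, pos: StrengthLevel) -> SignedStrength:
        return self.oppose_table[(neg, pos)]

    def transmit(self, argument: StrengthLevel, ker: StrengthLevel) -> StrengthLevel:
        return min(argument, ker)

    # -- resolution -----------------------------------------------------------

    def resolve_signed(self, signed: list[SignedStrength]) -> SignedStrength:
        """Resolve a mixed bag of signed strengths: cancel equal-magnitude
        For/Against pairs, combine the survivors on each side, then oppose
        the two aggregates."""
        pro = sorted(s.magnitude for s in signed if s.direction is Direction.FOR)
        con = sorted(s.magnitude for s in signed if s.direction is Direction.AGAINST)
        # greedy cancellation of equal magnitudes; pairs are interchangeable
        # so the outcome is order independent
        keep_pro: list[StrengthLevel] = []
        keep_con = list(con)
        for m in pro:
            if m in keep_con:
                keep_con.remove(m)
            else:
                keep_pro.append(m)
        if keep_pro and keep_con:
            return self.oppose(self.combine_sorted(keep_con), self.combine_sorted(keep_pro))
        if keep_pro:
            return SignedStrength(self.combine_sorted(keep_pro), Direction.FOR)
        if keep_con:
            return SignedStrength(self.combine_sorted(keep_con), Direction.AGAINST)
        return BALANCED

    def resolve(self, args: list[Argument]) -> SignedStrength:
        signed = [
            SignedStrength(self.strength_of(a.convincingness, a.reliability), a.direction)
            for a in args
        ]
        return self.resolve_signed(signed)


DEFAULT_CALCULUS = Calculus.load()


# Module-level convenience wrappers over the packaged default calculus.

def strength_of(convincingness: Grade, reliability: Grade) -> StrengthLevel:
    """Reduce (convincingness, reliability) to an argument strength."""
    return DEFAULT_CALCULUS.strength_of(convincingness, reliability)


def combine_pair(a: StrengthLevel, b: StrengthLevel) -> StrengthLevel:
    """Combine two same-direction strengths."""
    return DEFAULT_CALCULUS.combine_pair(a, b)


def combine_sorted(strengths: list[StrengthLevel]) -> StrengthLevel:
    """Sort ascending and fold with combine_pair (the normative order)."""
    return DEFAULT_CALCULUS.combine_sorted(strengths)


def oppose(neg: StrengthLevel, pos: StrengthLevel) -> SignedStrength:
    """Resolve an Against magnitude against a For magnitude."""
    return DEFAULT_CALCULUS.oppose(neg, pos)


def resolve(args: list[Argument]) -> SignedStrength:
    """Full resolution of an argument list to one signed conclusion."""
    return DEFAULT_CALCULUS.resolve(args)


def resolve_signed(signed: list[SignedStrength]) -> SignedStrength:
    return DEFAULT_CALCULUS.resolve_signed(signed)


def transmit(argument: StrengthLevel, ker: StrengthLevel) -> StrengthLevel:
    """Transmit a strength along a connection: take the lower value."""
    return DEFAULT_CALCULUS.transmit(argument, ker)


# ---------------------------------------------------------------------------
# Categorical merge paradigms
# ---------------------------------------------------------------------------

def conservative_merge(states: list[ConcernState]) -> ConcernState:
    """Any cause for concern wins; no data at all is Unknown."""
    if ConcernState.CONCERN in states:
        return ConcernState.CONCERN
    if ConcernState.NO_CONCERN in states:
        return ConcernState.NO_CONCERN
    return ConcernState.UNKNOWN


#: Default biological-complexity ranking: measured overrules predicted,
#: whole-organism overrules cell-based.  in_vitro and in_chemico share a
#: rank.  ``INFERRED_TIER`` marks states propagated from upstream events,
#: ranked below everything measured or predicted.
INFERRED_TIER = "inferred"

TIER_RANK: dict[AssayTier | str, int] = {
    AssayTier.HUMAN_OBSERVATION: 4,
    AssayTier.IN_VIVO: 3,
    AssayTier.IN_VITRO: 2,
    AssayTier.IN_CHEMICO: 2,
    AssayTier.IN_SILICO: 1,
    INFERRED_TIER: 0,
}


def tiered_merge(
    evidence: list[tuple[AssayTier | str, ConcernState]],
    tier_rank: dict | None = None,
) -> ConcernState:
    """Assay results overrule predictions: keep only the highest tier with
    an informative state, then merge conservatively within it."""
    ranks = TIER_RANK if tier_rank is None else tier_rank
    informative = [
        (t, s) for t, s in evidence if s is not ConcernState.UNKNOWN
    ]
    if not informative:
        return ConcernState.UNKNOWN
    top = max(ranks[t] for t, _ in informative)
    return conservative_merge([s for t, s in informative if ranks[t] == top])


def weighted_score(
    args: list[WeightedArgument],
    threshold: float = 0.15,
) -> tuple[float, ConcernState]:
    """Weight-normalised mean of argument scores, classified against a
    symmetric equivocation band of +/- ``threshold``."""
    total = sum(a.weight for a in args)
    if total <= 0:
        raise ValueError("weighted_score needs at least one positive weight")
    score = sum(a.weight * a.score for a in args) / total
    if score > threshold:
        state = ConcernState.CONCERN
    elif score < -threshold:
        state = ConcernState.NO_CONCERN
    else:
        state = ConcernState.UNKNOWN
    return score, state
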