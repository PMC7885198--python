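"""The argumentation calculus: table lookups, combination, opposition,
resolution, transmission and the merge paradigms."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aopnet import (
    BALANCED,
    Argument,
    AssayTier,
    ConcernState,
    Direction,
    Grade,
    SignedStrength,
    StrengthLevel,
    WeightedArgument,
    combine_pair,
    combine_sorted,
    conservative_merge,
    oppose,
    resolve,
    resolve_signed,
    strength_of,
    tiered_merge,
    transmit,
    weighted_score,
)

VL, L, M, H, VH = StrengthLevel
S, MED, LG = Grade


def signed(mag, direction=Direction.FOR):
    return SignedStrength(mag, direction)


class TestStrengthOf:
    @pytest.mark.parametrize(
        "conv, rel, expected",
        [(LG, LG, VH), (S, S, VL), (S, LG, M), (LG, S, M), (MED, MED, M), (MED, LG, H)],
    )
    def test_published_cells(self, conv, rel, expected):
        assert strength_of(conv, rel) == expected

    def test_symmetric_in_grades(self):
        for conv, rel in itertools.product(Grade, Grade):
            assert strength_of(conv, rel) == strength_of(rel, conv)


class TestCombine:
    @pytest.mark.parametrize(
        "a, b, expected", [(VL, VL, L), (M, VL, M), (L, L, M), (H, H, VH), (VL, M, M)]
    )
    def test_published_cells(self, a, b, expected):
        assert combine_pair(a, b) == expected

    def test_commutative_and_monotone(self):
        for a, b in itertools.product(StrengthLevel, StrengthLevel):
            assert combine_pair(a, b) == combine_pair(b, a)
            assert combine_pair(a, b) >= max(a, b)

    def test_very_high_absorbing(self):
        for a in StrengthLevel:
            assert combine_pair(VH, a) == VH

    def test_weak_arguments_do_not_enhance_strong_ones(self):
        # very-low never lifts medium and above; low never lifts high and above
        assert combine_pair(M, VL) == M
        assert combine_pair(H, VL) == H
        assert combine_pair(VH, VL) == VH
        assert combine_pair(H, L) == H
        assert combine_pair(VH, L) == VH

    def test_not_associative_witness(self):
        # the pair table is deliberately folded in sorted order because it
        # is not associative: (VL+VL)+M != VL+(VL+M)
        left = combine_pair(combine_pair(VL, VL), M)
        right = combine_pair(VL, combine_pair(VL, M))
        assert left == H and right == M

    def test_sorted_fold(self):
        assert combine_sorted([VL, VL, VL, VL]) == M
        assert combine_sorted([VL, VL, M]) == H
        for x in StrengthLevel:
            assert combine_sorted([x]) == x
        with pytest.raises(ValueError):
            combine_sorted([])

    def test_sorted_fold_order_invariant(self):
        for perm in itertools.permutations([M, VL, VL]):
            assert combine_sorted(list(perm)) == H


class TestOppose:
    @pytest.mark.parametrize(
        "neg, pos, expected",
        [
            (M, M, BALANCED),
            (H, M, signed(M, Direction.AGAINST)),
            (VL, M, signed(L, Direction.FOR)),
            (VH, VH, BALANCED),
        ],
    )
    def test_published_cells(self, neg, pos, expected):
        assert oppose(neg, pos) == expected

    def test_antisymmetric_under_sign_swap(self):
        for neg, pos in itertools.product(StrengthLevel, StrengthLevel):
            assert oppose(neg, pos) == oppose(pos, neg).negate()

    def test_diagonal_balanced(self):
        for x in StrengthLevel:
            assert oppose(x, x) == BALANCED

    def test_no_irrefutable_arguments(self):
        # even the strongest argument is offset by an equal counterargument
        assert oppose(VH, VH) == BALANCED

    def test_not_monotone_implemented_literally(self):
        # the published opposition table is not monotone in the For column;
        # it is applied literally, without smoothing
        assert oppose(VH, H) == signed(H, Direction.AGAINST)
        assert oppose(VH, M) == signed(VH, Direction.AGAINST)


class TestResolve:
    def test_worked_opposing_example(self):
        # -M and +M cancel, leaving the lone +L
        out = resolve_signed(
            [signed(M, Direction.AGAINST), signed(M, Direction.FOR), signed(L, Direction.FOR)]
        )
        assert out == signed(L, Direction.FOR)

    def test_empty_is_balanced(self):
        assert resolve([]) == BALANCED

    def test_cancel_leaves_survivor(self):
        out = resolve_signed(
            [signed(VL), signed(VL), signed(VL, Direction.AGAINST)]
        )
        assert out == signed(VL, Direction.FOR)

    def test_single_argument_identity(self):
        for conv, rel in itertools.product(Grade, Grade):
            for d in (Direction.FOR, Direction.AGAINST):
                arg = Argument(d, conv, rel)
                assert resolve([arg]) == signed(strength_of(conv, rel), d)

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(list(StrengthLevel)),
                st.sampled_from([Direction.FOR, Direction.AGAINST]),
            ),
            max_size=7,
        ),
        st.randoms(use_true_random=False),
    )
    def test_permutation_invariant(self, items, rnd):
        args = [signed(m, d) for m, d in items]
        shuffled = list(args)
        rnd.shuffle(shuffled)
        assert resolve_signed(args) == resolve_signed(shuffled)


class TestTransmit:
    @pytest.mark.parametrize("arg, ker, expected", [(M, L, L), (H, VH, H), (L, L, L)])
    def test_takes_the_lower_value(self, arg, ker, expected):
        assert transmit(arg, ker) == expected

    def test_lattice_meet(self):
        for a, b in itertools.product(StrengthLevel, StrengthLevel):
            assert transmit(a, b) == transmit(b, a) == min(a, b)
            assert transmit(a, a) == a


class TestCategoricalMerges:
    def test_conservative_concern_wins(self):
        assert (
            conservative_merge([ConcernState.CONCERN, ConcernState.NO_CONCERN])
            == ConcernState.CONCERN
        )
        assert (
            conservative_merge([ConcernState.NO_CONCERN, ConcernState.NO_CONCERN])
            == ConcernState.NO_CONCERN
        )
        assert conservative_merge([]) == ConcernState.UNKNOWN

    @pytest.mark.parametrize(
        "evidence, expected",
        [
            ([(AssayTier.IN_VITRO, ConcernState.NO_CONCERN), (AssayTier.IN_SILICO, ConcernState.CONCERN)],
             ConcernState.NO_CONCERN),
            ([(AssayTier.IN_VIVO, ConcernState.NO_CONCERN), (AssayTier.IN_VITRO, ConcernState.CONCERN)],
             ConcernState.NO_CONCERN),
            ([(AssayTier.IN_SILICO, ConcernState.CONCERN)], ConcernState.CONCERN),
            ([], ConcernState.UNKNOWN),
        ],
    )
    def test_tiered_overruling(self, evidence, expected):
        assert tiered_merge(evidence) == expected

    def test_tiered_equal_rank_merges_conservatively(self):
        # in vitro and in chemico share a rank: disagreement is a concern
        evidence = [
            (AssayTier.IN_VITRO, ConcernState.NO_CONCERN),
            (AssayTier.IN_CHEMICO, ConcernState.CONCERN),
        ]
        assert tiered_merge(evidence) == ConcernState.CONCERN


class TestWeightedScore:
    def test_expert_weighting(self):
        score, _ = weighted_score(
            [WeightedArgument(75, -1), WeightedArgument(23, 1), WeightedArgument(2, 1)]
        )
        assert score == pytest.approx(-0.5)

    def test_weighting_can_flip_the_call(self):
        # same three argument directions, different expert weights
        heavy_human = [WeightedArgument(75, -1), WeightedArgument(23, 1), WeightedArgument(2, 1)]
        balanced = [WeightedArgument(50, -1), WeightedArgument(40, 1), WeightedArgument(10, 1)]
        _, state_a = weighted_score(heavy_human)
        _, state_b = weighted_score(balanced)
        assert state_a == ConcernState.NO_CONCERN
        assert state_b == ConcernState.UNKNOWN

    def test_symmetry_and_unanimity(self):
        score, state = weighted_score([WeightedArgument(1, 1), WeightedArgument(1, -1)])
        assert score == 0 and state == ConcernState.UNKNOWN
        score, state = weighted_score([WeightedArgument(3, 1), WeightedArgument(1, 1)])
        assert score == 1 and state == ConcernState.CONCERN

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_score([WeightedArgument(0, 1)])


def test_signed_carrier_has_eleven_positions():
    carrier = SignedStrength.carrier()
    assert len(carrier) == len(set(carrier)) == 11
    assert BALANCED in carrier


def test_argument_must_have_direction():
    with pytest.raises(ValueError):
        Argument(Direction.NONE, Grade.SMALL, Grade.SMALL)
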