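"""Event-pair relations, edit cost (minimum cover), and move sets."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seqhet import (
    ABSENT,
    Direction,
    PairRelation,
    RankedSequence,
    changed_pairs,
    minimum_move_sets,
    pair_relation,
    parsimov_cost,
    presence_changes,
)
from seqhet.parsimov import majority_moves

from conftest import brute_force_parsimov_cost, make_seq

A, B, C, D = 1, 2, 3, 4


def random_pair(rng, n_events, absent_prob=0.15):
    def one():
        ranks = {}
        for e in range(1, n_events + 1):
            if rng.random() < absent_prob:
                ranks[e] = ABSENT
            else:
                ranks[e] = int(rng.integers(1, n_events + 1))
        return RankedSequence.from_ranks(ranks)

    return one(), one()


class TestPairRelation:
    def test_before_simultaneous_undefined(self):
        seq = make_seq(A=1, B=2, C=2, D=None)
        assert pair_relation(seq, A, B) == PairRelation.BEFORE
        assert pair_relation(seq, B, A) == PairRelation.AFTER
        assert pair_relation(seq, B, C) == PairRelation.SIMULTANEOUS
        assert pair_relation(seq, A, D) == PairRelation.UNDEFINED

    def test_rejects_same_event_and_unknown_event(self):
        seq = make_seq(A=1, B=2)
        with pytest.raises(ValueError):
            pair_relation(seq, A, A)
        with pytest.raises(KeyError):
            pair_relation(seq, A, 99)


class TestChangedPairs:
    def test_identity_and_single_inversion(self):
        s = make_seq(A=1, B=2)
        assert changed_pairs(s, s) == set()
        assert changed_pairs(s, make_seq(A=2, B=1)) == {frozenset({A, B})}

    def test_one_event_relocation_changes_its_pairs_only(self):
        s1 = make_seq(A=1, B=2, C=3, D=4)
        s2 = make_seq(D=1, A=2, B=3, C=4)
        assert changed_pairs(s1, s2) == {
            frozenset({A, D}), frozenset({B, D}), frozenset({C, D})
        }

    def test_absent_pairs_never_reported(self):
        s1 = make_seq(A=1, B=2, C=3)
        s2 = make_seq(A=2, B=1, C=None)
        assert changed_pairs(s1, s2) == {frozenset({A, B})}


class TestParsimovCost:
    @pytest.mark.parametrize(
        "s1, s2, cost",
        [
            (dict(A=1, B=2, C=3, D=4), dict(A=1, B=2, C=3, D=4), 0),
            (dict(A=1, B=2, C=3, D=4), dict(D=1, A=2, B=3, C=4), 1),
            (dict(A=1, B=2, C=3, D=4), dict(B=1, A=2, D=3, C=4), 2),
        ],
    )
    def test_frozen_examples(self, s1, s2, cost):
        assert parsimov_cost(make_seq(**s1), make_seq(**s2)) == cost

    def test_symmetric_zero_on_self_and_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b = random_pair(rng, 8)
            c = parsimov_cost(a, b)
            assert c == parsimov_cost(b, a)
            assert parsimov_cost(a, a) == 0
            assert c <= len(a.present_ids)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(2, 11))
            a, b = random_pair(rng, n)
            assert parsimov_cost(a, b) == brute_force_parsimov_cost(a, b)

    def test_marking_an_event_absent_never_raises_cost(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a, b = random_pair(rng, 8, absent_prob=0.0)
            base = parsimov_cost(a, b)
            e = int(rng.integers(1, 9))
            ranks = dict(a.ranks)
            ranks[e] = ABSENT
            a2 = RankedSequence.from_ranks(ranks)
            assert parsimov_cost(a2, b) <= base


class TestMinimumMoveSets:
    def test_identity_yields_single_empty_set(self):
        s = make_seq(A=1, B=2)
        sets = minimum_move_sets(s, s)
        assert len(sets) == 1 and len(sets[0]) == 0

    def test_swap_has_two_singleton_explanations_with_directions(self):
        got = minimum_move_sets(make_seq(A=1, B=2), make_seq(B=1, A=2))
        moves = {tuple(ms.moves)[0] for ms in got}
        assert moves == {(A, Direction.DELAYED), (B, Direction.ACCELERATED)}

    def test_unique_cover_with_acceleration(self):
        got = minimum_move_sets(
            make_seq(A=1, B=2, C=3, D=4), make_seq(D=1, A=2, B=3, C=4)
        )
        assert len(got) == 1
        assert got[0].moves == frozenset({(D, Direction.ACCELERATED)})

    def test_rejects_cap_below_one(self):
        s = make_seq(A=1, B=2)
        with pytest.raises(ValueError):
            minimum_move_sets(s, s, cap=0)

    def test_all_sets_are_minimum_covers_and_complete(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b = random_pair(rng, 7)
            cost = parsimov_cost(a, b)
            sets = minimum_move_sets(a, b, cap=500)
            pairs = [set(p) for p in changed_pairs(a, b)]
            assert all(len(ms) == cost for ms in sets)
            for ms in sets:
                ids = ms.event_ids
                assert all(p & ids for p in pairs)

    def test_majority_moves_agrees_with_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            a, b = random_pair(rng, 7)
            sets = minimum_move_sets(a, b, cap=5000)
            votes = {}
            for ms in sets:
                for e, d in ms.moves:
                    votes[(e, d)] = votes.get((e, d), 0) + 1
            expected = {ed for ed, v in votes.items() if 2 * v > len(sets)}
            assert majority_moves(a, b) == expected


class TestPresenceChanges:
    def test_loss_and_gain_are_reported_separately(self):
        a = make_seq(A=1, B=2, C=3)
        b = make_seq(A=1, B=None, C=2)
        assert presence_changes(a, b) == {B: "loss"}
        assert presence_changes(b, a) == {B: "gain"}


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, derandomize=True, deadline=None)
def test_cost_is_metric_like_on_random_triples(seed):
    """Symmetry and identity hold for arbitrary random sequence pairs."""
    rng = np.random.default_rng(seed)
    a, b = random_pair(rng, 6)
    assert parsimov_cost(a, b) == parsimov_cost(b, a) >= 0
    assert (parsimov_cost(a, b) == 0) == (len(changed_pairs(a, b)) == 0)
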