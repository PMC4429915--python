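"""Majority-rule consensus: records, supports, mean-rank ancestors."""

import pytest

from seqhet import (
    ABSENT,
    ConsensusTree,
    Direction,
    HeterochronyRecord,
    Phylogeny,
    RankedSequence,
    SolutionPool,
    TreeSolution,
    mean_rank_ancestors,
    pseudoconsensus,
    solution_heterochronies,
    superconsensus,
)
from seqhet.sequence import RankMatrix

from conftest import make_seq

A, B, C, D = 1, 2, 3, 4


@pytest.fixture
def cherry():
    """Two tips below one ancestor; the simplest consensus arena."""
    tree = Phylogeny(root="r", children={"r": ("a", "b")})
    tips = RankMatrix.from_rows(
        [("a", make_seq(A=1, B=2, C=3, D=4).ranks),
         ("b", make_seq(D=1, A=2, B=3, C=4).ranks)]
    )
    return tree, tips


def solution(tree, **node_ranks):
    return TreeSolution({n: RankedSequence.from_ranks(r) for n, r in node_ranks.items()}, 0)


def pool_of(tree, solutions, cost=0):
    sols = [TreeSolution(s.node_sequences, cost) for s in solutions]
    return SolutionPool(best_cost=cost, solutions=sols, tree=tree)


class TestSolutionHeterochronies:
    def test_zero_cost_branch_is_empty(self, cherry):
        tree, tips = cherry
        sol = solution(tree, r=make_seq(A=1, B=2, C=3, D=4).ranks)
        het = solution_heterochronies(sol, tips, tree)
        assert het[("r", "a")] == set()

    def test_unique_cover_is_reported_with_direction(self, cherry):
        tree, tips = cherry
        sol = solution(tree, r=make_seq(A=1, B=2, C=3, D=4).ranks)
        het = solution_heterochronies(sol, tips, tree)
        assert het[("r", "b")] == {(D, Direction.ACCELERATED)}

    def test_two_disjoint_singleton_covers_reach_no_majority(self):
        tree = Phylogeny(root="r", children={"r": ("a",)})
        tips = RankMatrix.from_rows([("a", make_seq(B=1, A=2).ranks)])
        sol = solution(tree, r=make_seq(A=1, B=2).ranks)
        het = solution_heterochronies(sol, tips, tree)
        assert het[("r", "a")] == set()  # {A} and {B} split the vote 1/2 each


class TestPseudoconsensus:
    def make_pool(self, cherry, root_seqs):
        tree, tips = cherry
        sols = [solution(tree, r=s.ranks) for s in root_seqs]
        return pool_of(tree, sols), tips

    def test_majority_support_arithmetic(self, cherry):
        tree, tips = cherry
        base = make_seq(A=1, B=2, C=3, D=4)
        other = make_seq(D=1, A=2, B=3, C=4)  # equals tip b: zero-cost branch
        pool, tips = self.make_pool(cherry, [base, base, other])
        cons = pseudoconsensus(pool, tips)
        on_b = {(r.event_id, round(r.support, 1)) for r in cons.records_on(("r", "b"))}
        # (D, accelerated) in the two 'base' solutions only: 2/3 = 66.7%
        assert on_b == {(D, 66.7)}
        # the third solution's move (on branch r->a) is 1/3 and dropped
        assert cons.records_on(("r", "a")) == []

    def test_unanimous_records_have_full_support(self, cherry):
        base = make_seq(A=1, B=2, C=3, D=4)
        pool, tips = self.make_pool(cherry, [base, base, base])
        cons = pseudoconsensus(pool, tips)
        assert all(r.support == 100.0 for r in cons.records)
        assert {(r.event_id, r.direction) for r in cons.records_on(("r", "b"))} == {
            (D, Direction.ACCELERATED)
        }

    def test_minority_records_are_dropped(self, cherry):
        tree, tips = cherry
        s1 = make_seq(A=1, B=2, C=3, D=4)     # explains branch b by moving D
        s2 = make_seq(D=1, A=2, B=3, C=4)     # explains branch a by moving D
        s3 = make_seq(A=1, D=1, B=2, C=3)
        pool, tips = self.make_pool(cherry, [s1, s2, s3])
        cons = pseudoconsensus(pool, tips)
        for r in cons.records:
            assert r.support > 50.0

    def test_empty_pool_rejected(self, cherry):
        tree, tips = cherry
        with pytest.raises(ValueError):
            pseudoconsensus(SolutionPool(0, [], tree), tips)


class TestSuperconsensus:
    def test_single_pool_equals_pseudoconsensus(self, cherry):
        tree, tips = cherry
        base = make_seq(A=1, B=2, C=3, D=4)
        pool = pool_of(tree, [solution(tree, r=base.ranks)])
        a = pseudoconsensus(pool, tips)
        b = superconsensus([pool], tips)
        assert a.records == b.records
        assert a.ancestral_sequences == b.ancestral_sequences

    def test_mean_tree_length_of_published_run_lengths(self, cherry):
        tree, tips = cherry
        base = make_seq(A=1, B=2, C=3, D=4)
        pools = [
            pool_of(tree, [solution(tree, r=base.ranks)], cost=c)
            for c in (101, 100, 98)
        ]
        cons = superconsensus(pools, tips)
        assert cons.run_tree_lengths == [101, 100, 98]
        assert round(cons.mean_tree_length, 2) == 99.67

    def test_identical_pools_keep_full_support(self, cherry):
        tree, tips = cherry
        base = make_seq(A=1, B=2, C=3, D=4)
        pool = pool_of(tree, [solution(tree, r=base.ranks)])
        cons = superconsensus([pool, pool, pool], tips)
        assert all(r.support == 100.0 for r in cons.records)

    def test_rejects_pools_over_different_trees(self, cherry):
        tree, tips = cherry
        other_tree = Phylogeny(root="r", children={"r": ("b", "a")})
        base = make_seq(A=1, B=2, C=3, D=4)
        p1 = pool_of(tree, [solution(tree, r=base.ranks)])
        p2 = pool_of(other_tree, [solution(other_tree, r=base.ranks)])
        with pytest.raises(ValueError, match="different trees"):
            superconsensus([p1, p2], tips)


class TestMeanRankAncestors:
    def test_single_solution_is_idempotent(self):
        s = solution(None, r=make_seq(A=1, B=2, C=2).ranks, x=make_seq(C=1, A=2, B=2).ranks)
        anc = mean_rank_ancestors([s])
        assert anc == dict(s.node_sequences)

    def test_means_order_events(self):
        s1 = solution(None, r=make_seq(A=2, B=1, C=3).ranks)
        s2 = solution(None, r=make_seq(A=3, B=2, C=1).ranks)
        anc = mean_rank_ancestors([s1, s2])
        # means: A 2.5, B 1.5, C 2.0 -> order B < C < A
        assert anc["r"] == make_seq(B=1, C=2, A=3)

    def test_exact_mean_ties_and_densification(self):
        s1 = solution(None, r=make_seq(A=1, B=2, C=3).ranks)
        s2 = solution(None, r=make_seq(A=2, B=1, C=3).ranks)
        anc = mean_rank_ancestors([s1, s2])
        # means: A 1.5, B 1.5, C 3.0 -> {A:1, B:1, C:2}
        assert anc["r"] == make_seq(A=1, B=1, C=2)

    def test_absent_anywhere_stays_absent(self):
        s1 = solution(None, r=make_seq(A=1, B=2, C=3).ranks)
        s2 = solution(None, r=make_seq(A=1, B=2, C=None).ranks)
        anc = mean_rank_ancestors([s1, s2])
        assert anc["r"].rank(C) is ABSENT

    def test_order_invariance(self):
        sols = [
            solution(None, r=make_seq(A=1, B=2, C=3).ranks),
            solution(None, r=make_seq(C=1, B=2, A=3).ranks),
            solution(None, r=make_seq(B=1, A=2, C=2).ranks),
        ]
        assert mean_rank_ancestors(sols) == mean_rank_ancestors(sols[::-1])


class TestRecordValidation:
    def test_support_must_exceed_majority_threshold(self):
        with pytest.raises(ValueError):
            HeterochronyRecord(("r", "a"), 1, Direction.DELAYED, support=50.0)
        with pytest.raises(ValueError):
            HeterochronyRecord(("r", "a"), 1, Direction.DELAYED, support=100.5)
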