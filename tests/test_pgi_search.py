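"""GA ancestral-sequence search against exhaustive oracles on tiny instances."""

import itertools

import numpy as np
import pytest

from seqhet import (
    ABSENT,
    Dataset,
    FAST_PARAMS,
    Phylogeny,
    RankedSequence,
    SearchParams,
    exhaustive_tree_search,
    node_fitness,
    optimize_node,
    optimize_tree,
    parsimov_cost,
)
from seqhet.sequence import RankMatrix

from conftest import make_seq


def tiny_dataset(rows, children):
    return Dataset(matrix=RankMatrix.from_rows(rows), tree=Phylogeny(root="r", children=children))


def all_canonical_seqs(event_ids):
    n = len(event_ids)
    for combo in itertools.product(range(1, n + 1), repeat=n):
        k = max(combo)
        if set(combo) == set(range(1, k + 1)):
            yield RankedSequence(dict(zip(event_ids, combo)))


class TestSearchParams:
    def test_defaults_are_the_analysis_settings(self):
        p = SearchParams()
        assert (p.cycles_per_node, p.population, p.retain_per_node, p.solution_cap) == (
            100, 200, 100, 3000,
        )

    def test_rejects_retain_above_population(self):
        with pytest.raises(ValueError):
            SearchParams(population=10, retain_per_node=20)


class TestNodeFitness:
    def test_zero_against_identical_neighbours(self):
        s = make_seq(A=1, B=2, C=3)
        assert node_fitness(s, [s, s, s]) == 0

    def test_single_inverted_pair_costs_one(self):
        assert node_fitness(make_seq(A=1, B=2), [make_seq(B=1, A=2)]) == 1

    def test_additive_over_identical_neighbours(self):
        a, b = make_seq(A=1, B=2, C=3, D=4), make_seq(B=1, A=2, D=3, C=4)
        c = parsimov_cost(a, b)
        assert node_fitness(a, [b, b]) == 2 * c

    def test_requires_neighbours(self):
        with pytest.raises(ValueError):
            node_fitness(make_seq(A=1), [])


class TestOptimizeNode:
    def test_identical_neighbours_recover_shared_sequence(self):
        s = make_seq(A=1, B=2, C=3)
        got = optimize_node(s, [s, s], FAST_PARAMS, np.random.default_rng(0))
        assert s in got
        assert all(node_fitness(g, [s, s]) == 0 for g in got)

    def test_matches_exhaustive_scan_on_three_events(self):
        n1 = make_seq(A=1, B=2, C=3)
        n2 = make_seq(B=1, A=2, C=3)
        neighbors = [n1, n1, n2]
        best = min(node_fitness(s, neighbors) for s in all_canonical_seqs((1, 2, 3)))
        got = optimize_node(n1, neighbors, FAST_PARAMS, np.random.default_rng(1))
        assert best == 1
        assert n1 in got
        assert all(node_fitness(g, neighbors) == best for g in got)

    def test_seeded_determinism(self):
        n1, n2 = make_seq(A=1, B=2, C=3, D=4), make_seq(D=1, C=2, B=3, A=4)
        runs = [
            optimize_node(n1, [n1, n2], FAST_PARAMS, np.random.default_rng(5))
            for _ in range(2)
        ]
        assert runs[0] == runs[1]


class TestOptimizeTree:
    def test_identical_tips_give_zero_cost(self):
        s = {1: 1, 2: 2, 3: 2, 4: 3}
        ds = tiny_dataset(
            [(t, dict(s)) for t in ("a", "b", "c", "d")],
            {"r": ("a", "x"), "x": ("b", "y"), "y": ("c", "d")},
        )
        pool = optimize_tree(ds, FAST_PARAMS.with_seed(0))
        assert pool.best_cost == 0
        expected = RankedSequence.from_ranks(s)
        for sol in pool.solutions:
            for node_seq in sol.node_sequences.values():
                assert node_seq == expected

    def test_clade_inversion_matches_exhaustive_optimum(self):
        base = dict(A=1, B=2, C=3, D=4)
        inverted = dict(B=1, A=2, C=3, D=4)
        ds = tiny_dataset(
            [("a", make_seq(**base).ranks), ("b", make_seq(**base).ranks),
             ("c", make_seq(**inverted).ranks), ("d", make_seq(**inverted).ranks)],
            {"r": ("x", "y"), "x": ("a", "b"), "y": ("c", "d")},
        )
        oracle = exhaustive_tree_search(ds)
        pool = optimize_tree(ds, FAST_PARAMS.with_seed(3))
        assert oracle.best_cost == 1
        assert pool.best_cost == oracle.best_cost

    def test_sweep_costs_never_increase(self, paper_ds):
        pool = optimize_tree(paper_ds, FAST_PARAMS.with_seed(2))
        assert all(b <= a for a, b in zip(pool.sweep_costs, pool.sweep_costs[1:]))

    def test_never_worse_than_outgroup_everywhere_baseline(self, paper_ds):
        out_seq = paper_ds.matrix[paper_ds.outgroup]
        def seq_of(n):
            return paper_ds.matrix[n] if paper_ds.tree.is_tip(n) else out_seq
        baseline = sum(
            parsimov_cost(seq_of(p), seq_of(c)) for p, c in paper_ds.tree.branches
        )
        pool = optimize_tree(paper_ds, FAST_PARAMS.with_seed(4))
        assert pool.best_cost <= baseline

    def test_seeded_reproducibility(self):
        ds = tiny_dataset(
            [("a", {1: 1, 2: 2, 3: 3}), ("b", {1: 2, 2: 1, 3: 3}),
             ("c", {1: 1, 2: 1, 3: 2}), ("d", {1: 3, 2: 2, 3: 1})],
            {"r": ("a", "x"), "x": ("b", "y"), "y": ("c", "d")},
        )
        p1 = optimize_tree(ds, FAST_PARAMS.with_seed(9))
        p2 = optimize_tree(ds, FAST_PARAMS.with_seed(9))
        assert p1.best_cost == p2.best_cost
        assert [s.node_sequences for s in p1.solutions] == [s.node_sequences for s in p2.solutions]

    def test_tree_matrix_mismatch_rejected(self):
        with pytest.raises(ValueError, match="disagree"):
            Dataset(
                matrix=RankMatrix.from_rows([("a", {1: 1}), ("b", {1: 1})]),
                tree=Phylogeny(root="r", children={"r": ("a", "zz")}),
            )


class TestExhaustiveOracle:
    def test_two_tip_identical_is_zero(self):
        ds = tiny_dataset(
            [("a", {1: 1, 2: 2}), ("b", {1: 1, 2: 2})], {"r": ("a", "b")}
        )
        assert exhaustive_tree_search(ds).best_cost == 0

    def test_star_tree_matches_hand_enumeration(self):
        tips = [("a", {1: 1, 2: 2, 3: 3}), ("b", {1: 2, 2: 1, 3: 3}), ("c", {1: 1, 2: 2, 3: 3})]
        ds = tiny_dataset(tips, {"r": ("a", "b", "c")})
        seqs = {t: RankedSequence.from_ranks(dict(r)) for t, r in tips}
        best = min(
            sum(parsimov_cost(cand, s) for s in seqs.values())
            for cand in all_canonical_seqs((1, 2, 3))
        )
        assert exhaustive_tree_search(ds).best_cost == best == 1

    def test_refuses_oversized_instances(self):
        ds = tiny_dataset(
            [("a", {e: e for e in range(1, 8)}), ("b", {e: e for e in range(1, 8)})],
            {"r": ("a", "b")},
        )
        with pytest.raises(ValueError, match="too large"):
            exhaustive_tree_search(ds)
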