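"""Genetic-algorithm reconstruction of ancestral developmental sequences.

The whole event sequence is treated as a single complex character: each
internal node of a rooted phylogeny is assigned a complete canonical ranked
sequence, and a tree solution is scored by the sum of Parsimov edit costs
over all branches (tips contribute their observed sequences).  A per-node GA
(selection over a candidate population built by crossover and mutation)
minimises the local cost against the node's current neighbours; nodes are
revisited in alternating post-/pre-order sweeps until a sweep brings no
improvement.  Finally the retained co-optimal candidates of every node are
combined: because the total cost decomposes over branches, the minimum-cost
combinations are found exactly by dynamic programming over the tree and
enumerated (up to ``solution_cap``) by backtracking through the ties.

Ancestral candidates always carry every event that is present in at least
one tip: since pairs with an absent event are undefined and contribute no
cost, a search allowed to drop events would trivially empty every ancestor.
Presence/absence evolution is reported separately (see
:func:`seqhet.parsimov.presence_changes`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .nexus import Dataset
from .parsimov import PairTable
from .sequence import RankedSequence, canonicalize_array
from .tree import Phylogeny

__all__ = [
    "SearchParams",
    "FAST_PARAMS",
    "TreeSolution",
    "SolutionPool",
    "node_fitness",
    "optimize_node",
    "optimize_tree",
    "exhaustive_tree_search",
]


@dataclass(frozen=True)
class SearchParams:
    """GA settings; the defaults are the analysis defaults used throughout.

    cycles_per_node
        Selection cycles each time a node is visited.
    population
        Candidate sequences evaluated per cycle.
    retain_per_node
        Maximum number of co-optimal ancestral sequences kept at a node.
    solution_cap
        Maximum number of equal-score whole-tree solutions collected.
    max_sweeps
        Upper bound on alternating post-/pre-order sweeps.
    """

    cycles_per_node: int = 100
    population: int = 200
    retain_per_node: int = 100
    solution_cap: int = 3000
    max_sweeps: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cycles_per_node", "population", "retain_per_node", "solution_cap", "max_sweeps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.retain_per_node > self.population:
            raise ValueError("retain_per_node must not exceed population")

    def with_seed(self, seed: int) -> "SearchParams":
        return replace(self, seed=seed)


#: Reduced-effort profile for quick runs and continuous testing.
FAST_PARAMS = SearchParams(cycles_per_node=20, population=50, retain_per_node=20, solution_cap=200)


@dataclass(frozen=True)
class TreeSolution:
    """One assignment of ancestral sequences to all internal nodes."""

    node_sequences: Dict[str, RankedSequence]
    total_cost: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "node_sequences", dict(self.node_sequences))


@dataclass
class SolutionPool:
    """Equally most-parsimonious tree solutions collected in one run."""

    best_cost: int
    solutions: List[TreeSolution]
    tree: Phylogeny
    sweep_costs: List[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.solutions)


# ---------------------------------------------------------------------------
# public per-node API
# ---------------------------------------------------------------------------

def node_fitness(candidate: RankedSequence, neighbor_seqs: Sequence[RankedSequence]) -> int:
    """Sum of Parsimov costs from a candidate to each neighbour sequence."""
    if not neighbor_seqs:
        raise ValueError("node_fitness requires at least one neighbour")
    universe = tuple(sorted(candidate.event_ids))
    table = PairTable(universe)
    cand = candidate.to_array(universe)
    return sum(table.cost(cand, nb.to_array(universe)) for nb in neighbor_seqs)


def optimize_node(
    candidate: RankedSequence,
    neighbor_seqs: Sequence[RankedSequence],
    params: SearchParams,
    rng: np.random.Generator,
) -> List[RankedSequence]:
    """GA over ancestral candidates for a single node.

    Returns all co-optimal sequences found (at most ``retain_per_node``),
    each minimising :func:`node_fitness` against the fixed neighbours; the
    optimum is never worse than the incumbent ``candidate``.
    """
    if not neighbor_seqs:
        raise ValueError("optimize_node requires at least one neighbour")
    universe = tuple(sorted(candidate.event_ids))
    table = PairTable(universe)
    incumbent = candidate.to_array(universe)
    neighbors = [nb.to_array(universe) for nb in neighbor_seqs]
    active = np.flatnonzero(incumbent > 0)
    retained, best = _ga_node(incumbent, neighbors, active, table, params, rng)
    co_optimal = [
        a for a in retained if sum(table.cost(a, nb) for nb in neighbors) == best
    ]
    return [RankedSequence.from_array(a, universe) for a in co_optimal]


# ---------------------------------------------------------------------------
# GA internals (array representation; 0 = absent)
# ---------------------------------------------------------------------------

#: a node's GA stops early after this many cycles without any change to the
#: retained elite — selection has converged and further cycles only resample
_STAGNATION_CYCLES = 10


def _mutate(arr: np.ndarray, active: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Move one event; works on a doubled rank scale so that a move can
    either join an existing level (even target) or split out into a new
    level between two existing ones (odd target)."""
    out = arr.astype(np.int32) * 2
    e = int(active[rng.integers(len(active))])
    k2 = 2 * int(arr.max())
    if rng.random() < 0.5:
        # nudge by one half-step or one full level
        out[e] += int(rng.choice((-2, -1, 1, 2)))
    else:
        # relocate anywhere (odd = between levels, even = join a level)
        out[e] = int(rng.integers(1, k2 + 2))
    out[e] = max(out[e], 1)
    out[arr == 0] = 0
    return canonicalize_array(out).astype(np.int16)


def _crossover(a: np.ndarray, b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    pick = rng.random(a.shape[0]) < 0.5
    child = np.where(pick, a, b).astype(np.int16)
    return canonicalize_array(child)


def _ga_node(
    incumbent: np.ndarray,
    neighbors: List[np.ndarray],
    active: np.ndarray,
    table: PairTable,
    params: SearchParams,
    rng: np.random.Generator,
) -> Tuple[List[np.ndarray], int]:
    """Returns (retained arrays sorted by fitness then key, best fitness).

    The retained set holds the ``retain_per_node`` best candidates seen, not
    only the co-optimal ones: near-optimal local candidates are what lets
    the whole-tree combination step coordinate changes across nodes that
    per-node descent cannot make on its own.
    """

    def fitness(arr: np.ndarray) -> int:
        return sum(table.cost(arr, nb) for nb in neighbors)

    # elite: key -> (fitness, arr), pruned to retain_per_node each cycle
    elite: Dict[bytes, Tuple[int, np.ndarray]] = {}

    def consider(arr: np.ndarray) -> None:
        key = arr.tobytes()
        if key not in elite:
            elite[key] = (fitness(arr), arr)

    consider(incumbent)
    # seed with the neighbours themselves (absences filled from the incumbent)
    for nb in neighbors:
        filled = np.where(nb > 0, nb, incumbent.astype(np.int32) * 100).astype(np.int32)
        consider(canonicalize_array(filled).astype(np.int16))

    def prune() -> None:
        if len(elite) > params.retain_per_node:
            keep = sorted(elite.items(), key=lambda kv: (kv[1][0], kv[0]))
            for key, _ in keep[params.retain_per_node:]:
                del elite[key]

    prev_keys: Optional[frozenset] = None
    stagnant = 0
    for _ in range(params.cycles_per_node):
        prune()
        keys = frozenset(elite)
        if keys == prev_keys:
            stagnant += 1
            if stagnant >= _STAGNATION_CYCLES:
                break
        else:
            stagnant = 0
        prev_keys = keys
        parents = [arr for _, (_, arr) in sorted(elite.items(), key=lambda kv: (kv[1][0], kv[0]))]
        seen: set = set(elite)
        produced = 0
        attempts = 0
        # distinct candidates can be scarce on tiny universes; bound the fill
        while produced < params.population and attempts < 4 * params.population:
            attempts += 1
            p1 = parents[rng.integers(len(parents))]
            if len(parents) > 1 and rng.random() < 0.5:
                p2 = parents[rng.integers(len(parents))]
                child = _crossover(p1, p2, rng)
                if rng.random() < 0.5:
                    child = _mutate(child, active, rng)
            else:
                child = _mutate(p1, active, rng)
            key = child.tobytes()
            if key not in seen:
                seen.add(key)
                produced += 1
                if key not in elite:
                    elite[key] = (fitness(child), child)

    ordered = sorted(elite.items(), key=lambda kv: (kv[1][0], kv[0]))
    best = ordered[0][1][0]
    return [arr for _, (_, arr) in ordered[: params.retain_per_node]], best


# ---------------------------------------------------------------------------
# whole-tree search
# ---------------------------------------------------------------------------

class _TreeProblem:
    """Array-level view of a dataset: tip arrays over the sorted universe."""

    def __init__(self, dataset: Dataset):
        self.tree = dataset.tree
        self.universe = dataset.matrix.event_ids
        self.table = PairTable(self.universe)
        tips = set(self.tree.tips)
        rows = set(dataset.matrix.taxa)
        if tips != rows:
            raise ValueError(
                f"tree tips and matrix rows disagree: only in tree {sorted(tips - rows)}, "
                f"only in matrix {sorted(rows - tips)}"
            )
        self.tip_arrays = {t: dataset.matrix[t].to_array(self.universe) for t in self.tree.tips}
        present = np.zeros(len(self.universe), dtype=bool)
        for arr in self.tip_arrays.values():
            present |= arr > 0
        #: indices of events observed in at least one tip — ancestral
        #: sequences range over exactly these.
        self.active = np.flatnonzero(present)

    def total_cost(self, assignment: Dict[str, np.ndarray]) -> int:
        def arr_of(n: str) -> np.ndarray:
            return self.tip_arrays[n] if self.tree.is_tip(n) else assignment[n]

        return sum(
            self.table.cost(arr_of(p), arr_of(c)) for p, c in self.tree.branches
        )

    def initial_assignment(self) -> Dict[str, np.ndarray]:
        """Post-order rank-wise lower-median of child sequences (cheap incumbent)."""
        assignment: Dict[str, np.ndarray] = {}
        tip_stack = np.stack(list(self.tip_arrays.values()))
        for node in self.tree.postorder():
            if self.tree.is_tip(node):
                continue
            kids = [
                self.tip_arrays[c] if self.tree.is_tip(c) else assignment[c]
                for c in self.tree.children_of(node)
            ]
            stack = np.stack(kids)
            arr = np.zeros(len(self.universe), dtype=np.int32)
            for e in self.active:
                vals = stack[:, e][stack[:, e] > 0]
                if len(vals) == 0:  # unseen below this node: fall back to tips
                    vals = tip_stack[:, e][tip_stack[:, e] > 0]
                arr[e] = int(np.sort(vals)[(len(vals) - 1) // 2])
            assignment[node] = canonicalize_array(arr).astype(np.int16)
        return assignment


def optimize_tree(dataset: Dataset, params: SearchParams = SearchParams()) -> SolutionPool:
    """Run the GA over a dataset and collect equally most-parsimonious solutions.

    Deterministic for a given ``params`` (including its seed).
    """
    prob = _TreeProblem(dataset)
    tree = prob.tree
    rng = np.random.default_rng(params.seed)

    assignment = prob.initial_assignment()
    internal_post = [n for n in tree.postorder() if not tree.is_tip(n)]
    internal_pre = [n for n in tree.preorder() if not tree.is_tip(n)]

    retained_sets: Dict[str, List[np.ndarray]] = {n: [assignment[n]] for n in internal_post}
    # (incumbent, neighbours) -> GA result; skips re-optimising converged nodes
    visit_cache: Dict[str, Tuple] = {}
    sweep_costs: List[int] = []
    sweep = 0
    incumbent_cost = prob.total_cost(assignment)
    while sweep < params.max_sweeps:
        round_start = incumbent_cost
        # alternating post-/pre-order sweeps until a sweep brings no gain
        while sweep < params.max_sweeps:
            order = internal_post if sweep % 2 == 0 else internal_pre
            for node in order:
                neighbors = []
                parent = tree.parent(node)
                if parent is not None:
                    neighbors.append(assignment[parent])
                for c in tree.children_of(node):
                    neighbors.append(prob.tip_arrays[c] if tree.is_tip(c) else assignment[c])
                context = (assignment[node].tobytes(),
                           tuple(nb.tobytes() for nb in neighbors))
                if visit_cache.get(node, (None,))[0] == context:
                    retained, best_local = visit_cache[node][1], visit_cache[node][2]
                else:
                    retained, best_local = _ga_node(
                        assignment[node], neighbors, prob.active, prob.table, params, rng
                    )
                    visit_cache[node] = (context, retained, best_local)
                retained_sets[node] = retained
                # move to a locally optimal candidate; keep the incumbent
                # when it is still one of them, for stability
                def local_fit(a: np.ndarray) -> int:
                    return sum(prob.table.cost(a, nb) for nb in neighbors)

                if local_fit(assignment[node]) > best_local:
                    assignment[node] = retained[0]
            cost = prob.total_cost(assignment)
            sweep_costs.append(cost)
            sweep += 1
            if cost >= incumbent_cost and len(sweep_costs) > 1:
                incumbent_cost = min(incumbent_cost, cost)
                break
            incumbent_cost = min(incumbent_cost, cost)
        # recombine retained candidates exactly; if that beats the sweep
        # incumbent, restart the descent from the recombined assignment
        combined_cost, combined = _combine(prob, retained_sets, 1, rng)
        if combined_cost < incumbent_cost and sweep < params.max_sweeps:
            assignment = dict(combined[0])
            incumbent_cost = combined_cost
            continue
        incumbent_cost = min(incumbent_cost, combined_cost)
        if combined_cost >= round_start:
            break

    best_cost, solutions = _combine(prob, retained_sets, params.solution_cap, rng)
    return SolutionPool(
        best_cost=best_cost,
        solutions=[
            TreeSolution(
                {n: RankedSequence.from_array(a, prob.universe) for n, a in sol.items()},
                best_cost,
            )
            for sol in solutions
        ],
        tree=tree,
        sweep_costs=sweep_costs,
    )


def _combine(
    prob: _TreeProblem,
    candidates: Dict[str, List[np.ndarray]],
    cap: int,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[int, List[Dict[str, np.ndarray]]]:
    """Exact minimum-cost combinations of per-node candidates by tree DP.

    ``down[v][j]`` is the optimal cost of the subtree rooted at internal
    node ``v`` when ``v`` uses its candidate ``j`` (tip children contribute
    fixed costs).  When the number of optimal combinations fits within
    ``cap`` they are all enumerated by backtracking through the per-child
    argmin sets; otherwise ``cap`` distinct combinations are sampled
    uniformly from the optimal set (top-down, proportional to the DP
    counts), so that consensus supports are not distorted by enumeration
    order.
    """
    tree = prob.tree
    table = prob.table
    down: Dict[str, np.ndarray] = {}
    # choice[v][c][j] = list of optimal candidate indices of internal child c
    choice: Dict[str, Dict[str, List[List[int]]]] = {}

    for v in tree.postorder():
        if tree.is_tip(v):
            continue
        cands = candidates[v]
        totals = np.zeros(len(cands), dtype=np.int64)
        choice[v] = {}
        for c in tree.children_of(v):
            if tree.is_tip(c):
                tip = prob.tip_arrays[c]
                totals += np.array([table.cost(a, tip) for a in cands])
            else:
                sub = down[c]
                opts: List[List[int]] = []
                for j, a in enumerate(cands):
                    edge = np.array([table.cost(a, b) for b in candidates[c]]) + sub
                    m = edge.min()
                    totals[j] += m
                    opts.append(np.flatnonzero(edge == m).tolist())
                choice[v][c] = opts
        down[v] = totals

    root = tree.root
    best = int(down[root].min())
    root_opts = np.flatnonzero(down[root] == best).tolist()

    # number of optimal combinations below each (node, candidate)
    count: Dict[str, List[int]] = {}
    for v in tree.postorder():
        if tree.is_tip(v):
            continue
        counts = []
        for j in range(len(candidates[v])):
            n = 1
            for c in tree.children_of(v):
                if not tree.is_tip(c):
                    n *= sum(count[c][jj] for jj in choice[v][c][j])
            counts.append(n)
        count[v] = counts
    n_optimal = sum(count[root][j] for j in root_opts)

    solutions: List[Dict[str, np.ndarray]] = []

    if n_optimal > cap and rng is not None:
        seen = set()
        attempts = 0
        while len(solutions) < cap and attempts < 20 * cap:
            attempts += 1
            j = _weighted_pick(rng, [(jj, count[root][jj]) for jj in root_opts])
            sol: Dict[str, np.ndarray] = {}
            key = []

            def draw(v: str, jv: int) -> None:
                sol[v] = candidates[v][jv]
                key.append((v, jv))
                for c in tree.children_of(v):
                    if not tree.is_tip(c):
                        jj = _weighted_pick(
                            rng, [(o, count[c][o]) for o in choice[v][c][jv]]
                        )
                        draw(c, jj)

            draw(root, j)
            k = tuple(sorted(key))
            if k not in seen:
                seen.add(k)
                solutions.append(sol)
        return best, solutions

    def expand(v: str, j: int) -> Iterator[Dict[str, np.ndarray]]:
        # lazy recursive enumeration so the cap truncates cheaply
        internal_children = [c for c in tree.children_of(v) if not tree.is_tip(c)]

        def rec(idx: int) -> Iterator[Dict[str, np.ndarray]]:
            if idx == len(internal_children):
                yield {v: candidates[v][j]}
                return
            c = internal_children[idx]
            for jj in choice[v][c][j]:
                for sub in expand(c, jj):
                    for rest in rec(idx + 1):
                        merged = dict(rest)
                        merged.update(sub)
                        yield merged

        yield from rec(0)

    for j in root_opts:
        for sol in expand(root, j):
            solutions.append(sol)
            if len(solutions) >= cap:
                return best, solutions
    return best, solutions


# ---------------------------------------------------------------------------
# exhaustive oracle for tiny instances
# ---------------------------------------------------------------------------

def _weighted_pick(rng: np.random.Generator, options: List[Tuple[int, int]]) -> int:
    """Pick an option index with probability proportional to its count."""
    total = sum(w for _, w in options)
    r = int(rng.integers(total)) if total < 2**62 else int(rng.random() * total)
    acc = 0
    for idx, w in options:
        acc += w
        if r < acc:
            return idx
    return options[-1][0]


def _all_canonical_arrays(n_events: int) -> List[np.ndarray]:
    """Every canonical dense ranking of n events (ordered set partitions)."""
    out = []
    for combo in itertools.product(range(1, n_events + 1), repeat=n_events):
        k = max(combo)
        if set(combo) == set(range(1, k + 1)):
            out.append(np.array(combo, dtype=np.int16))
    return out


def exhaustive_tree_search(dataset: Dataset, max_events: int = 5) -> SolutionPool:
    """Global optimum by scanning all canonical sequences at every internal node.

    A test oracle: refuses instances with more than ``max_events`` (<= 5)
    events present or more than 4 internal nodes.
    """
    if max_events > 5:
        raise ValueError("exhaustive_tree_search supports at most 5 events")
    prob = _TreeProblem(dataset)
    n_internal = sum(1 for n in prob.tree.postorder() if not prob.tree.is_tip(n))
    if len(prob.active) > max_events or n_internal > 4:
        raise ValueError(
            f"instance too large for exhaustive search: {len(prob.active)} events "
            f"(limit {max_events}), {n_internal} internal nodes (limit 4)"
        )
    n = len(prob.universe)
    cands = []
    for small in _all_canonical_arrays(len(prob.active)):
        arr = np.zeros(n, dtype=np.int16)
        arr[prob.active] = small
        cands.append(arr)
    candidates = {v: cands for v in prob.tree.postorder() if not prob.tree.is_tip(v)}
    best, solutions = _combine(prob, candidates, cap=10_000)
    return SolutionPool(
        best_cost=best,
        solutions=[
            TreeSolution(
                {v: RankedSequence.from_array(a, prob.universe) for v, a in sol.items()},
                best,
            )
            for sol in solutions
        ],
        tree=prob.tree,
    )
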