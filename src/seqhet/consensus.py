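"""Majority-rule consensus of equally most-parsimonious tree solutions.

Each tree solution implies, per branch, a set of heterochronies: the
(event, direction) pairs that appear in more than half of the branch's
minimum move sets (so within-solution ambiguity between alternative
minimal explanations is resolved by strict majority before solutions
vote).  A *pseudoconsensus* then keeps, per branch, every heterochrony
present in more than 50% of the solutions of one run, with that
percentage reported as support; a *superconsensus* pools the solutions
of several independent runs and applies the same rule, so support stays
interpretable as a fraction of solutions.

Ancestral sequences are summarised per node by mean ranks over all
solutions, re-ranked into canonical form (ties only at exact mean
equality).  Mean-rank sequences can show small positional differences
that are not majority heterochronies; that is expected and is why the
records, not the sequences, carry the support values.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import TYPE_CHECKING, Dict, List, Sequence, Set, Tuple

if TYPE_CHECKING:  # pragma: no cover
    from .pgi import SolutionPool, TreeSolution

from .parsimov import DEFAULT_MOVE_SET_CAP, Direction, majority_moves
from .sequence import ABSENT, RankMatrix, RankedSequence
from .tree import Phylogeny

__all__ = [
    "HeterochronyRecord",
    "ConsensusTree",
    "solution_heterochronies",
    "pseudoconsensus",
    "superconsensus",
    "mean_rank_ancestors",
    "write_records_tsv",
    "write_ancestral_json",
]

Branch = Tuple[str, str]


@dataclass(frozen=True)
class HeterochronyRecord:
    """One supported heterochrony on one branch of the consensus tree."""

    branch: Branch
    event_id: int
    direction: Direction
    support: float  # percent, in (50, 100]

    def __post_init__(self) -> None:
        if not 50.0 < self.support <= 100.0:
            raise ValueError(f"support {self.support} outside the majority-rule range (50, 100]")


@dataclass
class ConsensusTree:
    tree: Phylogeny
    records: List[HeterochronyRecord]
    ancestral_sequences: Dict[str, RankedSequence]
    run_tree_lengths: List[int]

    @property
    def mean_tree_length(self) -> float:
        return sum(self.run_tree_lengths) / len(self.run_tree_lengths)

    def records_on(self, branch: Branch) -> List[HeterochronyRecord]:
        return [r for r in self.records if r.branch == branch]

    @property
    def changes_per_branch(self) -> float:
        """Mean number of supported heterochronies per branch of the tree."""
        return len(self.records) / len(self.tree.branches)


def solution_heterochronies(
    solution: "TreeSolution",
    tips: RankMatrix,
    tree: Phylogeny,
    cap: int = DEFAULT_MOVE_SET_CAP,
) -> Dict[Branch, Set[Tuple[int, Direction]]]:
    """Per-branch heterochrony set implied by a single tree solution.

    An (event, direction) makes the set of a branch iff the event occurs in
    more than half of the branch's minimum move sets.  The vote fraction is
    computed exactly, component by component of the conflict graph, so the
    result does not depend on any enumeration order or cap (``cap`` bounds
    only the per-component enumeration and is never binding in practice).
    """

    def seq_of(node: str) -> RankedSequence:
        return tips[node] if tree.is_tip(node) else solution.node_sequences[node]

    return {
        (parent, child): majority_moves(seq_of(parent), seq_of(child))
        for parent, child in tree.branches
    }


def _majority_records(
    per_solution: List[Dict[Branch, Set[Tuple[int, Direction]]]],
) -> List[HeterochronyRecord]:
    n = len(per_solution)
    votes: Counter = Counter()
    for het in per_solution:
        for branch, items in het.items():
            for event, direction in items:
                votes[(branch, event, direction)] += 1
    records = [
        HeterochronyRecord(branch, event, direction, support=100.0 * count / n)
        for (branch, event, direction), count in votes.items()
        if 2 * count > n
    ]
    records.sort(key=lambda r: (r.branch, r.event_id, r.direction.value))
    return records


def pseudoconsensus(pool: "SolutionPool", tips: RankMatrix) -> ConsensusTree:
    """Majority-rule consensus of one run's equally parsimonious solutions."""
    if not pool.solutions:
        raise ValueError("empty solution pool")
    per_solution = [solution_heterochronies(s, tips, pool.tree) for s in pool.solutions]
    return ConsensusTree(
        tree=pool.tree,
        records=_majority_records(per_solution),
        ancestral_sequences=mean_rank_ancestors(pool.solutions),
        run_tree_lengths=[pool.best_cost],
    )


def superconsensus(pools: Sequence["SolutionPool"], tips: RankMatrix) -> ConsensusTree:
    """Consensus over several independent runs, by pooling all solutions."""
    if not pools:
        raise ValueError("superconsensus requires at least one pool")
    topologies = {p.tree.to_newick() for p in pools}
    if len(topologies) > 1:
        raise ValueError("solution pools are over different trees")
    all_solutions = [s for p in pools for s in p.solutions]
    per_solution = [
        solution_heterochronies(s, tips, pools[0].tree) for s in all_solutions
    ]
    return ConsensusTree(
        tree=pools[0].tree,
        records=_majority_records(per_solution),
        ancestral_sequences=mean_rank_ancestors(all_solutions),
        run_tree_lengths=[p.best_cost for p in pools],
    )


def mean_rank_ancestors(solutions: Sequence["TreeSolution"]) -> Dict[str, RankedSequence]:
    """Per node, the canonical ranking of events by mean rank over solutions.

    Events absent in any solution's sequence for a node stay absent.  Ranks
    tie only at exact mean equality (means are compared as exact fractions),
    and the result is densified to canonical form.  Order-invariant in the
    solution list and idempotent on a single solution.
    """
    if not solutions:
        raise ValueError("mean_rank_ancestors requires at least one solution")
    nodes = set(solutions[0].node_sequences)
    for s in solutions[1:]:
        if set(s.node_sequences) != nodes:
            raise ValueError("solutions cover different node sets")
    out: Dict[str, RankedSequence] = {}
    for node in sorted(nodes):
        sums: Dict[int, Fraction] = {}
        absent: Set[int] = set()
        events = solutions[0].node_sequences[node].event_ids
        for s in solutions:
            seq = s.node_sequences[node]
            for e in events:
                r = seq.rank(e)
                if r is ABSENT:
                    absent.add(e)
                else:
                    sums[e] = sums.get(e, Fraction(0)) + r
        means = {
            e: total / len(solutions) for e, total in sums.items() if e not in absent
        }
        levels = sorted(set(means.values()))
        level_of = {m: i + 1 for i, m in enumerate(levels)}
        ranks = {e: (ABSENT if e in absent or e not in means else level_of[means[e]]) for e in events}
        out[node] = RankedSequence(ranks)
    return out


# ---------------------------------------------------------------------------
# outputs
# ---------------------------------------------------------------------------

def write_records_tsv(
    consensus: ConsensusTree, path: Path, abbreviations: Dict[int, str]
) -> None:
    """TSV of supported heterochronies: branch, event, direction, support."""
    lines = ["parent\tchild\tevent_id\tevent\tdirection\tsupport"]
    for r in consensus.records:
        d = r.direction.value if r.direction is not Direction.AMBIGUOUS else "A/D"
        lines.append(
            f"{r.branch[0]}\t{r.branch[1]}\t{r.event_id}\t"
            f"{abbreviations.get(r.event_id, str(r.event_id))}\t{d}\t{r.support:.1f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_ancestral_json(consensus: ConsensusTree, path: Path) -> None:
    """JSON of ancestral sequences keyed by node label (null = absent)."""
    payload = {
        node: {str(e): (None if r is ABSENT else r) for e, r in seq.ranks.items()}
        for node, seq in consensus.ancestral_sequences.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
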