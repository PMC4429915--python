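"""Synthetic ranked-sequence datasets with known, planted heterochronies.

A root sequence of ``n_events`` events on about ``n_rank_levels`` dense rank
levels evolves down a rooted tree.  Along each branch, a Poisson number of
*shifts* relocate a uniformly chosen present event to a uniformly chosen
rank level, and each event is independently *lost* with a small probability
(losses are inherited).  Every shift and loss is recorded, so the pipeline's
output can be scored against the exact ground truth.

The default shape mirrors the real dataset: 33 events on ~10 rank levels
with frequent ties and rare absences.  What it does not emulate: correlated
(tissue-linked) co-shifting of events, and rank granularity differences
between taxa beyond what shifting itself produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .sequence import ABSENT, RankMatrix, RankedSequence, canonicalize_array
from .tree import Phylogeny

__all__ = ["SimParams", "Shift", "SimTruth", "random_sequence", "simulate", "recovery_score", "write_truth_tsv"]


@dataclass(frozen=True)
class SimParams:
    """Generator settings.

    n_events, n_rank_levels
        Universe size and target number of dense rank levels at the root
        (levels never exceed events).
    tie_probability
        Fraction of events that share a level with an earlier event; the
        effective level count is ``min(n_rank_levels, round(n_events * (1 -
        tie_probability)))``, so with tie_probability 0 and as many levels
        as events the root is a strict permutation.
    shifts_per_branch
        Poisson mean of planted relocations per branch.
    loss_probability
        Per-branch, per-event probability of (inherited) loss.
    """

    n_events: int = 33
    n_rank_levels: int = 10
    tie_probability: float = 0.35
    shifts_per_branch: float = 1.0
    loss_probability: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be positive")
        if not 1 <= self.n_rank_levels <= self.n_events:
            raise ValueError("need 1 <= n_rank_levels <= n_events")
        if not 0 <= self.tie_probability < 1:
            raise ValueError("tie_probability must be in [0, 1)")
        if not 0 <= self.loss_probability < 1:
            raise ValueError("loss_probability must be in [0, 1)")
        if self.shifts_per_branch < 0:
            raise ValueError("shifts_per_branch must be non-negative")


@dataclass(frozen=True)
class Shift:
    """One planted relocation on a branch (positions are normalised ranks)."""

    event_id: int
    target_level: int  # raw level set before re-canonicalisation
    old_position: float
    new_position: float


@dataclass
class SimTruth:
    """Ground truth of one simulation: per-node sequences and per-branch edits."""

    tree: Phylogeny
    root_sequence: RankedSequence
    node_sequences: Dict[str, RankedSequence]
    shifts: Dict[Tuple[str, str], List[Shift]]
    losses: Dict[Tuple[str, str], List[int]]
    matrix: RankMatrix = field(init=False)

    def __post_init__(self) -> None:
        tips = self.tree.tips
        self.matrix = RankMatrix(tips, {t: self.node_sequences[t] for t in tips})

    def replay(self) -> Dict[str, RankedSequence]:
        """Re-derive every node's sequence from the root and the edit log."""
        universe = tuple(sorted(self.root_sequence.event_ids))
        seqs = {self.tree.root: self.root_sequence}
        for parent, child in self.tree.branches_preorder:
            arr = seqs[parent].to_array(universe).astype(np.int32)
            for e in self.losses[(parent, child)]:
                arr[universe.index(e)] = 0
            arr = canonicalize_array(arr)
            for sh in self.shifts[(parent, child)]:
                arr = _apply_relocation(arr, universe.index(sh.event_id), sh.target_level)
            seqs[child] = RankedSequence.from_array(arr.astype(np.int16), universe)
        return seqs

    def detectable_shifts(self) -> List[Tuple[Tuple[str, str], int]]:
        """Planted (branch, event) shifts with nonzero *net* displacement.

        A shift whose event ends the branch at the same normalised position
        it started from (e.g. cancelled by a later shift) is unobservable in
        principle and excluded.
        """
        out = []
        for branch, shifts in self.shifts.items():
            parent, child = branch
            pseq = self.node_sequences[parent]
            cseq = self.node_sequences[child]
            for e in sorted({s.event_id for s in shifts}):
                pa = pseq.normalized_position(e)
                pb = cseq.normalized_position(e)
                if pa is not None and pb is not None and pa != pb:
                    out.append((branch, e))
        return out


def random_sequence(params: SimParams, rng: np.random.Generator) -> RankedSequence:
    """A canonical random sequence over the full universe (no absences)."""
    n = params.n_events
    k = min(params.n_rank_levels, max(1, round(n * (1.0 - params.tie_probability))))
    order = rng.permutation(n)
    ranks = np.zeros(n, dtype=np.int16)
    # the first k events guarantee dense levels 1..k; the rest join a level
    ranks[order[:k]] = np.arange(1, k + 1, dtype=np.int16)
    if n > k:
        ranks[order[k:]] = rng.integers(1, k + 1, size=n - k).astype(np.int16)
    universe = tuple(range(1, n + 1))
    return RankedSequence.from_array(ranks, universe)


def _apply_relocation(arr: np.ndarray, idx: int, target_level: int) -> np.ndarray:
    out = arr.astype(np.int32).copy()
    out[idx] = target_level
    return canonicalize_array(out)


def simulate(tree: Phylogeny, params: SimParams) -> SimTruth:
    """Evolve a root sequence down ``tree``; deterministic in ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    universe = tuple(range(1, params.n_events + 1))
    root_seq = random_sequence(params, rng)
    arrays: Dict[str, np.ndarray] = {tree.root: root_seq.to_array(universe)}
    shifts: Dict[Tuple[str, str], List[Shift]] = {}
    losses: Dict[Tuple[str, str], List[int]] = {}

    for parent, child in tree.branches_preorder:
        arr = arrays[parent].astype(np.int32).copy()
        branch_losses: List[int] = []
        if params.loss_probability > 0:
            for i in np.flatnonzero(arr > 0):
                if rng.random() < params.loss_probability:
                    arr[i] = 0
                    branch_losses.append(universe[i])
        arr = canonicalize_array(arr)
        branch_shifts: List[Shift] = []
        n_shifts = int(rng.poisson(params.shifts_per_branch))
        for _ in range(n_shifts):
            present = np.flatnonzero(arr > 0)
            if len(present) == 0:
                break
            idx = int(present[rng.integers(len(present))])
            k = int(arr.max())
            target = int(rng.integers(1, k + 1))
            old_pos = _norm_pos(arr, idx)
            arr = _apply_relocation(arr, idx, target)
            branch_shifts.append(
                Shift(universe[idx], target, old_pos, _norm_pos(arr, idx))
            )
        arrays[child] = arr.astype(np.int16)
        shifts[(parent, child)] = branch_shifts
        losses[(parent, child)] = branch_losses

    node_sequences = {
        n: RankedSequence.from_array(a, universe) for n, a in arrays.items()
    }
    return SimTruth(
        tree=tree,
        root_sequence=root_seq,
        node_sequences=node_sequences,
        shifts=shifts,
        losses=losses,
    )


def _norm_pos(arr: np.ndarray, idx: int) -> float:
    k = int(arr.max())
    return 0.0 if k <= 1 else (int(arr[idx]) - 1) / (k - 1)


def recovery_score(truth: SimTruth, consensus: "ConsensusTree") -> Tuple[float, float]:
    """(recall, precision) of consensus records against the planted shifts.

    Recall: fraction of detectable planted (branch, event) shifts recovered
    as a supported record on the same branch.  Precision: fraction of
    records matching a planted shift.  Both are 1 when their denominator is
    empty (nothing to find / nothing claimed).
    """
    if truth.tree.to_newick() != consensus.tree.to_newick():
        raise ValueError("truth and consensus are over different trees")
    planted = set(truth.detectable_shifts())
    found = {(r.branch, r.event_id) for r in consensus.records}
    recall = 1.0 if not planted else len(planted & found) / len(planted)
    precision = 1.0 if not found else len(planted & found) / len(found)
    return recall, precision


def write_truth_tsv(truth: SimTruth, path) -> None:
    """Edit log as TSV: one row per planted shift or loss."""
    lines = ["parent\tchild\tkind\tevent_id\ttarget_level\told_position\tnew_position"]
    for parent, child in truth.tree.branches:
        for e in truth.losses[(parent, child)]:
            lines.append(f"{parent}\t{child}\tloss\t{e}\t\t\t")
        for s in truth.shifts[(parent, child)]:
            lines.append(
                f"{parent}\t{child}\tshift\t{s.event_id}\t{s.target_level}\t"
                f"{s.old_position:.6f}\t{s.new_position:.6f}"
            )
    from pathlib import Path as _P

    _P(path).write_text("\n".join(lines) + "\n")
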