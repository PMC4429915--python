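"""Parsimov event-pair edit cost between ranked developmental sequences.

The unit of comparison is the *event pair*: for two events i, j a sequence
defines the relation before / simultaneous / after, or leaves it undefined
when either event is absent.  Between two sequences, the *changed pairs* are
those whose relation is defined in both and differs.  The Parsimov edit cost
is the minimum number of events whose movement explains all changed pairs —
equivalently, a minimum vertex cover of the conflict graph whose edges are
the changed pairs (every changed pair must involve at least one mover).

Conflict graphs here have at most 33 vertices, so the cover is solved
exactly by branch and bound with a maximal-matching lower bound.

Each moving event is tagged with a direction relative to its *normalised*
position (rank-1)/(k-1): ``A`` (accelerated, earlier in the second
sequence), ``D`` (delayed) or ``AMBIGUOUS`` (position unchanged, e.g. a
pure tie join/split).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np

from .sequence import ABSENT, RankedSequence

__all__ = [
    "PairRelation",
    "Direction",
    "MoveSet",
    "pair_relation",
    "changed_pairs",
    "parsimov_cost",
    "minimum_move_sets",
    "majority_moves",
    "presence_changes",
    "PairTable",
    "DEFAULT_MOVE_SET_CAP",
]

DEFAULT_MOVE_SET_CAP = 64


class PairRelation(Enum):
    BEFORE = "<"
    SIMULTANEOUS = "="
    AFTER = ">"
    UNDEFINED = "?"


class Direction(str, Enum):
    ACCELERATED = "A"
    DELAYED = "D"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class MoveSet:
    """One minimal explanation of a sequence change: who moved, and which way."""

    moves: FrozenSet[Tuple[int, Direction]]

    @property
    def event_ids(self) -> FrozenSet[int]:
        return frozenset(e for e, _ in self.moves)

    def __len__(self) -> int:
        return len(self.moves)


# ---------------------------------------------------------------------------
# relation / changed-pair primitives (RankedSequence API)
# ---------------------------------------------------------------------------

def pair_relation(seq: RankedSequence, i: int, j: int) -> PairRelation:
    """Relation of event i to event j in one sequence."""
    if i == j:
        raise ValueError("pair_relation needs two distinct events")
    ri, rj = seq.rank(i), seq.rank(j)
    if ri is ABSENT or rj is ABSENT:
        return PairRelation.UNDEFINED
    if ri < rj:
        return PairRelation.BEFORE
    if ri > rj:
        return PairRelation.AFTER
    return PairRelation.SIMULTANEOUS


def _check_universe(a: RankedSequence, b: RankedSequence) -> Tuple[int, ...]:
    ua, ub = tuple(sorted(a.event_ids)), tuple(sorted(b.event_ids))
    if ua != ub:
        raise ValueError("sequences are not over the same event universe")
    return ua


def changed_pairs(seq_a: RankedSequence, seq_b: RankedSequence) -> Set[FrozenSet[int]]:
    """Unordered event pairs with defined-but-different relations."""
    universe = _check_universe(seq_a, seq_b)
    table = PairTable(universe)
    ii, jj = table.changed_pair_indices(table.encode(seq_a.to_array(universe)),
                                        table.encode(seq_b.to_array(universe)))
    return {frozenset((universe[i], universe[j])) for i, j in zip(ii, jj)}


def parsimov_cost(seq_a: RankedSequence, seq_b: RankedSequence) -> int:
    """Minimum number of moving events explaining all changed pairs."""
    universe = _check_universe(seq_a, seq_b)
    table = PairTable(universe)
    return table.cost(seq_a.to_array(universe), seq_b.to_array(universe))


def minimum_move_sets(
    seq_a: RankedSequence,
    seq_b: RankedSequence,
    cap: int = DEFAULT_MOVE_SET_CAP,
) -> List[MoveSet]:
    """All minimum vertex covers of the conflict graph (up to ``cap``),
    with the direction of each mover read off the normalised positions.

    Directions describe the change a -> b: ``A`` if the event sits earlier
    (smaller normalised position) in ``seq_b`` than in ``seq_a``.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    universe = _check_universe(seq_a, seq_b)
    table = PairTable(universe)
    covers = table.minimum_covers(seq_a.to_array(universe), seq_b.to_array(universe), cap)
    out: List[MoveSet] = []
    for cover in covers:
        moves = set()
        for idx in cover:
            e = universe[idx]
            moves.add((e, _direction(seq_a, seq_b, e)))
        out.append(MoveSet(frozenset(moves)))
    return out


def _direction(seq_a: RankedSequence, seq_b: RankedSequence, event_id: int) -> Direction:
    pa = seq_a.normalized_position(event_id)
    pb = seq_b.normalized_position(event_id)
    if pa is None or pb is None or pa == pb:
        return Direction.AMBIGUOUS
    return Direction.ACCELERATED if pb < pa else Direction.DELAYED


def presence_changes(seq_a: RankedSequence, seq_b: RankedSequence) -> Dict[int, str]:
    """Presence/absence differences a -> b: 'loss' or 'gain' per event.

    Kept apart from the edit cost: an absence is missing data to Parsimov,
    while evolutionary loss/novelty along a branch is a separate statement.
    """
    universe = _check_universe(seq_a, seq_b)
    out: Dict[int, str] = {}
    for e in universe:
        pa, pb = seq_a.is_present(e), seq_b.is_present(e)
        if pa and not pb:
            out[e] = "loss"
        elif pb and not pa:
            out[e] = "gain"
    return out


# ---------------------------------------------------------------------------
# fast array path with memoised pair encodings
# ---------------------------------------------------------------------------

_UNDEF = np.int8(9)


class PairTable:
    """Memoised pair-relation encodings over a fixed event universe.

    Sequences are int arrays over the universe order (0 = absent).  The
    encoding of a sequence is an int8 vector over all i<j pairs with values
    -1 (before), 0 (simultaneous), +1 (after) and 9 (undefined); encodings
    and pairwise costs are cached by the array bytes, which makes repeated
    cost evaluations in the GA cheap.
    """

    _instances: Dict[Tuple[int, ...], "PairTable"] = {}

    def __new__(cls, universe: Sequence[int]) -> "PairTable":
        key = tuple(universe)
        inst = cls._instances.get(key)
        if inst is None:
            inst = super().__new__(cls)
            inst._init(key)
            cls._instances[key] = inst
        return inst

    def _init(self, universe: Tuple[int, ...]) -> None:
        self.universe = universe
        n = len(universe)
        self.n_events = n
        self._i, self._j = np.triu_indices(n, k=1)
        self._enc_cache: Dict[bytes, np.ndarray] = {}
        self._cost_cache: Dict[Tuple[bytes, bytes], int] = {}
        self._mask_cost_cache: Dict[bytes, int] = {}
        self._fraction_cache: Dict[Tuple[bytes, bytes], Dict[int, float]] = {}

    def encode(self, arr: np.ndarray) -> np.ndarray:
        key = arr.tobytes()
        enc = self._enc_cache.get(key)
        if enc is None:
            a = arr[self._i]
            b = arr[self._j]
            enc = np.sign(a - b).astype(np.int8)
            enc[(a == 0) | (b == 0)] = _UNDEF
            enc.setflags(write=False)
            if len(self._enc_cache) < 500_000:  # bounded memoisation
                self._enc_cache[key] = enc
        return enc

    def changed_pair_indices(self, enc_a: np.ndarray, enc_b: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        changed = (enc_a != enc_b) & (enc_a != _UNDEF) & (enc_b != _UNDEF)
        return self._i[changed], self._j[changed]

    def cost(self, arr_a: np.ndarray, arr_b: np.ndarray) -> int:
        ka, kb = arr_a.tobytes(), arr_b.tobytes()
        if ka == kb:
            return 0
        key = (ka, kb) if ka < kb else (kb, ka)
        c = self._cost_cache.get(key)
        if c is None:
            enc_a, enc_b = self.encode(arr_a), self.encode(arr_b)
            changed = (enc_a != enc_b) & (enc_a != _UNDEF) & (enc_b != _UNDEF)
            # distinct sequence pairs often share a conflict pattern: cache
            # the cover size by the packed changed-pair mask as well
            mkey = np.packbits(changed).tobytes()
            c = self._mask_cost_cache.get(mkey)
            if c is None:
                c = _cover_size_from_pairs(
                    self.n_events, self._i[changed], self._j[changed]
                )
                if len(self._mask_cost_cache) < 2_000_000:
                    self._mask_cost_cache[mkey] = c
            if len(self._cost_cache) < 2_000_000:
                self._cost_cache[key] = c
        return c

    def minimum_covers(self, arr_a: np.ndarray, arr_b: np.ndarray, cap: int) -> List[FrozenSet[int]]:
        ii, jj = self.changed_pair_indices(self.encode(arr_a), self.encode(arr_b))
        adj = _adjacency(ii, jj)
        size = _min_cover_size(adj)
        return _enumerate_covers(adj, size, cap)

    def move_fractions(self, arr_a: np.ndarray, arr_b: np.ndarray) -> Dict[int, float]:
        """For each event index, the exact fraction of minimum vertex covers
        of the conflict graph that contain it.

        The conflict graph splits into connected components and minimum
        covers combine freely across components, so an event's fraction over
        *all* minimum covers equals its fraction within its own component's
        covers — computed here without enumerating the cross product.
        """
        ka, kb = arr_a.tobytes(), arr_b.tobytes()
        key = (ka, kb) if ka < kb else (kb, ka)
        cached = self._fraction_cache.get(key)
        if cached is not None:
            return cached
        ii, jj = self.changed_pair_indices(self.encode(arr_a), self.encode(arr_b))
        adj = _adjacency(ii, jj)
        fractions: Dict[int, float] = {}
        for comp in _components(adj):
            sub = {v: adj[v] & comp for v in comp}
            size = _min_cover_size(sub)
            covers = _enumerate_covers(sub, size, cap=_COMPONENT_COVER_CAP)
            counts: Dict[int, int] = {}
            for cover in covers:
                for v in cover:
                    counts[v] = counts.get(v, 0) + 1
            for v in comp:
                fractions[v] = counts.get(v, 0) / len(covers)
        self._fraction_cache[key] = fractions
        return fractions


#: per-component enumeration cap; components of these conflict graphs are
#: small, so this is effectively "all of them"
_COMPONENT_COVER_CAP = 4096


def majority_moves(
    seq_a: RankedSequence, seq_b: RankedSequence
) -> Set[Tuple[int, Direction]]:
    """Events occurring in more than half of ALL minimum move sets a -> b,
    with their directions.  Vote fractions are exact (component-wise)."""
    universe = _check_universe(seq_a, seq_b)
    table = PairTable(universe)
    fractions = table.move_fractions(seq_a.to_array(universe), seq_b.to_array(universe))
    out: Set[Tuple[int, Direction]] = set()
    for idx, frac in fractions.items():
        if frac > 0.5:
            e = universe[idx]
            out.add((e, _direction(seq_a, seq_b, e)))
    return out


def _components(adj: Dict[int, Set[int]]) -> List[Set[int]]:
    seen: Set[int] = set()
    comps: List[Set[int]] = []
    for v in adj:
        if v in seen:
            continue
        comp = {v}
        stack = [v]
        while stack:
            u = stack.pop()
            for w in adj[u]:
                if w not in comp:
                    comp.add(w)
                    stack.append(w)
        seen |= comp
        comps.append(comp)
    return comps


def _adjacency(ii: np.ndarray, jj: np.ndarray) -> Dict[int, Set[int]]:
    adj: Dict[int, Set[int]] = {}
    for i, j in zip(ii.tolist(), jj.tolist()):
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    return adj


def _matching_lower_bound(adj: Dict[int, Set[int]]) -> int:
    """Size of a greedy maximal matching — a lower bound on the cover."""
    used: Set[int] = set()
    m = 0
    for v in adj:
        if v in used:
            continue
        for w in adj[v]:
            if w not in used:
                used.add(v)
                used.add(w)
                m += 1
                break
    return m


def _min_cover_size(adj: Dict[int, Set[int]]) -> int:
    """Exact minimum vertex cover size of an adjacency-dict graph."""
    if not adj:
        return 0
    pairs = [(u, v) for u in adj for v in adj[u] if u < v]
    verts = sorted(adj)
    idx = {v: i for i, v in enumerate(verts)}
    ii = np.array([idx[u] for u, _ in pairs])
    jj = np.array([idx[v] for _, v in pairs])
    return _cover_size_from_pairs(len(verts), ii, jj)


def _cover_size_from_pairs(n: int, ii: np.ndarray, jj: np.ndarray) -> int:
    """Exact minimum vertex cover of the graph given by edge index arrays.

    Bitmask branch and bound, run per connected component: always branches
    on a maximum-degree vertex (in the cover, or excluded with its whole
    neighbourhood in), folds degree-1 vertices, and prunes with a greedy
    maximal-matching lower bound.
    """
    masks = [0] * n
    involved = 0
    for i, j in zip(ii.tolist(), jj.tolist()):
        masks[i] |= 1 << j
        masks[j] |= 1 << i
        involved |= (1 << i) | (1 << j)
    if not involved:
        return 0

    def matching_lb(rem: int) -> int:
        m = 0
        r = rem
        while r:
            v = (r & -r).bit_length() - 1
            r &= r - 1
            nb = masks[v] & r
            if nb:
                r &= ~(nb & -nb)
                m += 1
        return m

    total = 0
    rem_all = involved
    while rem_all:
        # peel off one connected component by bitmask BFS
        comp = rem_all & -rem_all
        frontier = comp
        while frontier:
            nxt = 0
            f = frontier
            while f:
                v = (f & -f).bit_length() - 1
                f &= f - 1
                nxt |= masks[v]
            nxt &= rem_all & ~comp
            comp |= nxt
            frontier = nxt
        rem_all &= ~comp

        best = [comp.bit_count()]

        def bb(rem: int, size: int) -> None:
            if size >= best[0]:
                return
            vmax, dmax = -1, 0
            r = rem
            while r:
                v = (r & -r).bit_length() - 1
                r &= r - 1
                nbr = masks[v] & rem
                d = nbr.bit_count()
                if d == 1:
                    # fold the leaf: its neighbour is in some optimal cover
                    bb(rem & ~((1 << v) | nbr), size + 1)
                    return
                if d > dmax:
                    vmax, dmax = v, d
            if dmax == 0:
                best[0] = size
                return
            if size + matching_lb(rem) >= best[0]:
                return
            nbr = masks[vmax] & rem
            bb(rem & ~(1 << vmax), size + 1)
            bb(rem & ~(nbr | (1 << vmax)), size + nbr.bit_count())

        bb(comp, 0)
        total += best[0]
    return total


def _remove(adj: Dict[int, Set[int]], vertices: Set[int]) -> Dict[int, Set[int]]:
    out: Dict[int, Set[int]] = {}
    for v, nb in adj.items():
        if v in vertices:
            continue
        rest = nb - vertices
        if rest:
            out[v] = rest
    return out


def _enumerate_covers(adj: Dict[int, Set[int]], size: int, cap: int) -> List[FrozenSet[int]]:
    """All vertex covers of exactly ``size`` vertices, up to ``cap``."""
    if not adj:
        return [frozenset()]
    found: List[FrozenSet[int]] = []
    seen: Set[FrozenSet[int]] = set()

    def search(adj_: Dict[int, Set[int]], chosen: Set[int]) -> bool:
        """Returns False once the cap is reached."""
        if len(chosen) > size:
            return True
        if not adj_:
            if len(chosen) == size:
                s = frozenset(chosen)
                if s not in seen:
                    seen.add(s)
                    found.append(s)
            return len(found) < cap
        budget = size - len(chosen)
        if budget <= 0 or _matching_lower_bound(adj_) > budget:
            return True
        v = max(adj_, key=lambda u: len(adj_[u]))
        if not search(_remove(adj_, {v}), chosen | {v}):
            return False
        nb = set(adj_[v])
        return search(_remove(adj_, nb), chosen | nb)

    search(adj, set())
    found.sort(key=lambda s: tuple(sorted(s)))
    return found
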