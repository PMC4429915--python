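"""Ranked developmental sequences with ties and explicit absences.

A developmental sequence assigns each event an ordinal *rank*: its position
in the series of semaphoronts (operational stages) in which it first appears.
Events first seen in the same semaphoront share a rank (a tie).  Events never
observed in a species carry the :data:`ABSENT` marker and take part in no
timing comparison.

Sequences are kept in *canonical dense* form: the ranks actually used are
exactly ``1..k``.  Canonical form makes rank arithmetic comparable between
species whose raw stagings differ in resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np

__all__ = ["ABSENT", "RankedSequence", "canonicalize", "RankMatrix"]


class _Absent:
    """Singleton marker for an event with no rank (missing or lost)."""

    _instance: Optional["_Absent"] = None

    def __new__(cls) -> "_Absent":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "ABSENT"

    def __reduce__(self):
        return (_Absent, ())


ABSENT = _Absent()

Rank = int  # positive, 1-based


@dataclass(frozen=True)
class RankedSequence:
    """Map event-id -> rank (or :data:`ABSENT`), in canonical dense form.

    Construct via :func:`canonicalize` or :meth:`from_ranks` unless the input
    is already canonical.
    """

    ranks: Mapping[int, object]  # int rank or ABSENT

    def __post_init__(self) -> None:
        object.__setattr__(self, "ranks", dict(self.ranks))

    @classmethod
    def from_ranks(cls, ranks: Mapping[int, object]) -> "RankedSequence":
        return canonicalize(cls(ranks))

    # -- basic queries -------------------------------------------------
    def rank(self, event_id: int) -> object:
        try:
            return self.ranks[event_id]
        except KeyError:
            raise KeyError(f"unknown event id {event_id!r}") from None

    def is_present(self, event_id: int) -> bool:
        return self.rank(event_id) is not ABSENT

    @property
    def event_ids(self) -> Tuple[int, ...]:
        return tuple(self.ranks)

    @property
    def present_ids(self) -> Tuple[int, ...]:
        return tuple(e for e, r in self.ranks.items() if r is not ABSENT)

    @property
    def max_rank(self) -> int:
        """Number of rank levels k (0 for an all-absent sequence)."""
        present = [r for r in self.ranks.values() if r is not ABSENT]
        return max(present) if present else 0

    def is_canonical(self) -> bool:
        present = sorted({r for r in self.ranks.values() if r is not ABSENT})
        return present == list(range(1, len(present) + 1))

    def normalized_position(self, event_id: int) -> Optional[float]:
        """Rank rescaled to [0, 1]: ``(rank-1)/(k-1)`` (0 when k == 1).

        Returns None for an absent event.  Normalised positions let
        sequences with different numbers of rank levels be compared.
        """
        r = self.rank(event_id)
        if r is ABSENT:
            return None
        k = self.max_rank
        return 0.0 if k <= 1 else (r - 1) / (k - 1)

    # -- array bridge (fast path used by the cost function / GA) -------
    def to_array(self, universe: Tuple[int, ...]) -> np.ndarray:
        """Ranks as int16 array over ``universe`` order; 0 encodes ABSENT."""
        out = np.zeros(len(universe), dtype=np.int16)
        for i, e in enumerate(universe):
            r = self.rank(e)
            if r is not ABSENT:
                out[i] = r
        return out

    @classmethod
    def from_array(cls, arr: np.ndarray, universe: Tuple[int, ...]) -> "RankedSequence":
        ranks: Dict[int, object] = {}
        for i, e in enumerate(universe):
            v = int(arr[i])
            ranks[e] = ABSENT if v == 0 else v
        return cls(ranks)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RankedSequence):
            return NotImplemented
        return dict(self.ranks) == dict(other.ranks)

    def __hash__(self) -> int:
        return hash(tuple(sorted((e, r if r is not ABSENT else 0) for e, r in self.ranks.items())))


def canonicalize(seq: RankedSequence) -> RankedSequence:
    """Re-number ranks densely to ``1..k``, preserving order and ties.

    Absent events are left absent.  Idempotent, and never changes any
    before/simultaneous/after relation between present events.

    Raises
    ------
    ValueError
        If any present rank is not a positive integer.
    """
    for e, r in seq.ranks.items():
        if r is ABSENT:
            continue
        if not isinstance(r, (int, np.integer)) or isinstance(r, bool) or r < 1:
            raise ValueError(f"event {e!r} has invalid rank {r!r}; ranks must be positive integers")
    levels = sorted({r for r in seq.ranks.values() if r is not ABSENT})
    remap = {old: new for new, old in enumerate(levels, start=1)}
    return RankedSequence(
        {e: (ABSENT if r is ABSENT else remap[r]) for e, r in seq.ranks.items()}
    )


def canonicalize_array(arr: np.ndarray) -> np.ndarray:
    """Array-form canonicalisation (0 = ABSENT stays 0)."""
    out = np.zeros_like(arr)
    present = arr > 0
    if present.any():
        levels = np.unique(arr[present])
        lut = np.zeros(int(levels[-1]) + 1, dtype=arr.dtype)
        lut[levels] = np.arange(1, len(levels) + 1, dtype=arr.dtype)
        out[present] = lut[arr[present]]
    return out


@dataclass
class RankMatrix:
    """Ordered taxa x shared event universe of canonical ranked sequences."""

    taxa: Tuple[str, ...]
    sequences: Dict[str, RankedSequence]

    def __post_init__(self) -> None:
        self.taxa = tuple(self.taxa)
        if set(self.taxa) != set(self.sequences):
            raise ValueError("taxon list and sequence keys disagree")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")
        universes = {tuple(sorted(s.event_ids)) for s in self.sequences.values()}
        if len(universes) > 1:
            raise ValueError("sequences are not over the same event universe")
        for t in self.taxa:
            if not self.sequences[t].is_canonical():
                raise ValueError(f"sequence for {t!r} is not in canonical dense form")

    @property
    def event_ids(self) -> Tuple[int, ...]:
        first = self.sequences[self.taxa[0]]
        return tuple(sorted(first.event_ids))

    def __getitem__(self, taxon: str) -> RankedSequence:
        return self.sequences[taxon]

    def __len__(self) -> int:
        return len(self.taxa)

    @classmethod
    def from_rows(cls, rows: Iterable[Tuple[str, Mapping[int, object]]]) -> "RankMatrix":
        taxa = []
        seqs = {}
        for name, ranks in rows:
            taxa.append(name)
            seqs[name] = RankedSequence.from_ranks(ranks)
        return cls(tuple(taxa), seqs)
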