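"""Catalogue of the 33 developmental events scored across eumalacostracan taxa.

Each event is the *onset* (first appearance) of a morphological feature —
an appendage bud, a ganglion anlage, a muscle precursor group — together
with the anatomical bookkeeping needed by the rate statistics: tissue type,
germ layer, and the body segment(s) the feature belongs to.

Segment affiliation follows the appendage named in the event abbreviation
(``a2-m`` is a second-antenna muscle, ``lmp-mx1`` a first-maxilla-segment
longitudinal precursor).  Four events have no usable segment affiliation and
are excluded from segment-wise statistics: offset of segmentation [FS],
the stomodeal muscle precursor [st], the nauplius eye anlage [NEA], and
hatching [HAT].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Tuple

__all__ = [
    "EventDef",
    "default_event_table",
    "CATEGORIES",
    "TISSUES",
    "GERM_LAYERS",
    "SEGMENTS",
    "SEGMENT_EXCLUDED_EVENTS",
]

CATEGORIES = (
    "epidermal-appendage",
    "segmentation",
    "myogenesis",
    "neurogenesis",
    "hatching",
)
TISSUES = ("epidermis", "neural", "muscle", "none")
GERM_LAYERS = ("ectoderm", "mesoderm", "none")
SEGMENTS = ("A1", "A2", "Md", "Mx1", "Mx2", "T1", "P6", "telson")

#: Events with problematic segment affiliation, excluded from segment rates.
SEGMENT_EXCLUDED_EVENTS = frozenset({7, 8, 31, 33})

_TISSUE_TO_LAYER = {"epidermis": "ectoderm", "neural": "ectoderm", "muscle": "mesoderm", "none": "none"}


@dataclass(frozen=True)
class EventDef:
    """One developmental event with its anatomical affiliation.

    Attributes
    ----------
    id : int
        Event number, 1-33; this numbering is fixed across all analyses.
    abbreviation : str
        The bracketed shorthand used in figures and output tables.
    category : str
        One of :data:`CATEGORIES`.
    tissue : str
        Tissue type used for tissue-wise rate means ("none" for events that
        belong to no scored tissue: segmentation offset and hatching).
    germ_layer : str
        Germ layer implied by the tissue (ectoderm for epidermis and neural
        tissue, mesoderm for muscle).
    segments : frozenset of str
        Body segments the feature belongs to; composite events carry several
        (the joint antennal bud event covers A1 and A2, the naupliar ganglion
        event covers A1, A2 and Md), events without clear affiliation none.
    """

    id: int
    abbreviation: str
    category: str
    tissue: str
    segments: FrozenSet[str] = field(default_factory=frozenset)

    @property
    def germ_layer(self) -> str:
        return _TISSUE_TO_LAYER[self.tissue]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r} for event {self.id}")
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r} for event {self.id}")
        unknown = set(self.segments) - set(SEGMENTS)
        if unknown:
            raise ValueError(f"unknown segments {sorted(unknown)} for event {self.id}")


def _ev(id_: int, abbr: str, category: str, tissue: str, *segments: str) -> EventDef:
    return EventDef(id_, abbr, category, tissue, frozenset(segments))


def default_event_table() -> Tuple[EventDef, ...]:
    """The 33 scored events of the eumalacostracan developmental dataset.

    Six epidermal appendage-bud events, one segmentation event, eighteen
    myogenic events, seven neurogenic events and the hatching event.
    """
    return (
        _ev(1, "[A1/A2]", "epidermal-appendage", "epidermis", "A1", "A2"),
        _ev(2, "[Md]", "epidermal-appendage", "epidermis", "Md"),
        _ev(3, "[Mx1]", "epidermal-appendage", "epidermis", "Mx1"),
        _ev(4, "[Mx2]", "epidermal-appendage", "epidermis", "Mx2"),
        _ev(5, "[T1]", "epidermal-appendage", "epidermis", "T1"),
        _ev(6, "[P6]", "epidermal-appendage", "epidermis", "P6"),
        _ev(7, "[FS]", "segmentation", "none"),
        _ev(8, "[st]", "myogenesis", "muscle"),
        _ev(9, "[a1-m]", "myogenesis", "muscle", "A1"),
        _ev(10, "[a1-l]", "myogenesis", "muscle", "A1"),
        _ev(11, "[a2-m]", "myogenesis", "muscle", "A2"),
        _ev(12, "[a2-l]", "myogenesis", "muscle", "A2"),
        _ev(13, "[md-m]", "myogenesis", "muscle", "Md"),
        _ev(14, "[md-l]", "myogenesis", "muscle", "Md"),
        _ev(15, "[mx1-m]", "myogenesis", "muscle", "Mx1"),
        _ev(16, "[mx1-l]", "myogenesis", "muscle", "Mx1"),
        _ev(17, "[lmp-mx1]", "myogenesis", "muscle", "Mx1"),
        _ev(18, "[mx2-m]", "myogenesis", "muscle", "Mx2"),
        _ev(19, "[mx2-l]", "myogenesis", "muscle", "Mx2"),
        _ev(20, "[lmp-mx2]", "myogenesis", "muscle", "Mx2"),
        _ev(21, "[t1-m]", "myogenesis", "muscle", "T1"),
        _ev(22, "[t1-l]", "myogenesis", "muscle", "T1"),
        _ev(23, "[lmp-t1]", "myogenesis", "muscle", "T1"),
        _ev(24, "[lmp-p6]", "myogenesis", "muscle", "P6"),
        _ev(25, "[lmp-post]", "myogenesis", "muscle", "telson"),
        _ev(26, "[NGA]", "neurogenesis", "neural", "A1", "A2", "Md"),
        _ev(27, "[mx1-g]", "neurogenesis", "neural", "Mx1"),
        _ev(28, "[mx2-g]", "neurogenesis", "neural", "Mx2"),
        _ev(29, "[t1-g]", "neurogenesis", "neural", "T1"),
        _ev(30, "[p6-g]", "neurogenesis", "neural", "P6"),
        _ev(31, "[NEA]", "neurogenesis", "neural"),
        _ev(32, "[PPN]", "neurogenesis", "neural", "telson"),
        _ev(33, "[HAT]", "hatching", "none"),
    )
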