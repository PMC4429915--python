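"""Heterochrony-rate statistics over a consensus tree.

The heterochrony rate of an event is the number of supported heterochronic
changes it shows across all branches of the (super)consensus tree,
multiplied by the mean support of those changes taken as a fraction
(two changes at 60% and 72% support give 2 x 0.66 = 1.32).  Direction does
not matter: accelerations, delays and ambiguous shifts all count.

Aggregates:

* tissue rates — unweighted mean of the per-event rates over the events of
  each tissue (6 appendage-bud, 7 neural, 18 myogenic events);
* germ-layer rates — ectoderm is the unweighted mean of the epidermis and
  neural tissue rates, mesoderm equals the muscle tissue rate;
* segment rates — per body segment and tissue column; a composite event
  contributes its full rate to each of its segments, and where several
  myogenic events share a segment their mean is used.  Events without a
  usable segment affiliation ([FS], [st], [NEA], [HAT]) are excluded from
  the segment grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

from .consensus import ConsensusTree
from .events import SEGMENT_EXCLUDED_EVENTS, SEGMENTS, EventDef, default_event_table

__all__ = [
    "RateTable",
    "event_rate",
    "per_event_rates",
    "tissue_rates",
    "germ_layer_rates",
    "segment_rates",
    "compute_rate_table",
    "write_rate_tables",
]

#: tissue columns of the segment grid, in anterior-to-posterior figure order
SEGMENT_TISSUES = ("epidermis", "neural", "muscle")


@dataclass
class RateTable:
    per_event: Dict[int, float]
    per_tissue: Dict[str, float]
    per_germ_layer: Dict[str, float]
    per_segment: Dict[Tuple[str, str], Optional[float]]  # (segment, tissue) -> rate or None


def event_rate(consensus: ConsensusTree, event_id: int) -> float:
    """(number of supported changes) x (their mean support as a fraction)."""
    universe = set()
    for seq in consensus.ancestral_sequences.values():
        universe = set(seq.event_ids)
        break
    if universe and event_id not in universe:
        raise ValueError(f"unknown event id {event_id}")
    supports = [r.support for r in consensus.records if r.event_id == event_id]
    if not supports:
        return 0.0
    mean_support = sum(supports) / len(supports)
    return len(supports) * (mean_support / 100.0)


def per_event_rates(
    consensus: ConsensusTree, events: Sequence[EventDef]
) -> Dict[int, float]:
    return {e.id: event_rate(consensus, e.id) for e in events}


def tissue_rates(
    per_event: Dict[int, float], events: Sequence[EventDef]
) -> Dict[str, float]:
    """Unweighted mean per-event rate for each scored tissue."""
    out: Dict[str, float] = {}
    for tissue in ("epidermis", "neural", "muscle"):
        members = [e.id for e in events if e.tissue == tissue]
        out[tissue] = sum(per_event.get(i, 0.0) for i in members) / len(members)
    return out


def germ_layer_rates(tissue: Dict[str, float]) -> Dict[str, float]:
    """Ectoderm = mean of its two tissue rates; mesoderm = the muscle rate."""
    return {
        "ectoderm": (tissue["epidermis"] + tissue["neural"]) / 2.0,
        "mesoderm": tissue["muscle"],
    }


def segment_rates(
    per_event: Dict[int, float], events: Sequence[EventDef]
) -> Dict[Tuple[str, str], Optional[float]]:
    """Segment x tissue grid of rates; None where no event is affiliated."""
    out: Dict[Tuple[str, str], Optional[float]] = {}
    for segment in SEGMENTS:
        for tissue in SEGMENT_TISSUES:
            members = [
                e.id
                for e in events
                if e.tissue == tissue
                and segment in e.segments
                and e.id not in SEGMENT_EXCLUDED_EVENTS
            ]
            if not members:
                out[(segment, tissue)] = None
            else:
                out[(segment, tissue)] = sum(per_event.get(i, 0.0) for i in members) / len(members)
    return out


def compute_rate_table(
    consensus: ConsensusTree, events: Sequence[EventDef] = None
) -> RateTable:
    events = tuple(events) if events is not None else default_event_table()
    per_event = per_event_rates(consensus, events)
    tissue = tissue_rates(per_event, events)
    return RateTable(
        per_event=per_event,
        per_tissue=tissue,
        per_germ_layer=germ_layer_rates(tissue),
        per_segment=segment_rates(per_event, events),
    )


def write_rate_tables(table: RateTable, out_dir: Path, events: Sequence[EventDef] = None) -> None:
    """TSVs: germ-layer/tissue summary and the segment grid, plus per-event rates."""
    events = tuple(events) if events is not None else default_event_table()
    out_dir = Path(out_dir)
    by_id = {e.id: e for e in events}

    lines = ["germ_layer\ttissue\tevents\tmean_rate\tgerm_layer_mean_rate"]
    layer_of = {"epidermis": "ectoderm", "neural": "ectoderm", "muscle": "mesoderm"}
    for tissue in ("epidermis", "neural", "muscle"):
        n = sum(1 for e in events if e.tissue == tissue)
        lines.append(
            f"{layer_of[tissue]}\t{tissue}\t{n}\t{table.per_tissue[tissue]:.2f}\t"
            f"{table.per_germ_layer[layer_of[tissue]]:.2f}"
        )
    (out_dir / "rates_by_tissue.tsv").write_text("\n".join(lines) + "\n")

    lines = ["segment\t" + "\t".join(SEGMENT_TISSUES)]
    for segment in SEGMENTS:
        cells = [
            ("NA" if table.per_segment[(segment, t)] is None else f"{table.per_segment[(segment, t)]:.2f}")
            for t in SEGMENT_TISSUES
        ]
        lines.append(segment + "\t" + "\t".join(cells))
    (out_dir / "rates_by_segment.tsv").write_text("\n".join(lines) + "\n")

    lines = ["event_id\tevent\trate"]
    for e in events:
        lines.append(f"{e.id}\t{e.abbreviation}\t{table.per_event[e.id]:.2f}")
    (out_dir / "rates_by_event.tsv").write_text("\n".join(lines) + "\n")
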