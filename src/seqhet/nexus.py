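"""NEXUS I/O for rank matrices plus a rooted tree, and the built-in dataset.

The dialect is deliberately narrow: a DATA (or CHARACTERS) block of
single-character states over the symbols ``1``-``9``, ``a`` (rank 10),
``b`` (11), ``c`` (12) with ``z`` for absent, and a TREES block holding one
rooted newick tree whose internal nodes are labelled.  Parsing goes through
dendropy; writing is direct, since the format is fixed.

The built-in dataset is the published 7-species x 33-event rank table of
eumalacostracan development (brine shrimp outgroup plus stomatopod, penaeid
shrimp, lophogastrid, crayfish, mysid and amphipod), with the accepted
phylogeny.  ``'-'`` (feature absent/lost) and ``'n.a.'`` (not applicable to
the outgroup) are both treated as absent — an absent event simply takes
part in no event-pair comparison.  By default the outgroup row is entered
twice, as two sister tips at the root: a free-swimming nauplius larva is
ancestral for the wider clade, and the duplicated outgroup anchors the
root's reconstruction toward the outgroup condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import dendropy

from .events import EventDef, default_event_table
from .sequence import ABSENT, RankMatrix, RankedSequence
from .tree import Phylogeny

__all__ = ["Dataset", "read_nexus", "write_nexus", "load_paper_dataset", "PAPER_TAXA"]

_SYMBOLS = "123456789abc"
_MISSING = "z"
_RANK_TO_CHAR = {i + 1: ch for i, ch in enumerate(_SYMBOLS)}
_CHAR_TO_RANK = {ch: i + 1 for i, ch in enumerate(_SYMBOLS)}

#: Taxon column order of the published rank table.
PAPER_TAXA = ("A.f.", "G.f.", "S.i.", "N.h.", "P.f.", "N.i.", "P.h.")
DUPLICATE_OUTGROUP_TIP = "A.f._dup"


@dataclass
class Dataset:
    """A rank matrix with its rooted tree, event table, and outgroup."""

    matrix: RankMatrix
    tree: Phylogeny
    events: Optional[Tuple[EventDef, ...]] = None
    outgroup: Optional[str] = None

    def __post_init__(self) -> None:
        tips = set(self.tree.tips)
        rows = set(self.matrix.taxa)
        if tips != rows:
            only_tree = sorted(tips - rows)
            only_matrix = sorted(rows - tips)
            raise ValueError(
                f"tree tips and matrix rows disagree: only in tree {only_tree}, "
                f"only in matrix {only_matrix}"
            )
        if self.outgroup is not None and self.outgroup not in tips:
            raise ValueError(f"outgroup {self.outgroup!r} is not a tip of the tree")


def read_nexus(path) -> Dataset:
    """Read a dataset from the NEXUS dialect described in the module docstring."""
    path = Path(path)
    try:
        ds = dendropy.DataSet.get(path=str(path), schema="nexus")
    except Exception as exc:  # dendropy errors carry line/column context
        raise ValueError(f"could not parse NEXUS file {path}: {exc}") from exc
    if not ds.char_matrices:
        raise ValueError(f"{path}: no DATA/CHARACTERS block found")
    if not ds.tree_lists or not ds.tree_lists[0]:
        raise ValueError(f"{path}: no TREES block found")
    cm = ds.char_matrices[0]

    rows = []
    for taxon in cm.taxon_namespace:
        name = taxon.label.replace(" ", "_")
        ranks: Dict[int, object] = {}
        for i, state in enumerate(cm[taxon], start=1):
            sym = str(state.symbol).lower()  # dendropy may upcase the missing symbol
            if sym in (_MISSING, "?"):
                ranks[i] = ABSENT
            elif sym in _CHAR_TO_RANK:
                ranks[i] = _CHAR_TO_RANK[sym]
            else:
                raise ValueError(
                    f"{path}: taxon {name!r}, character {i}: symbol {sym!r} "
                    f"is outside the dialect ({_SYMBOLS} / {_MISSING})"
                )
        rows.append((name, ranks))
    matrix = RankMatrix.from_rows(rows)
    tree = Phylogeny.from_dendropy(ds.tree_lists[0][0])
    return Dataset(matrix=matrix, tree=tree, outgroup=matrix.taxa[0])


def write_nexus(dataset: Dataset, path) -> Path:
    """Write a dataset in the dialect; inverse of :func:`read_nexus`.

    Raises
    ------
    ValueError
        If a rank exceeds 12, the largest value the dialect can encode.
    """
    path = Path(path)
    matrix = dataset.matrix
    events = matrix.event_ids
    lines = [
        "#NEXUS",
        "",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={len(matrix.taxa)} NCHAR={len(events)};",
        f'    FORMAT DATATYPE=STANDARD SYMBOLS="{_SYMBOLS}" MISSING={_MISSING};',
        "    MATRIX",
    ]
    width = max(len(t) for t in matrix.taxa) + 2
    for taxon in matrix.taxa:
        seq = matrix[taxon]
        chars = []
        for e in events:
            r = seq.rank(e)
            if r is ABSENT:
                chars.append(_MISSING)
            elif r in _RANK_TO_CHAR:
                chars.append(_RANK_TO_CHAR[r])
            else:
                raise ValueError(
                    f"rank {r} of event {e} in taxon {taxon!r} exceeds 12 and "
                    f"cannot be written in this dialect"
                )
        lines.append(f"    {taxon:<{width}}{''.join(chars)}")
    lines += ["    ;", "END;", "", "BEGIN TREES;"]
    lines.append(f"    TREE tree1 = [&R] {dataset.tree.to_newick()}")
    lines += ["END;", ""]
    path.write_text("\n".join(lines))
    return path


# ---------------------------------------------------------------------------
# built-in dataset
# ---------------------------------------------------------------------------

def _read_rank_table() -> Dict[str, Dict[int, object]]:
    text = resources.files("seqhet.data").joinpath("rank_table.tsv").read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    taxa = header[2:]
    ranks: Dict[str, Dict[int, object]] = {t: {} for t in taxa}
    for ln in lines[1:]:
        cells = ln.split("\t")
        event_id = int(cells[0])
        for taxon, cell in zip(taxa, cells[2:]):
            ranks[taxon][event_id] = ABSENT if cell in ("-", "n.a.") else int(cell)
    return ranks


def paper_tree(duplicate_outgroup: bool = True) -> Phylogeny:
    """The accepted topology with named ancestral nodes.

    Root = branchiopod/malacostracan LCA; the malacostracan clade is
    (stomatopod, (Caridoida = (Decapoda, Peracarida))).  With
    ``duplicate_outgroup`` the outgroup tip appears twice at the root.
    """
    root_children = ["A.f."]
    if duplicate_outgroup:
        root_children.append(DUPLICATE_OUTGROUP_TIP)
    root_children.append("Eumalacostraca_LCA")
    return Phylogeny(
        root="Branchiopod_Malacostracan_LCA",
        children={
            "Branchiopod_Malacostracan_LCA": tuple(root_children),
            "Eumalacostraca_LCA": ("G.f.", "Caridoida_LCA"),
            "Caridoida_LCA": ("Decapoda_LCA", "Peracarida_LCA"),
            "Decapoda_LCA": ("S.i.", "Pleocyemata_LCA"),
            "Pleocyemata_LCA": ("N.h.", "P.f."),
            "Peracarida_LCA": ("N.i.", "P.h."),
        },
    )


def load_paper_dataset(duplicate_outgroup: bool = True) -> Dataset:
    """The built-in 7 x 33 rank table with the accepted phylogeny.

    With ``duplicate_outgroup`` (the analysis default) the outgroup row is
    entered under a second tip name, sister to the original at the root.
    """
    raw = _read_rank_table()
    rows = [(t, raw[t]) for t in PAPER_TAXA]
    if duplicate_outgroup:
        rows.insert(1, (DUPLICATE_OUTGROUP_TIP, dict(raw["A.f."])))
    return Dataset(
        matrix=RankMatrix.from_rows(rows),
        tree=paper_tree(duplicate_outgroup),
        events=default_event_table(),
        outgroup="A.f.",
    )
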