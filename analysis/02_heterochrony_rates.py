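#!/usr/bin/env python
"""Heterochrony-rate tables from the saved superconsensus records.

Reads results/heterochronies.tsv (written by 01_reconstruct_ancestral_
sequences.py), rebuilds the per-event rates (changes x mean support) and
writes the tissue / germ-layer summary and the segment x tissue grid.

    python analysis/02_heterochrony_rates.py [--results results]
"""

import argparse
from pathlib import Path

from seqhet import ConsensusTree, Direction, HeterochronyRecord, default_event_table
from seqhet.nexus import paper_tree
from seqhet.rates import compute_rate_table, write_rate_tables


def read_records(path: Path):
    records = []
    for line in path.read_text().splitlines()[1:]:
        parent, child, event_id, _, direction, support = line.split("\t")
        records.append(HeterochronyRecord(
            (parent, child), int(event_id),
            {"A": Direction.ACCELERATED, "D": Direction.DELAYED}.get(direction, Direction.AMBIGUOUS),
            float(support),
        ))
    return records


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    records = read_records(args.results / "heterochronies.tsv")
    consensus = ConsensusTree(tree=paper_tree(), records=records,
                              ancestral_sequences={}, run_tree_lengths=[0])
    events = default_event_table()
    table = compute_rate_table(consensus, events)
    write_rate_tables(table, args.results, events)

    print(f"{len(records)} supported heterochronies "
          f"({consensus.changes_per_branch:.2f} per branch)")
    for tissue in ("epidermis", "neural", "muscle"):
        print(f"mean {tissue} rate: {table.per_tissue[tissue]:.2f}")
    print(f"germ layers: ectoderm {table.per_germ_layer['ectoderm']:.2f}, "
          f"mesoderm {table.per_germ_layer['mesoderm']:.2f}")
    print(f"tables written to {args.results}/rates_by_*.tsv")


if __name__ == "__main__":
    main()
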