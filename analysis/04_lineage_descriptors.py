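#!/usr/bin/env python
"""Sequence-evolution descriptors of the synthetic MT lineage.

Reads the lineage alignment and tree written by 01_simulate_inputs.py,
computes per-node substitution counts (total and per domain), cumulative
counts, identity to the root, side-chain bulkiness and K/N ratios, and
writes results/evolution/descriptors.tsv plus the headline substitution
bookkeeping (results/evolution/substitution_counts.json).
"""

import json
from pathlib import Path

from mtconform.evolution import (
    branch_lengths_in_substitutions,
    count_substitutions,
    substitution_persistence,
    lineage_descriptor_table,
)
from mtconform.io_formats import read_alignment, read_newick
from mtconform.synthetic import LINEAGE_PARTITION

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    aln = read_alignment(ROOT / "inputs" / "lineage_alignment.fasta")
    tree = read_newick(ROOT / "inputs" / "lineage_tree.nwk")
    out = ROOT / "evolution"
    out.mkdir(parents=True, exist_ok=True)

    table = lineage_descriptor_table(aln, tree, partition=LINEAGE_PARTITION)
    table.to_csv(out / "descriptors.tsv", sep="\t", index=False, float_format="%.4f")

    g = aln.get
    nd = LINEAGE_PARTITION.n_domain
    branches = branch_lengths_in_substitutions(aln, tree).set_index("node")
    counts = {
        "subs_a1cdmt_to_a2cumt": count_substitutions(g("a1CdMT"), g("a2CuMT")),
        "persisting_in_hpcumt": substitution_persistence(
            g("a1CdMT"), g("a2CuMT"), g("HpCuMT")
        ),
        "subs_a2cumt_to_a3cumt": count_substitutions(g("a2CuMT"), g("a3CuMT")),
        "persisting_in_hpcumt_2": substitution_persistence(
            g("a2CuMT"), g("a3CuMT"), g("HpCuMT")
        ),
        "ndomain_a3cumt_to_hpunmt2": count_substitutions(
            g("a3CuMT"), g("HpUnMT2"), region=nd
        ),
        "ndomain_a3cumt_to_hpcumt": count_substitutions(
            g("a3CuMT"), g("HpCuMT"), region=nd
        ),
        "ndomain_a4cdmt_to_hpcdmt": count_substitutions(
            g("a4CdMT"), g("HpCdMT"), region=nd
        ),
        "cd_lineage_total": int(
            branches.loc["HpCdMT", "cumulative_substitutions_from_root"]
        ),
        "alignment_sequences": len(aln),
    }
    with open(out / "substitution_counts.json", "w") as fh:
        json.dump(counts, fh, indent=2)

    for key, val in counts.items():
        print(f"{key}: {val}")
    rec = table.set_index("node")
    print(f"\nbulkiness a1CdMT -> HpCuMT: {rec.loc['a1CdMT','bulkiness_A3']:.0f} -> "
          f"{rec.loc['HpCuMT','bulkiness_A3']:.0f} A^3")
    print(f"K/N a1CdMT={rec.loc['a1CdMT','kn_ratio']:.2f} "
          f"HpCuMT={rec.loc['HpCuMT','kn_ratio']:.2f}")
    print(f"descriptor table written to {out / 'descriptors.tsv'}")


if __name__ == "__main__":
    main()
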