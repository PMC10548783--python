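"""Lineage descriptors over an alignment and a phylogeny.

Substitution bookkeeping is literal counting, not evolutionary-distance
estimation: a column counts as one substitution on every branch along which
it changes, with no multiple-hit correction.  Gap-versus-residue columns are
indels and are never added to substitution totals.

Also provided: sequence identity under three denominator policies,
side-chain bulkiness (summed Zamyatnin residue volumes, Å^3) and the K/N
ratio (lysines per asparagine from the first conserved Cys onward).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import dendropy
import numpy as np
import pandas as pd

from mtconform.errors import FormatError
from mtconform.io_formats import AlignmentSet, node_name

#: Amino-acid residue volumes (Å^3) after Zamyatnin, as tabulated by IMGT.
ZAMYATNIN_VOLUMES: dict[str, float] = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

Region = "tuple[int, int] | None"  # 1-based inclusive alignment-column range


@dataclass(frozen=True)
class DomainPartition:
    """1-based inclusive alignment-column ranges of the two-domain MT
    architecture: N-domain, two-residue linker, C-domain."""

    n_domain: tuple[int, int]
    linker: tuple[int, int]
    c_domain: tuple[int, int]

    def __post_init__(self) -> None:
        ranges = [self.n_domain, self.linker, self.c_domain]
        for lo, hi in ranges:
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid range ({lo}, {hi})")
        for (_, hi), (lo, _) in zip(ranges, ranges[1:]):
            if lo <= hi:
                raise ValueError("partition ranges must be disjoint and ordered")

    def regions(self) -> dict[str, tuple[int, int]]:
        return {
            "n_domain": self.n_domain,
            "linker": self.linker,
            "c_domain": self.c_domain,
        }


def _slice(seq: str, region) -> str:
    if region is None:
        return seq
    lo, hi = region
    if lo < 1 or hi > len(seq) or hi < lo:
        raise ValueError(f"region ({lo}, {hi}) outside alignment of length {len(seq)}")
    return seq[lo - 1 : hi]


def _check_aligned(*seqs: str) -> None:
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences are not aligned (lengths {sorted(lengths)})")


def count_substitutions(seq_a: str, seq_b: str, region=None) -> int:
    """Columns in ``region`` where both sequences carry a residue and the
    residues differ.  Gap-vs-residue columns are indels, not substitutions."""
    _check_aligned(seq_a, seq_b)
    a, b = _slice(seq_a, region), _slice(seq_b, region)
    return sum(1 for x, y in zip(a, b) if x != "-" and y != "-" and x != y)


def count_indels(seq_a: str, seq_b: str, region=None) -> int:
    """Columns where exactly one of the two sequences has a gap."""
    _check_aligned(seq_a, seq_b)
    a, b = _slice(seq_a, region), _slice(seq_b, region)
    return sum(1 for x, y in zip(a, b) if (x == "-") != (y == "-"))


def substitution_persistence(
    anc_a: str, anc_b: str, descendant: str, region=None
) -> int:
    """Of the substitutions acquired between ``anc_a`` and ``anc_b``, how
    many are still present (descendant carries anc_b's residue)."""
    _check_aligned(anc_a, anc_b, descendant)
    a = _slice(anc_a, region)
    b = _slice(anc_b, region)
    d = _slice(descendant, region)
    return sum(
        1
        for x, y, z in zip(a, b, d)
        if x != "-" and y != "-" and x != y and z == y
    )


def sequence_identity(
    seq_a: str,
    seq_b: str,
    region=None,
    denominator_policy: str = "alignment_columns",
) -> float:
    """Fraction of identical residues under a declared denominator policy.

    ``alignment_columns``: columns in the region where at least one sequence
    has a residue; ``shorter_sequence``: ungapped length of the shorter
    sequence; ``mean_length``: mean of the two ungapped lengths.
    """
    _check_aligned(seq_a, seq_b)
    a, b = _slice(seq_a, region), _slice(seq_b, region)
    matches = sum(1 for x, y in zip(a, b) if x != "-" and x == y)
    if denominator_policy == "alignment_columns":
        denom = sum(1 for x, y in zip(a, b) if x != "-" or y != "-")
    elif denominator_policy == "shorter_sequence":
        denom = min(len(a.replace("-", "")), len(b.replace("-", "")))
    elif denominator_policy == "mean_length":
        denom = (len(a.replace("-", "")) + len(b.replace("-", ""))) / 2
    else:
        raise ValueError(f"unknown denominator policy {denominator_policy!r}")
    if denom == 0:
        raise ValueError("identity denominator is zero")
    return matches / denom


def bulkiness(sequence: str, volumes: dict | None = None, region=None) -> float:
    """Sum of per-residue side-chain volumes (Å^3) over a region; gaps skipped."""
    volumes = volumes if volumes is not None else ZAMYATNIN_VOLUMES
    total = 0.0
    for res in _slice(sequence, region):
        if res == "-":
            continue
        try:
            total += volumes[res]
        except KeyError:
            raise ValueError(f"no volume tabulated for residue {res!r}") from None
    return total


def first_cys_position(sequence: str) -> int:
    """1-based position (gaps included in numbering) of the first Cys."""
    idx = sequence.find("C")
    if idx < 0:
        raise ValueError("sequence contains no Cys residue")
    return idx + 1


@dataclass(frozen=True)
class KNRatio:
    """K/N ratio over the region from the first Cys to the C-terminus.

    With zero Asn the ratio is undefined (``defined=False``) and reported as
    such, never as a number: ratios fluctuate strongly at very low Asn
    counts, so a pseudo-value would mislead.
    """

    lys: int
    asn: int
    ratio: float | None
    defined: bool


def kn_ratio(sequence: str) -> KNRatio:
    """Lys/Asn count ratio, excluding residues N-terminal of the first Cys."""
    start = first_cys_position(sequence)
    tail = sequence[start - 1 :].replace("-", "")
    lys = tail.count("K")
    asn = tail.count("N")
    if asn == 0:
        return KNRatio(lys=lys, asn=0, ratio=None, defined=False)
    return KNRatio(lys=lys, asn=asn, ratio=lys / asn, defined=True)


# ---------------------------------------------------------------------------
# tree traversal
# ---------------------------------------------------------------------------

def _sequence_for_node(node: dendropy.Node, alignment: AlignmentSet) -> str:
    name = node_name(node)
    if name is None:
        raise FormatError("tree contains an unnamed node; every node needs a sequence")
    try:
        return alignment.get(name)
    except KeyError:
        raise FormatError(f"no sequence in alignment for tree node {name!r}") from None


def branch_lengths_in_substitutions(
    alignment: AlignmentSet, tree: dendropy.Tree, region=None
) -> pd.DataFrame:
    """Annotate every branch with its substitution count and each node with
    the cumulative count from the root.

    Returns a DataFrame (node, parent, substitutions_from_parent, indels,
    cumulative_substitutions_from_root) and stores the same numbers on the
    dendropy nodes (``substitutions_from_parent`` /
    ``cumulative_substitutions``).
    """
    rows = []
    for node in tree.preorder_node_iter():
        seq = _sequence_for_node(node, alignment)
        if node.parent_node is None:
            node.substitutions_from_parent = 0
            node.indels_from_parent = 0
            node.cumulative_substitutions = 0
            parent = None
        else:
            parent_seq = _sequence_for_node(node.parent_node, alignment)
            subs = count_substitutions(parent_seq, seq, region)
            node.substitutions_from_parent = subs
            node.indels_from_parent = count_indels(parent_seq, seq, region)
            node.cumulative_substitutions = (
                node.parent_node.cumulative_substitutions + subs
            )
            parent = node_name(node.parent_node)
        rows.append(
            {
                "node": node_name(node),
                "parent": parent,
                "substitutions_from_parent": node.substitutions_from_parent,
                "indels_from_parent": node.indels_from_parent,
                "cumulative_substitutions_from_root": node.cumulative_substitutions,
            }
        )
    return pd.DataFrame(rows)


def _infer_lineage(name: str) -> str:
    for tag in ("Un", "Cu", "Cd"):
        if tag in name:
            return tag
    return ""


def lineage_descriptor_table(
    alignment: AlignmentSet,
    tree: dendropy.Tree,
    partition: DomainPartition | None = None,
    root_name: str | None = None,
    volumes: dict | None = None,
    identity_policy: str = "alignment_columns",
    bulkiness_from_first_cys: bool = True,
    lineage_of=_infer_lineage,
) -> pd.DataFrame:
    """Per-node descriptor table: substitutions (total and per domain),
    cumulative counts, identity to the root sequence (full and per domain),
    bulkiness and K/N ratio.

    Bulkiness by default excludes residues N-terminal of the first Cys, for
    consistency with the K/N convention; pass
    ``bulkiness_from_first_cys=False`` for whole-sequence sums.
    """
    totals = branch_lengths_in_substitutions(alignment, tree, region=None)
    per_domain: dict[str, pd.DataFrame] = {}
    if partition is not None:
        for dom, region in partition.regions().items():
            per_domain[dom] = branch_lengths_in_substitutions(
                alignment, tree, region=region
            ).set_index("node")
    root = root_name or node_name(tree.seed_node)
    root_seq = alignment.get(root)
    rows = []
    for _, rec in totals.iterrows():
        name = rec["node"]
        seq = alignment.get(name)
        if bulkiness_from_first_cys:
            bulk_region = (first_cys_position(seq), len(seq))
        else:
            bulk_region = None
        kn = kn_ratio(seq)
        row = {
            "node": name,
            "lineage": lineage_of(name),
            "substitutions_from_parent": rec["substitutions_from_parent"],
            "cumulative_substitutions_from_root": rec[
                "cumulative_substitutions_from_root"
            ],
            "identity_to_root": sequence_identity(
                root_seq, seq, denominator_policy=identity_policy
            ),
            "bulkiness_A3": bulkiness(seq, volumes=volumes, region=bulk_region),
            "kn_lys": kn.lys,
            "kn_asn": kn.asn,
            "kn_ratio": kn.ratio if kn.defined else float("nan"),
            "kn_defined": kn.defined,
        }
        for dom, table in per_domain.items():
            row[f"substitutions_{dom}"] = table.loc[name, "substitutions_from_parent"]
            row[f"identity_to_root_{dom}"] = sequence_identity(
                root_seq,
                seq,
                region=partition.regions()[dom],
                denominator_policy=identity_policy,
            )
        rows.append(row)
    return pd.DataFrame(rows)
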