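"""Readers and writers for the external formats the pipeline touches.

Canonical peak-table dialect
----------------------------
The relaxation peak tables are header-driven delimited text (TSV canonical,
CSV accepted).  Required leading columns are ``peak_id``, ``h_ppm`` and
``n_ppm``; they are followed either by one intensity column per CPMG
relaxation delay, named ``I_<delay>ms`` (e.g. ``I_20ms``), or by a single
column ``I`` for a plain HSQC peak list.  Empty intensity cells denote peaks
that were not observable at that delay and are kept as missing values —
never silently coerced to zero.

Alignments are read with Biopython (FASTA/Clustal), phylogenies with
dendropy (Newick, underscores preserved), and NMR structure bundles from
MODEL-separated PDB files with Bio.PDB.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.PDB import PDBParser

from mtconform.errors import FormatError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Default CPMG relaxation delays (ms) of the T2 series.
DEFAULT_DELAYS_MS = (20.0, 50.0, 75.0, 100.0, 125.0, 150.0, 200.0, 250.0, 300.0)

_DELAY_COLUMN = re.compile(r"^I_(\d+(?:\.\d+)?)ms$")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All tunable thresholds of the analysis in one place.

    The delimiters (``t2_delim_ms``, ``inhom_delim``) are approximate
    boundaries between low and high conformational stability and are
    deliberately configurable rather than hard-coded.
    """

    delays_ms: tuple[float, ...] = DEFAULT_DELAYS_MS
    n_resamples: int = 500
    t2_error_cutoff_ms: float = 25.0
    top_k: int = 60
    t2_delim_ms: float = 140.0
    inhom_delim: float = 0.55
    peak_count_tolerance: float = 0.15
    random_seed: int | None = None
    #: 1-based inclusive alignment-column ranges (N-domain, linker, C-domain).
    domain_partition: dict | None = None
    #: identity denominator policy: alignment_columns | shorter_sequence | mean_length
    identity_denominator: str = "alignment_columns"
    #: which standard error the final Monte-Carlo resampling draw uses:
    #: "refit" (SE of each one-parameter refit) or "initial_fit".
    mc_se_source: str = "refit"

    def __post_init__(self) -> None:
        delays = tuple(float(d) for d in self.delays_ms)
        if any(d <= 0 for d in delays):
            raise ValueError("relaxation delays must be strictly positive")
        if list(delays) != sorted(delays) or len(set(delays)) != len(delays):
            raise ValueError("relaxation delays must be strictly increasing")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        for name in ("t2_error_cutoff_ms", "t2_delim_ms", "inhom_delim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.identity_denominator not in (
            "alignment_columns",
            "shorter_sequence",
            "mean_length",
        ):
            raise ValueError(f"unknown identity policy {self.identity_denominator!r}")
        if self.mc_se_source not in ("refit", "initial_fit"):
            raise ValueError(f"unknown mc_se_source {self.mc_se_source!r}")
        self.delays_ms = delays

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data["delays_ms"] = list(self.delays_ms)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# peak tables
# ---------------------------------------------------------------------------

@dataclass
class PeakTable:
    """A peak list with one intensity column per relaxation delay.

    ``data`` holds columns ``peak_id``, ``h_ppm``, ``n_ppm`` followed by the
    intensity columns.  Missing intensities are NaN ("absent", never zero).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["peak_id", "h_ppm", "n_ppm"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise FormatError(f"peak table lacks required column(s) {missing}")
        ids = self.data["peak_id"].astype(str)
        dup = ids[ids.duplicated()]
        if not dup.empty:
            raise FormatError(f"duplicate peak_id {dup.iloc[0]!r} in peak table")
        extra = [c for c in self.data.columns if c not in required]
        bad = [c for c in extra if c != "I" and not _DELAY_COLUMN.match(c)]
        if bad:
            raise FormatError(f"unrecognized intensity column(s) {bad}")
        delays = self.delays_ms
        if delays and (list(delays) != sorted(delays) or any(d <= 0 for d in delays)):
            raise FormatError("delay columns must be strictly increasing positive ms")
        for col in extra:
            vals = self.data[col].to_numpy(dtype=float)
            if np.isinf(vals).any():
                raise FormatError(f"non-finite intensity in column {col!r}")

    @property
    def delays_ms(self) -> list[float]:
        out = []
        for col in self.data.columns:
            m = _DELAY_COLUMN.match(col)
            if m:
                out.append(float(m.group(1)))
        return out

    @property
    def intensity_columns(self) -> list[str]:
        return [c for c in self.data.columns if c == "I" or _DELAY_COLUMN.match(c)]

    @property
    def n_peaks(self) -> int:
        return len(self.data)

    @property
    def peak_ids(self) -> list[str]:
        return [str(p) for p in self.data["peak_id"]]

    def series(self, peak_id: str):
        """Relaxation series for one peak; absent delays dropped pairwise."""
        from mtconform.relaxation import RelaxationSeries

        row = self.data.loc[self.data["peak_id"].astype(str) == str(peak_id)]
        if row.empty:
            raise KeyError(f"no peak {peak_id!r} in table")
        delays = np.asarray(self.delays_ms, dtype=float)
        cols = [c for c in self.data.columns if _DELAY_COLUMN.match(c)]
        intens = row[cols].to_numpy(dtype=float).ravel()
        keep = np.isfinite(intens)
        return RelaxationSeries(
            peak_id=str(peak_id), delays_ms=delays[keep], intensities=intens[keep]
        )

    def iter_series(self):
        for pid in self.peak_ids:
            yield self.series(pid)

    def intensities(self, column: str | None = None) -> np.ndarray:
        """Observed (finite) intensities of one column, default the HSQC
        column ``I`` or, failing that, the first delay column."""
        if column is None:
            cols = self.intensity_columns
            if not cols:
                raise FormatError("peak table has no intensity column")
            column = "I" if "I" in cols else cols[0]
        vals = self.data[column].to_numpy(dtype=float)
        return vals[np.isfinite(vals)]

    def write(self, path: str | Path) -> None:
        sep = "," if str(path).endswith(".csv") else "\t"
        self.data.to_csv(path, sep=sep, index=False)


def read_peak_table(path: str | Path, dialect: str | None = None) -> PeakTable:
    """Read a canonical-dialect peak table (TSV default, CSV accepted).

    Non-numeric intensity cells raise a :class:`FormatError` naming the
    offending row; empty cells become missing values.
    """
    if dialect is None:
        dialect = "csv" if str(path).endswith(".csv") else "tsv"
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    raw = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    raw.columns = [c.strip() for c in raw.columns]
    for col in ("peak_id", "h_ppm", "n_ppm"):
        if col not in raw.columns:
            raise FormatError(f"peak table {path} lacks column {col!r}")
    out = pd.DataFrame({"peak_id": raw["peak_id"].astype(str).str.strip()})
    numeric_cols = [c for c in raw.columns if c != "peak_id"]
    for col in numeric_cols:
        converted = []
        for pid, cell in zip(out["peak_id"], raw[col]):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
                converted.append(np.nan)
                continue
            try:
                converted.append(float(cell))
            except ValueError:
                raise FormatError(
                    f"non-numeric intensity {cell!r} for peak {pid!r} in column {col!r}"
                ) from None
        out[col] = converted
    return PeakTable(out)


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

@dataclass
class AlignmentSet:
    """An aligned set of amino-acid sequences ('-' gaps), names preserved."""

    sequences: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise FormatError("alignment is empty")
        self.sequences = [(str(n), str(s).upper()) for n, s in self.sequences]
        length = len(self.sequences[0][1])
        for name, seq in self.sequences:
            if len(seq) != length:
                raise FormatError(
                    f"ragged alignment: sequence {name!r} has length "
                    f"{len(seq)}, expected {length}"
                )
            bad = set(seq) - set(AMINO_ACIDS + "-")
            if bad:
                raise FormatError(f"sequence {name!r} contains invalid symbols {sorted(bad)}")
        names = [n for n, _ in self.sequences]
        if len(set(names)) != len(names):
            raise FormatError("duplicate sequence names in alignment")

    @property
    def column_count(self) -> int:
        return len(self.sequences[0][1])

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.sequences]

    def __len__(self) -> int:
        return len(self.sequences)

    def __contains__(self, name: str) -> bool:
        return name in dict(self.sequences)

    def get(self, name: str) -> str:
        try:
            return dict(self.sequences)[name]
        except KeyError:
            raise KeyError(f"no sequence named {name!r} in alignment") from None


def read_alignment(path: str | Path, format: str = "fasta") -> AlignmentSet:
    """Read a FASTA or Clustal alignment; ragged input raises naming the
    offending sequence."""
    if format not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {format!r}")
    records = list(SeqIO.parse(str(path), format))
    if not records:
        raise FormatError(f"no sequences found in {path}")
    return AlignmentSet([(r.id, str(r.seq)) for r in records])


def write_alignment(alignment: AlignmentSet, path: str | Path, format: str = "fasta") -> None:
    if format == "fasta":
        with open(path, "w") as fh:
            for name, seq in alignment.sequences:
                fh.write(f">{name}\n{seq}\n")
    elif format == "clustal":
        from Bio.Align import MultipleSeqAlignment
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        from Bio import AlignIO

        msa = MultipleSeqAlignment(
            [SeqRecord(Seq(seq), id=name, description="") for name, seq in alignment.sequences]
        )
        AlignIO.write(msa, str(path), "clustal")
    else:
        raise ValueError(f"unsupported alignment format {format!r}")


# ---------------------------------------------------------------------------
# phylogenies
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree keeping internal node labels and underscores."""
    tree = dendropy.Tree.get(
        path=str(path),
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
    )


def node_name(node: dendropy.Node) -> str | None:
    """Resolvable name of a node: taxon label for leaves, label otherwise."""
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label


# ---------------------------------------------------------------------------
# structure bundles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRecord:
    chain: str
    residue_number: int
    residue_name: str
    atom_name: str
    xyz: tuple[float, float, float]

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chain, self.residue_number, self.residue_name, self.atom_name)


@dataclass
class StructureBundle:
    """The conformer models of one NMR structure (identical atom inventory)."""

    models: list[list[AtomRecord]]

    def __post_init__(self) -> None:
        if not self.models:
            raise FormatError("structure bundle contains no models")
        inventory = [a.key for a in self.models[0]]
        for i, model in enumerate(self.models[1:], start=2):
            if [a.key for a in model] != inventory:
                raise FormatError(
                    f"model {i} atom inventory differs from model 1 "
                    f"({len(model)} vs {len(inventory)} atoms or order mismatch)"
                )
        for model in self.models:
            for atom in model:
                if not all(np.isfinite(atom.xyz)):
                    raise FormatError(f"non-finite coordinates for atom {atom.key}")

    @property
    def n_models(self) -> int:
        return len(self.models)

    def coordinates(self, keys: Sequence[tuple]) -> np.ndarray:
        """(n_models, n_atoms, 3) coordinates for the given atom keys."""
        index = {a.key: i for i, a in enumerate(self.models[0])}
        rows = [index[k] for k in keys]
        coords = np.array([[m[i].xyz for i in rows] for m in self.models], dtype=float)
        return coords


def read_structure_bundle(path: str | Path) -> StructureBundle:
    """Read a (possibly multi-MODEL) PDB file into a StructureBundle."""
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("bundle", str(path))
    models = []
    for model in structure:
        atoms = []
        for chain in model:
            for residue in chain:
                het, resnum, _icode = residue.id
                if het.strip():
                    continue  # skip heteroatoms/waters
                for atom in residue:
                    x, y, z = atom.coord
                    atoms.append(
                        AtomRecord(
                            chain=chain.id,
                            residue_number=int(resnum),
                            residue_name=residue.resname.strip(),
                            atom_name=atom.get_name().strip(),
                            xyz=(float(x), float(y), float(z)),
                        )
                    )
        atoms.sort(key=lambda a: (a.chain, a.residue_number, a.atom_name))
        models.append(atoms)
    if not models:
        raise FormatError(f"no models found in {path}")
    return StructureBundle(models)
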