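"""Synthetic inputs with recorded ground truth for every pipeline stage.

Nothing here is measured data: relaxation series are exponential decays
with additive Gaussian noise, spectra are log-normal intensity draws with
regime-dependent peak dropout/duplication, sequence evolution applies an
exact number of random substitutions per branch, and structure bundles are
jittered random chains.  Each generator returns the generating parameters
("ground truth") alongside the data so analyses can be checked for exact
recovery.

``stylommatophora_lineage`` builds a fully synthetic stand-in for the snail
metallothionein alignment/phylogeny: a deterministic 61-sequence alignment
whose hand-placed per-branch substitution events reproduce the published
lineage bookkeeping (11 substitutions to the first Cu-lineage ancestor, 7
of them persisting in HpCuMT, 8 more to the next ancestor with 4
persisting, N-domain counts of 1/5/8 and a cumulative Cd-lineage total of
23).  The real supplementary alignment is not shipped; this fixture has the
same bookkeeping structure, not the real residues.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from mtconform.evolution import DomainPartition
from mtconform.io_formats import (
    DEFAULT_DELAYS_MS,
    AlignmentSet,
    AtomRecord,
    PeakTable,
    StructureBundle,
    node_name,
)

# ---------------------------------------------------------------------------
# relaxation series and spectra
# ---------------------------------------------------------------------------

@dataclass
class RegimeSpec:
    """Generating parameters of one synthetic protein-metal spectrum/series.

    Defaults emulate a two-domain metallothionein with ~60 observable
    amides.  Per-regime presets via :meth:`for_regime`.
    """

    regime: str = "stable"
    n_residues: int = 66
    t2_mean_ms: float = 170.0
    t2_sd_ms: float = 25.0
    missing_fraction: float = 0.5
    extra_weak_fraction: float = 0.5
    weak_intensity_factor: float = 0.25
    t2_shortening: float = 0.8
    intensity_cv: float = 0.25
    noise_sd_fraction: float = 0.02
    base_intensity: float = 100.0
    seed: int | None = None

    _PRESETS = {
        "stable": {"t2_mean_ms": 170.0, "t2_sd_ms": 25.0},
        "intermediate_exchange": {"t2_mean_ms": 90.0, "t2_sd_ms": 20.0},
        "slow_exchange": {"t2_mean_ms": 120.0, "t2_sd_ms": 30.0},
        "mixed": {
            "t2_mean_ms": 100.0,
            "t2_sd_ms": 25.0,
            "missing_fraction": 0.3,
            "extra_weak_fraction": 0.4,
        },
    }

    def __post_init__(self) -> None:
        if self.regime not in self._PRESETS:
            raise ValueError(f"unknown regime {self.regime!r}")
        for name in ("missing_fraction", "extra_weak_fraction", "weak_intensity_factor"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.t2_mean_ms <= 0:
            raise ValueError("t2_mean_ms must be > 0")

    @classmethod
    def for_regime(cls, regime: str, seed: int | None = None, **overrides) -> "RegimeSpec":
        params = dict(cls._PRESETS[regime])
        params.update(overrides)
        return cls(regime=regime, seed=seed, **params)


def _base_peaks(spec: RegimeSpec, rng: np.random.Generator):
    n = spec.n_residues
    ids = [f"R{i + 1}" for i in range(n)]
    h_ppm = rng.uniform(6.5, 10.5, size=n)
    n_ppm = rng.uniform(104.0, 132.0, size=n)
    sigma = float(np.sqrt(np.log1p(spec.intensity_cv**2)))
    i0 = spec.base_intensity * rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=n)
    t2 = np.clip(rng.normal(spec.t2_mean_ms, spec.t2_sd_ms, size=n), 20.0, None)
    return ids, h_ppm, n_ppm, i0, t2


def _apply_regime(spec: RegimeSpec, rng, ids, h_ppm, n_ppm, i0, t2):
    """Regime-dependent peak dropout and weak-duplicate insertion."""
    ids, h_ppm, n_ppm = list(ids), list(h_ppm), list(n_ppm)
    i0, t2 = list(i0), list(t2)
    if spec.regime in ("intermediate_exchange", "mixed"):
        n_missing = round(spec.missing_fraction * spec.n_residues)
        drop = set(rng.choice(len(ids), size=n_missing, replace=False).tolist())
        keep = [i for i in range(len(ids)) if i not in drop]
        ids = [ids[i] for i in keep]
        h_ppm = [h_ppm[i] for i in keep]
        n_ppm = [n_ppm[i] for i in keep]
        i0 = [i0[i] for i in keep]
        # surviving neighbours feel the exchange too: shortened T2
        t2 = [t2[i] * spec.t2_shortening for i in keep]
    if spec.regime in ("slow_exchange", "mixed"):
        n_extra = round(spec.extra_weak_fraction * spec.n_residues)
        sources = rng.choice(len(ids), size=n_extra, replace=n_extra > len(ids))
        for j, src in enumerate(sources.tolist()):
            ids.append(f"{ids[src]}x{j + 1}")
            h_ppm.append(h_ppm[src] + rng.normal(0, 0.05))
            n_ppm.append(n_ppm[src] + rng.normal(0, 0.3))
            i0.append(i0[src] * spec.weak_intensity_factor)
            t2.append(float(np.clip(rng.normal(spec.t2_mean_ms, spec.t2_sd_ms), 20.0, None)))
    return ids, h_ppm, n_ppm, np.asarray(i0), np.asarray(t2)


def simulate_relaxation_table(
    spec: RegimeSpec, delays_ms=DEFAULT_DELAYS_MS
) -> tuple[PeakTable, dict]:
    """Synthetic CPMG relaxation peak table plus ground-truth sidecar."""
    rng = np.random.default_rng(spec.seed)
    ids, h_ppm, n_ppm, i0, t2 = _apply_regime(spec, rng, *_base_peaks(spec, rng))
    delays = np.asarray(delays_ms, dtype=float)
    data = {"peak_id": ids, "h_ppm": h_ppm, "n_ppm": n_ppm}
    clean = i0[:, None] * np.exp(-delays[None, :] / t2[:, None])
    noise = rng.normal(0, 1, size=clean.shape) * (spec.noise_sd_fraction * i0)[:, None]
    noisy = clean + noise
    for j, d in enumerate(delays):
        data[f"I_{d:g}ms"] = noisy[:, j]
    table = PeakTable(pd.DataFrame(data))
    truth = {
        "regime": spec.regime,
        "spec": asdict(spec),
        "peaks": {
            pid: {"t2_ms": float(t), "i0": float(a)}
            for pid, t, a in zip(ids, t2, i0)
        },
    }
    return table, truth


def simulate_spectrum(spec: RegimeSpec) -> tuple[PeakTable, dict]:
    """Synthetic plain-HSQC peak list (single intensity column) + truth."""
    rng = np.random.default_rng(spec.seed)
    ids, h_ppm, n_ppm, i0, t2 = _apply_regime(spec, rng, *_base_peaks(spec, rng))
    intensity = i0 + rng.normal(0, 1, size=i0.size) * spec.noise_sd_fraction * i0
    intensity = np.clip(intensity, 0.0, None)
    table = PeakTable(
        pd.DataFrame(
            {"peak_id": ids, "h_ppm": h_ppm, "n_ppm": n_ppm, "I": intensity}
        )
    )
    truth = {
        "regime": spec.regime,
        "spec": asdict(spec),
        "n_expected": spec.n_residues,
        "n_observed": len(ids),
    }
    return table, truth


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

@dataclass
class EvolutionSpec:
    """Exact-count substitution evolution down a named tree."""

    root_sequence: str
    tree: dendropy.Tree
    branch_counts: dict[str, int]  # node name -> substitutions from parent
    forbid_cys_substitution: bool = True
    unique_columns: bool = False  # no column substitutes twice anywhere
    seed: int | None = None


@dataclass
class SimulatedEvolution:
    alignment: AlignmentSet
    tree: dendropy.Tree
    branch_counts: dict[str, int]


def tree_from_parent_map(children: dict[str, list[str]], root: str) -> dendropy.Tree:
    """Build a rooted dendropy tree with named internal nodes and leaves."""
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True

    def build(name: str, node: dendropy.Node) -> None:
        kids = children.get(name, [])
        if kids:
            node.label = name
            for kid in kids:
                child = node.new_child()
                build(kid, child)
        else:
            node.taxon = taxa.new_taxon(name)

    build(root, tree.seed_node)
    return tree


def simulate_sequence_evolution(spec: EvolutionSpec) -> SimulatedEvolution:
    """Evolve sequences down the tree with exactly the requested number of
    random substitutions per branch (columns drawn without replacement
    within a branch; Cys columns untouched when the flag is set)."""
    rng = np.random.default_rng(spec.seed)
    root_seq = spec.root_sequence.upper()
    alphabet = [a for a in "ARNDQEGHILKMFPSTWYV"]
    used_columns: set[int] = set()
    sequences: dict[str, str] = {}

    def mutable_columns(seq: str) -> list[int]:
        cols = []
        for i, res in enumerate(seq):
            if res == "-":
                continue
            if spec.forbid_cys_substitution and res == "C":
                continue
            if spec.unique_columns and i in used_columns:
                continue
            cols.append(i)
        return cols

    for node in spec.tree.preorder_node_iter():
        name = node_name(node)
        if node.parent_node is None:
            sequences[name] = root_seq
            continue
        parent_seq = sequences[node_name(node.parent_node)]
        count = int(spec.branch_counts.get(name, 0))
        cols = mutable_columns(parent_seq)
        if count > len(cols):
            raise ValueError(
                f"branch to {name!r} requests {count} substitutions but only "
                f"{len(cols)} mutable columns remain"
            )
        chosen = rng.choice(len(cols), size=count, replace=False) if count else []
        seq = list(parent_seq)
        for idx in np.asarray(chosen, dtype=int):
            col = cols[idx]
            current = seq[col]
            options = [a for a in alphabet if a != current]
            seq[col] = options[rng.integers(len(options))]
            used_columns.add(col)
        sequences[name] = "".join(seq)

    names = [node_name(n) for n in spec.tree.preorder_node_iter()]
    alignment = AlignmentSet([(n, sequences[n]) for n in names])
    return SimulatedEvolution(
        alignment=alignment, tree=spec.tree, branch_counts=dict(spec.branch_counts)
    )


# ---------------------------------------------------------------------------
# the snail MT lineage fixture (synthetic stand-in for the real alignment)
# ---------------------------------------------------------------------------

#: 66-column synthetic root ("a1CdMT"): two 9-Cys domains joined by a
#: two-residue linker, first Cys at column 11.
LINEAGE_ROOT = (
    "MSGKAGETTS" "CAGCKCGQCT" "SCKSCKCGNC" "KCSG"
    "KECKTCGCST" "CNKCEACTAG" "TKCSECSGCK" "AK"
)

LINEAGE_PARTITION = DomainPartition(n_domain=(1, 32), linker=(33, 34), c_domain=(35, 66))

#: Hand-placed substitution columns (1-based) per branch.  The layout pins
#: the lineage bookkeeping: 11 substitutions root -> a2CuMT with 4 of them
#: overwritten later on the Cu path (7 persist in HpCuMT), 8 a2CuMT ->
#: a3CuMT with 4 overwritten (4 persist), single N-domain change on the Un
#: path, 5 fresh N-domain changes a3CuMT -> HpCuMT, 8 N-domain changes
#: a4CdMT -> HpCdMT, and 23 distinct-column substitutions along the whole
#: Cd lineage.
_LINEAGE_EDITS: dict[str, list[int]] = {
    "a2CdMT": [],
    "a2CuMT": [4, 7, 9, 18, 23, 36, 44, 47, 53, 59, 65],
    "a3CuMT": [6, 12, 38, 43, 49, 55, 61, 64],
    "a4CuMT": [2, 5, 36, 38, 43, 44],
    "a5CuMT": [10, 15, 47, 49],
    "HpCuMT": [20, 53, 55],
    "a4UnMT": [8, 39, 46, 50, 54, 58, 62],
    "a5UnMT": [41],
    "HpUnMT1": [3],
    "HpUnMT2": [],
    "a4CdMT": [1, 3, 5, 8, 10, 13, 18, 21, 23, 35, 39, 46, 52],
    "a5CdMT": [2, 6, 9, 24, 53],
    "HpCdMT": [4, 7, 12, 17, 59],
}

#: The one deletion of the lineage sits in a4UnMT (column 66); its
#: descendants carry the root residue again, so both adjacent branches have
#: an indel and no substitution at that column.
_LINEAGE_DELETION = {"a4UnMT": 66}

_LINEAGE_CHILDREN: dict[str, list[str]] = {
    "a1CdMT": ["a2CdMT", "a2CuMT"],
    "a2CdMT": ["AvCdMT", "a4CdMT"],
    "a4CdMT": ["CaCdMT", "a5CdMT"],
    "a5CdMT": ["CoCdMT", "HpCdMT"],
    "a2CuMT": ["AvCuMT", "a3CuMT"],
    "a3CuMT": ["a4CuMT", "a4UnMT"],
    "a4CuMT": ["CaCuMT", "a5CuMT"],
    "a5CuMT": ["CoCuMT", "HpCuMT"],
    "a4UnMT": ["CaUnMT", "a5UnMT"],
    "a5UnMT": ["CoUnMT", "HpUnMT1", "HpUnMT2"],
}

_COMPANIONS = [
    "AvCdMT", "AvCuMT", "CaCdMT", "CaCuMT", "CaUnMT", "CoCdMT", "CoCuMT", "CoUnMT",
]

_MUTATION_CYCLE = "ARNDQEGHILKMFPSTWYV"  # fixed-point-free shift, never Cys


def _shift_residue(res: str) -> str:
    idx = _MUTATION_CYCLE.index(res)
    return _MUTATION_CYCLE[(idx + 1) % len(_MUTATION_CYCLE)]


@dataclass
class LineageFixture:
    """Synthetic stand-in for the study alignment/tree with known truth."""

    alignment: AlignmentSet
    tree: dendropy.Tree
    partition: DomainPartition
    branch_counts: dict[str, int]
    branch_indels: dict[str, int]


def stylommatophora_lineage(n_sequences: int = 61, filler_seed: int = 2023) -> LineageFixture:
    """Deterministic synthetic MT lineage: 14 lineage nodes, 8 companion
    leaves and enough filler extant sequences for ``n_sequences`` total.

    The lineage edits are hand-placed (see ``_LINEAGE_EDITS``); fillers and
    companions are seeded random variants of their ancestor and carry no
    constraints.
    """
    sequences: dict[str, str] = {"a1CdMT": LINEAGE_ROOT}
    order = ["a1CdMT"]
    rng = np.random.default_rng(filler_seed)
    cys_cols = {i for i, r in enumerate(LINEAGE_ROOT) if r == "C"}

    def apply_edits(parent_seq: str, name: str) -> str:
        seq = list(parent_seq)
        for col in _LINEAGE_EDITS.get(name, []):
            res = seq[col - 1]
            if res in ("-", "C"):
                raise AssertionError(f"edit at untouchable column {col} for {name}")
            seq[col - 1] = _shift_residue(res)
        if name in _LINEAGE_DELETION:
            seq[_LINEAGE_DELETION[name] - 1] = "-"
        else:
            # descendants of the deletion carry the root residue again
            for col in _LINEAGE_DELETION.values():
                if seq[col - 1] == "-":
                    seq[col - 1] = LINEAGE_ROOT[col - 1]
        return "".join(seq)

    def random_variant(parent_seq: str, n_subs: int) -> str:
        seq = list(parent_seq)
        candidates = [
            i for i in range(len(seq)) if i not in cys_cols and seq[i] != "-"
        ]
        cols = rng.choice(len(candidates), size=n_subs, replace=False)
        for idx in np.asarray(cols, dtype=int):
            col = candidates[idx]
            options = [a for a in _MUTATION_CYCLE if a != seq[col]]
            seq[col] = options[rng.integers(len(options))]
        return "".join(seq)

    def walk(name: str) -> None:
        for child in _LINEAGE_CHILDREN.get(name, []):
            if child in _COMPANIONS:
                sequences[child] = random_variant(sequences[name], 3)
            else:
                sequences[child] = apply_edits(sequences[name], child)
            order.append(child)
            walk(child)

    walk("a1CdMT")

    n_filler = n_sequences - len(order)
    if n_filler < 0:
        raise ValueError(f"n_sequences must be >= {len(order)}")
    for i in range(n_filler):
        name = f"GastropodMT{i + 1:02d}"
        sequences[name] = random_variant(LINEAGE_ROOT, int(rng.integers(4, 9)))
        order.append(name)

    alignment = AlignmentSet([(n, sequences[n]) for n in order])
    tree = tree_from_parent_map(_LINEAGE_CHILDREN, "a1CdMT")
    branch_counts = {n: len(cols) for n, cols in _LINEAGE_EDITS.items()}
    branch_counts.update({c: 3 for c in _COMPANIONS})
    # CaUnMT inherits a4UnMT's gap, so only the branches into and out of
    # a4UnMT (on the a5 path) cross the deletion.
    branch_indels = {"a4UnMT": 1, "a5UnMT": 1}
    return LineageFixture(
        alignment=alignment,
        tree=tree,
        partition=LINEAGE_PARTITION,
        branch_counts=branch_counts,
        branch_indels=branch_indels,
    )


# ---------------------------------------------------------------------------
# structure bundles
# ---------------------------------------------------------------------------

def make_toy_bundle(
    n_residues: int = 20,
    n_models: int = 5,
    noise: float = 0.3,
    seed: int | None = 0,
    cys_every: int = 3,
) -> StructureBundle:
    """Random smooth CA chain (3.8 Å steps) with SG atoms on Cys residues,
    replicated into ``n_models`` conformers with Gaussian coordinate jitter."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(n_residues, 3))
    steps = 3.8 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
    base = np.cumsum(steps, axis=0)
    sg_dir = rng.normal(size=(n_residues, 3))
    sg_dir = 1.8 * sg_dir / np.linalg.norm(sg_dir, axis=1, keepdims=True)
    models = []
    for _ in range(n_models):
        jitter = rng.normal(0, noise, size=base.shape)
        atoms = []
        for i in range(n_residues):
            is_cys = (i % cys_every) == 0
            resname = "CYS" if is_cys else "ALA"
            ca = base[i] + jitter[i]
            atoms.append(
                AtomRecord("A", i + 1, resname, "CA", tuple(float(v) for v in ca))
            )
            if is_cys:
                sg = ca + sg_dir[i]
                atoms.append(
                    AtomRecord("A", i + 1, resname, "SG", tuple(float(v) for v in sg))
                )
        atoms.sort(key=lambda a: (a.chain, a.residue_number, a.atom_name))
        models.append(atoms)
    return StructureBundle(models)


def transform_bundle(
    bundle: StructureBundle, rotation: np.ndarray, translation=(0.0, 0.0, 0.0)
) -> StructureBundle:
    """Apply one rigid transform to every model of a bundle."""
    rotation = np.asarray(rotation, dtype=float)
    translation = np.asarray(translation, dtype=float)
    models = []
    for model in bundle.models:
        atoms = []
        for atom in model:
            xyz = rotation @ np.asarray(atom.xyz) + translation
            atoms.append(
                AtomRecord(
                    atom.chain,
                    atom.residue_number,
                    atom.residue_name,
                    atom.atom_name,
                    tuple(float(v) for v in xyz),
                )
            )
        models.append(atoms)
    return StructureBundle(models)


def write_ground_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
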