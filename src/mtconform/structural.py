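"""Averaged pairwise RMSD between two NMR structure bundles.

For every pair (conformer i of bundle A, conformer j of bundle B) the
selected atoms are superimposed by optimal least-squares rigid-body
rotation (SVD, reflections disallowed) and the RMSD is computed; the mean
and standard deviation over all |A| x |B| pairs summarise how similar the
two ensembles are.  Selections are C-alpha atoms or the Cys S-gamma atoms
of a residue range, superposition is performed on the selection itself
(domain-wise, not whole-molecule, when a domain range is given).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.SVDSuperimposer import SVDSuperimposer

from mtconform.errors import InsufficientDataError
from mtconform.io_formats import StructureBundle


@dataclass(frozen=True)
class AtomSelection:
    """Which atoms enter the superposition and the RMSD."""

    atom_policy: str = "c_alpha"  # "c_alpha" | "cys_s_gamma"
    residue_range: tuple[int, int] | None = None  # 1-based inclusive

    def __post_init__(self) -> None:
        if self.atom_policy not in ("c_alpha", "cys_s_gamma"):
            raise ValueError(f"unknown atom policy {self.atom_policy!r}")


def _selected_residues(bundle: StructureBundle, selection: AtomSelection) -> dict:
    """Map residue_number -> atom key for the selected atom of each residue."""
    wanted_atom = "CA" if selection.atom_policy == "c_alpha" else "SG"
    out = {}
    for atom in bundle.models[0]:
        if atom.atom_name != wanted_atom:
            continue
        if selection.atom_policy == "cys_s_gamma" and atom.residue_name != "CYS":
            continue
        if selection.residue_range is not None:
            lo, hi = selection.residue_range
            if not (lo <= atom.residue_number <= hi):
                continue
        out[atom.residue_number] = atom.key
    return out


def superimposed_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """RMSD of two (n, 3) coordinate sets after optimal rigid superposition."""
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (n, 3)")
    sup = SVDSuperimposer()
    sup.set(x, y)
    sup.run()
    return float(sup.get_rms())


def pairwise_bundle_rmsd(
    bundle_a: StructureBundle,
    bundle_b: StructureBundle,
    selection: AtomSelection | None = None,
    residue_map: dict[int, int] | None = None,
) -> tuple[float, float, int]:
    """Mean and SD of the RMSDs over all conformer pairs of two bundles.

    ``residue_map`` maps residue numbers of A to residue numbers of B (for
    non-identical proteins, e.g. derived from an alignment); identity by
    default.  Requires at least three mapped atoms (superposition is
    under-determined below that).  Returns ``(mean_rmsd, sd_rmsd, n_pairs)``
    in Å; the SD uses ``ddof=1`` (0.0 for a single pair).
    """
    selection = selection or AtomSelection()
    res_a = _selected_residues(bundle_a, selection)
    res_b = _selected_residues(bundle_b, selection)
    residue_map = residue_map or {r: r for r in res_a}
    keys_a, keys_b = [], []
    for ra in sorted(res_a):
        rb = residue_map.get(ra)
        if rb is not None and rb in res_b:
            keys_a.append(res_a[ra])
            keys_b.append(res_b[rb])
    if len(keys_a) < 3:
        raise InsufficientDataError(
            f"only {len(keys_a)} mapped atoms; superposition needs >= 3"
        )
    coords_a = bundle_a.coordinates(keys_a)
    coords_b = bundle_b.coordinates(keys_b)
    rmsds = [
        superimposed_rmsd(ca, cb) for ca in coords_a for cb in coords_b
    ]
    rmsds = np.asarray(rmsds)
    sd = float(rmsds.std(ddof=1)) if rmsds.size > 1 else 0.0
    return float(rmsds.mean()), sd, int(rmsds.size)
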