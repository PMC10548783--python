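"""Peak-intensity inhomogeneity statistic S.

For one HSQC spectrum the k (default 60) most intense peaks are kept; if
fewer than k peaks are observed the list is padded with zeros, so that
excessively broadened (invisible) peaks still count.  Intensities are then
normalised by their mean and S is the mean absolute deviation of the
normalised values from 1:

    I_norm = I / mean(I)
    S      = mean(|I_norm - 1|)

S = 0 for perfectly homogeneous spectra and grows both with intensity spread
and with missing peaks.  For n equal peaks padded to k the closed form is
S = 2 (k - n) / k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from mtconform.errors import InsufficientDataError
from mtconform.io_formats import PeakTable


def select_top_k(intensities, k: int = 60, peak_ids=None) -> np.ndarray:
    """The k largest intensities in descending order, zero-padded to length k.

    Ties at the k-th value are broken deterministically by a stable sort on
    (intensity descending, peak_id ascending) when ids are given, otherwise
    on input position.  Negative intensities are rejected.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = np.asarray(intensities, dtype=float)
    if values.ndim != 1:
        raise ValueError("intensities must be one-dimensional")
    if np.any(values < 0):
        raise ValueError("negative peak intensities are not supported")
    if values.size == 0:
        warnings.warn("empty spectrum: padding all k intensities with zero")
        return np.zeros(k)
    if peak_ids is not None:
        order = sorted(range(values.size), key=lambda i: (-values[i], str(peak_ids[i])))
    else:
        order = sorted(range(values.size), key=lambda i: (-values[i], i))
    top = values[order][:k]
    if top.size < k:
        top = np.concatenate([top, np.zeros(k - top.size)])
    return top


def inhomogeneity(padded) -> float:
    """S of an already top-k-selected, zero-padded intensity list."""
    values = np.asarray(padded, dtype=float)
    mean = values.mean()
    if mean == 0:
        raise InsufficientDataError("inhomogeneity undefined for an all-zero spectrum")
    normalized = values / mean
    return float(np.mean(np.abs(normalized - 1.0)))


def expected_peak_count(sequence: str) -> int:
    """Approximate number of observable backbone amide peaks for a
    construct: its non-proline residues (gaps ignored)."""
    seq = sequence.replace("-", "")
    return sum(1 for r in seq if r != "P")


@dataclass
class SpectrumSummary:
    """Peak count, S and max-normalised intensities of one spectrum."""

    protein_id: str
    metal: str
    peak_count: int
    intensities: np.ndarray
    s_value: float
    max_normalized: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.max_normalized is None:
            peak = self.intensities.max() if self.intensities.size else 1.0
            self.max_normalized = self.intensities / peak
        if self.s_value < 0:
            raise ValueError("s_value must be >= 0")


def summarize_spectrum(
    table: PeakTable,
    k: int = 60,
    protein_id: str = "",
    metal: str = "",
    column: str | None = None,
) -> SpectrumSummary:
    """Summarise a plain HSQC peak table (or one designated delay column).

    ``peak_count`` is the number of observed peaks before zero padding;
    ``max_normalized`` divides through the spectrum maximum (histogram
    convention for comparing spectra).
    """
    intensities = table.intensities(column)
    padded = select_top_k(intensities, k=k, peak_ids=None)
    s = inhomogeneity(padded)
    return SpectrumSummary(
        protein_id=protein_id,
        metal=metal,
        peak_count=int(intensities.size),
        intensities=intensities,
        s_value=s,
    )
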