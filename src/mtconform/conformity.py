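"""Conformity verdict and exchange-regime classification.

A metal-loaded metallothionein is called *conform* for that metal when the
complex adopts a unique, exchange-free structure.  Operationally: the mean
filtered T2 relaxation time is at or above a delimiter (default 140 ms) and
the peak-intensity inhomogeneity S is at or below a delimiter (default
0.55).  Both delimiters are approximate and configurable; the boundary is
inclusive.

The exchange regime is read from the HSQC peak count relative to the number
expected for a unique structure:

* far fewer peaks than expected — exchange in the intermediate (millisecond)
  regime broadens peaks beyond detection;
* far more peaks than expected — additional conformations exchanging much
  more slowly give duplicate (typically weak) peaks;
* otherwise the fold is conformationally stable;
* ``mixed`` — too few strong peaks while weak (duplicate) peaks are
  over-represented: intermediate and slow exchange coexist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from mtconform.inhomogeneity import SpectrumSummary
from mtconform.io_formats import RunConfig

REGIMES = ("stable", "intermediate_exchange", "slow_exchange", "mixed")


def classify_regime(
    peak_count: int, expected: int, tolerance_fraction: float = 0.15
) -> str:
    """Three-way regime call from the observed versus expected peak count."""
    if expected <= 0:
        raise ValueError("expected peak count must be > 0")
    if peak_count < expected * (1 - tolerance_fraction):
        return "intermediate_exchange"
    if peak_count > expected * (1 + tolerance_fraction):
        return "slow_exchange"
    return "stable"


def weak_peak_stats(intensities, weak_factor: float = 0.5) -> tuple[float, int]:
    """(weak fraction, strong-peak count) of a spectrum.

    A peak is weak when its intensity falls below ``weak_factor`` times the
    spectrum median.
    """
    values = np.asarray(intensities, dtype=float)
    if values.size == 0:
        return 0.0, 0
    threshold = weak_factor * float(np.median(values))
    weak = values < threshold
    return float(weak.mean()), int((~weak).sum())


def detect_mixed_exchange(
    intensities,
    weak_factor: float = 0.5,
    weak_quantile: float = 0.25,
) -> bool:
    """True when the spectrum carries an excess of weak peaks (a fraction
    above ``weak_quantile``), indicating coexisting slow exchange."""
    weak_fraction, _ = weak_peak_stats(intensities, weak_factor)
    return weak_fraction > weak_quantile


@dataclass
class ConformityReport:
    protein_id: str
    metal: str
    peak_count: int
    expected_peaks: int
    mean_t2_ms: float | None
    s_value: float
    conform: bool | None
    regime: str
    thresholds: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "protein_id": self.protein_id,
            "metal": self.metal,
            "peak_count": self.peak_count,
            "expected_peaks": self.expected_peaks,
            "mean_t2_ms": self.mean_t2_ms,
            "s_value": self.s_value,
            "conform": self.conform,
            "regime": self.regime,
            "thresholds": self.thresholds,
            "flags": list(self.flags),
        }


def assess_conformity(
    summary: SpectrumSummary,
    mean_t2_ms: float | None,
    config: RunConfig | None = None,
    expected_peaks: int | None = None,
    check_mixed: bool = True,
) -> ConformityReport:
    """Combine peak count, mean T2 and S into the conformity verdict.

    ``conform`` is True iff ``mean_t2_ms >= config.t2_delim_ms`` and
    ``s_value <= config.inhom_delim`` (inclusive boundaries).  A missing
    mean T2 yields ``conform=None`` with an explanatory flag.  The regime is
    the peak-count call, upgraded to ``mixed`` when the count is low but
    weak peaks are over-represented.
    """
    config = config or RunConfig()
    expected = expected_peaks if expected_peaks is not None else config.top_k
    regime = classify_regime(
        summary.peak_count, expected, config.peak_count_tolerance
    )
    if check_mixed and summary.intensities.size:
        # intermediate + slow exchange together: too few strong peaks while
        # weak (duplicate) peaks are over-represented.  Weak duplicates can
        # mask the missing peaks in the raw count, so judge the strong set.
        weak_fraction, strong_count = weak_peak_stats(summary.intensities)
        if (
            detect_mixed_exchange(summary.intensities)
            and strong_count < expected * (1 - config.peak_count_tolerance)
        ):
            regime = "mixed"
    flags: list[str] = []
    if mean_t2_ms is None or (isinstance(mean_t2_ms, float) and math.isnan(mean_t2_ms)):
        conform: bool | None = None
        mean_t2_ms = None
        flags.append("mean T2 unavailable: conformity undetermined")
    else:
        conform = bool(
            mean_t2_ms >= config.t2_delim_ms and summary.s_value <= config.inhom_delim
        )
    return ConformityReport(
        protein_id=summary.protein_id,
        metal=summary.metal,
        peak_count=summary.peak_count,
        expected_peaks=expected,
        mean_t2_ms=mean_t2_ms,
        s_value=summary.s_value,
        conform=conform,
        regime=regime,
        thresholds={
            "t2_delim_ms": config.t2_delim_ms,
            "inhom_delim": config.inhom_delim,
            "peak_count_tolerance": config.peak_count_tolerance,
            "top_k": config.top_k,
            "random_seed": config.random_seed,
        },
        flags=flags,
    )
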