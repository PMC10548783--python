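"""Exponential T2 fitting with a Monte-Carlo error model.

Each CPMG relaxation series is fitted to a two-parameter single-exponential
decay

    I(t) = I0 * exp(-t / T2)

where ``I0`` is the intensity extrapolated to a delay of 0 ms and ``T2`` the
transverse relaxation time (ms).  No baseline offset is fitted.

The error of T2 incorporates the uncertainty of the initial intensity via a
resampling procedure:

1. draw ``n_resamples`` initial intensities from ``Normal(I0, SE_I0)`` using
   the standard error of the original fit;
2. for each draw, refit the one-parameter model (I0 held fixed) to obtain a
   T2 value and its standard error;
3. resample each of these T2 values once from a Gaussian centred on it
   (by default with the refit's own standard error, configurable);
4. the standard deviation of the resampled T2 values is the reported error.

Fits whose Monte-Carlo error exceeds a cutoff (default 25 ms) are excluded
from downstream averages; the boundary is strict (only errors *larger than*
the cutoff are dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from mtconform.errors import FitFailureError, InsufficientDataError


@dataclass
class RelaxationSeries:
    """One peak's intensity-versus-delay curve (absent points already dropped)."""

    peak_id: str
    delays_ms: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.delays_ms = np.asarray(self.delays_ms, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.delays_ms.shape != self.intensities.shape:
            raise ValueError("delays and intensities must have equal length")
        if np.any(np.diff(self.delays_ms) <= 0):
            raise ValueError("delays must be strictly increasing")
        if not np.all(np.isfinite(self.delays_ms)):
            raise ValueError("delays must be finite")

    @property
    def n_points(self) -> int:
        return int(self.delays_ms.size)

    def scaled(self, factor: float) -> "RelaxationSeries":
        return RelaxationSeries(self.peak_id, self.delays_ms, self.intensities * factor)


@dataclass
class T2FitResult:
    peak_id: str
    t2_ms: float = np.nan
    i0: float = np.nan
    se_t2_ms: float = np.nan
    se_i0: float = np.nan
    mc_error_ms: float = np.nan
    converged: bool = False


def _decay(t: np.ndarray, i0: float, t2: float) -> np.ndarray:
    return i0 * np.exp(-t / t2)


def _loglinear_start(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Starting values from a log-linear regression of ln(I) on t."""
    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        i0 = float(np.exp(intercept))
        t2 = float(-1.0 / slope) if slope < 0 else float(t[-1])
        if t2 > 0 and np.isfinite(t2) and np.isfinite(i0):
            return i0, t2
    return float(np.max(np.abs(y)) or 1.0), float(t[-1] / 2)


def fit_exponential(series: RelaxationSeries) -> T2FitResult:
    """Nonlinear least-squares fit of ``I0 * exp(-t/T2)`` to one series.

    Raises :class:`InsufficientDataError` for fewer than three usable points.
    A failed optimisation or a non-positive fitted T2 yields
    ``converged=False`` with no estimates.
    """
    t, y = series.delays_ms, series.intensities
    if series.n_points < 3:
        raise InsufficientDataError(
            f"peak {series.peak_id!r}: {series.n_points} usable points, need >= 3"
        )
    if np.ptp(y) == 0:
        raise InsufficientDataError(
            f"peak {series.peak_id!r}: intensities are all equal, decay undefined"
        )
    i0_0, t2_0 = _loglinear_start(t, y)
    try:
        popt, pcov = curve_fit(_decay, t, y, p0=[i0_0, t2_0], maxfev=10000)
    except (RuntimeError, ValueError):
        return T2FitResult(peak_id=series.peak_id, converged=False)
    i0, t2 = popt
    se = np.sqrt(np.diag(pcov))
    if t2 <= 0 or not np.all(np.isfinite(popt)):
        return T2FitResult(peak_id=series.peak_id, converged=False)
    se_i0 = float(se[0]) if np.isfinite(se[0]) else np.nan
    se_t2 = float(se[1]) if np.isfinite(se[1]) else np.nan
    return T2FitResult(
        peak_id=series.peak_id,
        t2_ms=float(t2),
        i0=float(i0),
        se_t2_ms=se_t2,
        se_i0=se_i0,
        converged=True,
    )


def _refit_t2_fixed_i0(
    t: np.ndarray, y: np.ndarray, i0: float, t2_guess: float
) -> tuple[float, float]:
    """One-parameter refit of T2 with the initial intensity held fixed."""

    def model(tt, t2):
        return i0 * np.exp(-tt / t2)

    popt, pcov = curve_fit(model, t, y, p0=[t2_guess], maxfev=10000)
    t2 = float(popt[0])
    se = float(np.sqrt(pcov[0, 0]))
    if t2 <= 0 or not np.isfinite(t2) or not np.isfinite(se):
        raise FitFailureError("one-parameter refit did not converge")
    return t2, se


def monte_carlo_error(
    series: RelaxationSeries,
    fit: T2FitResult,
    n_resamples: int = 500,
    seed: int | np.random.Generator | None = None,
    se_source: str = "refit",
) -> float:
    """Monte-Carlo error (ms) of a converged T2 fit.

    ``se_source`` selects the standard error used for the final single
    resample of each refit T2: ``"refit"`` uses each one-parameter refit's
    own SE, ``"initial_fit"`` reuses the SE of the original two-parameter
    fit.  Refit failures are skipped; more than 50 % failures raises.
    """
    if not fit.converged:
        raise ValueError("monte_carlo_error requires a converged fit")
    if n_resamples < 2:
        raise ValueError("n_resamples must be >= 2")
    if se_source not in ("refit", "initial_fit"):
        raise ValueError(f"unknown se_source {se_source!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t, y = series.delays_ms, series.intensities
    se_i0 = fit.se_i0 if np.isfinite(fit.se_i0) else 0.0
    i0_draws = rng.normal(fit.i0, se_i0, size=n_resamples)
    resampled = []
    failures = 0
    for i0_i in i0_draws:
        try:
            t2_i, se_i = _refit_t2_fixed_i0(t, y, i0_i, fit.t2_ms)
        except (FitFailureError, RuntimeError, ValueError):
            failures += 1
            continue
        scale = se_i if se_source == "refit" else (
            fit.se_t2_ms if np.isfinite(fit.se_t2_ms) else 0.0
        )
        resampled.append(rng.normal(t2_i, scale))
    if failures > n_resamples / 2:
        raise FitFailureError(
            f"peak {series.peak_id!r}: {failures}/{n_resamples} Monte-Carlo refits failed"
        )
    return float(np.std(resampled, ddof=1))


@dataclass
class FilterResult:
    """Outcome of the error filter: retained fits plus exclusion reasons."""

    retained: list[T2FitResult]
    excluded: list[tuple[T2FitResult, str]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.retained)

    def __len__(self) -> int:
        return len(self.retained)


def filter_fits(fits: list[T2FitResult], cutoff_ms: float = 25.0) -> FilterResult:
    """Retain converged fits whose Monte-Carlo error is not larger than the
    cutoff (strict exclusion: only error > cutoff is dropped); order kept."""
    if cutoff_ms <= 0:
        raise ValueError("cutoff_ms must be > 0")
    retained: list[T2FitResult] = []
    excluded: list[tuple[T2FitResult, str]] = []
    for fit in fits:
        if not fit.converged:
            excluded.append((fit, "fit did not converge"))
        elif np.isnan(fit.mc_error_ms):
            excluded.append((fit, "no Monte-Carlo error computed"))
        elif fit.mc_error_ms > cutoff_ms:
            excluded.append(
                (fit, f"Monte-Carlo error {fit.mc_error_ms:.1f} ms > {cutoff_ms:g} ms")
            )
        else:
            retained.append(fit)
    return FilterResult(retained=retained, excluded=excluded)


def mean_t2(fits) -> float:
    """Arithmetic mean T2 (ms) over retained fits; empty input raises."""
    values = [f.t2_ms for f in fits]
    if not values:
        raise InsufficientDataError("mean_t2 of an empty set of fits")
    return float(np.mean(values))


def fit_peak_table(
    table,
    n_resamples: int = 500,
    seed: int | None = None,
    se_source: str = "refit",
    min_points: int = 3,
):
    """Fit every peak of a relaxation :class:`~mtconform.io_formats.PeakTable`.

    Returns a list of :class:`T2FitResult` with Monte-Carlo errors filled in.
    Peaks with fewer than ``min_points`` usable delays are returned as
    non-converged results rather than raising.
    """
    rng = np.random.default_rng(seed)
    results = []
    for series in table.iter_series():
        if series.n_points < min_points:
            results.append(T2FitResult(peak_id=series.peak_id, converged=False))
            continue
        fit = fit_exponential(series)
        if fit.converged:
            try:
                fit.mc_error_ms = monte_carlo_error(
                    series, fit, n_resamples=n_resamples, seed=rng, se_source=se_source
                )
            except FitFailureError:
                fit.converged = False
        results.append(fit)
    return results
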