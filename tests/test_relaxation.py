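import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mtconform.errors import InsufficientDataError
from mtconform.relaxation import (
    RelaxationSeries,
    T2FitResult,
    filter_fits,
    fit_exponential,
    mean_t2,
    monte_carlo_error,
)
from tests.conftest import make_noisy_series


class TestFitExponential:
    def test_exact_recovery_on_noiseless_decay(self, noiseless_series):
        fit = fit_exponential(noiseless_series)
        assert fit.converged
        assert fit.t2_ms == pytest.approx(120.0, rel=1e-6)
        assert fit.i0 == pytest.approx(100.0, rel=1e-6)

    def test_two_points_insufficient(self):
        series = RelaxationSeries("p", [20.0, 50.0], [10.0, 5.0])
        with pytest.raises(InsufficientDataError):
            fit_exponential(series)

    def test_constant_intensities_rejected(self, delays):
        with pytest.raises(InsufficientDataError):
            fit_exponential(RelaxationSeries("p", delays, np.full(delays.size, 3.0)))

    def test_mean_recovery_over_noisy_replicates(self, delays):
        """Mean fitted T2 over 200 replicate noisy series (sigma = 2% of I0)
        stays within 2% of the generating 80 ms."""
        rng = np.random.default_rng(42)
        fits = [
            fit_exponential(make_noisy_series(delays, rng=rng)).t2_ms
            for _ in range(200)
        ]
        assert np.mean(fits) == pytest.approx(80.0, rel=0.02)

    @given(factor=st.floats(0.01, 1e4))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, factor):
        delays = np.asarray([20.0, 50.0, 75.0, 100.0, 125.0, 150.0, 200.0, 250.0, 300.0])
        base = RelaxationSeries("p", delays, 100.0 * np.exp(-delays / 90.0))
        ref = fit_exponential(base)
        scaled = fit_exponential(base.scaled(factor))
        assert scaled.t2_ms == pytest.approx(ref.t2_ms, rel=1e-6)
        assert scaled.i0 == pytest.approx(ref.i0 * factor, rel=1e-6)

    def test_delay_unit_consistency(self, noiseless_series):
        """Fitting in seconds instead of ms scales T2 by exactly 1/1000."""
        in_seconds = RelaxationSeries(
            "p", noiseless_series.delays_ms / 1000.0, noiseless_series.intensities
        )
        assert fit_exponential(in_seconds).t2_ms == pytest.approx(0.120, rel=1e-9)


class TestMonteCarloError:
    def test_zero_for_noiseless_input(self, noiseless_series):
        fit = fit_exponential(noiseless_series)
        err = monte_carlo_error(noiseless_series, fit, n_resamples=100, seed=1)
        assert err <= 1e-9

    def test_seeded_determinism(self, delays):
        series = make_noisy_series(delays)
        fit = fit_exponential(series)
        a = monte_carlo_error(series, fit, n_resamples=200, seed=7)
        b = monte_carlo_error(series, fit, n_resamples=200, seed=7)
        assert a == b

    def test_tracks_empirical_sd_within_factor_two(self, delays):
        """The reported error of one noisy series is within a factor of two
        of the spread of fitted T2 over independently re-simulated series."""
        rng = np.random.default_rng(3)
        series = make_noisy_series(delays, rng=rng)
        fit = fit_exponential(series)
        reported = monte_carlo_error(series, fit, n_resamples=500, seed=11)
        empirical = np.std(
            [
                fit_exponential(make_noisy_series(delays, rng=rng)).t2_ms
                for _ in range(500)
            ],
            ddof=1,
        )
        assert empirical / 2 <= reported <= empirical * 2

    @pytest.mark.parametrize("sigmas", [(0.01, 0.05)])
    def test_nondecreasing_in_noise_level(self, delays, sigmas):
        """On average over seeds the error grows with the injected noise."""
        lo, hi = sigmas
        means = []
        for sigma in (lo, hi):
            errs = []
            for seed in range(5):
                rng = np.random.default_rng(100 + seed)
                series = make_noisy_series(delays, sigma_fraction=sigma, rng=rng)
                fit = fit_exponential(series)
                errs.append(monte_carlo_error(series, fit, 200, seed=seed))
            means.append(np.mean(errs))
        assert means[0] < means[1]


class TestFilterAndMean:
    def test_strict_larger_than_boundary(self):
        fits = [
            T2FitResult("a", t2_ms=100, converged=True, mc_error_ms=10.0),
            T2FitResult("b", t2_ms=110, converged=True, mc_error_ms=25.0),
            T2FitResult("c", t2_ms=120, converged=True, mc_error_ms=25.01),
            T2FitResult("d", t2_ms=130, converged=True, mc_error_ms=40.0),
        ]
        result = filter_fits(fits, cutoff_ms=25.0)
        assert [f.peak_id for f in result.retained] == ["a", "b"]
        assert len(result.excluded) == 2
        assert all("25" in reason for _, reason in result.excluded)

    def test_empty_input_empty_output(self):
        assert filter_fits([], 25.0).retained == []

    def test_all_good_is_identity(self):
        fits = [
            T2FitResult(str(i), t2_ms=100 + i, converged=True, mc_error_ms=5.0)
            for i in range(4)
        ]
        assert filter_fits(fits, 25.0).retained == fits

    def test_mean_t2_values(self):
        fits = [
            T2FitResult(str(t), t2_ms=t, converged=True, mc_error_ms=1.0)
            for t in (100.0, 140.0, 180.0)
        ]
        assert mean_t2(fits) == pytest.approx(140.0)
        assert mean_t2(fits[:1]) == pytest.approx(100.0)
        with pytest.raises(InsufficientDataError):
            mean_t2([])

    def test_mean_t2_recovers_simulated_population(self, delays):
        """60 low-noise peaks with T2 ~ U(100, 200): the mean of the fits
        lands within 5 ms of the true mean."""
        rng = np.random.default_rng(8)
        true = rng.uniform(100, 200, size=60)
        fits = []
        for i, t2 in enumerate(true):
            y = 100 * np.exp(-delays / t2) + rng.normal(0, 0.5, delays.size)
            fits.append(fit_exponential(RelaxationSeries(f"p{i}", delays, y)))
        assert mean_t2(fits) == pytest.approx(true.mean(), abs=5.0)
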