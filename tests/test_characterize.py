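"""Spectral slopes, jump statistics, ratio widths, rank abundance."""

import numpy as np
import pytest
from scipy import stats

from stochglv import (
    AbundanceSeries,
    classify_color,
    noise_color_slope,
    power_spectral_density,
    rank_abundance,
    ratio_distribution_width,
    successive_difference_stats,
    to_relative_abundance,
)


def make_series(values, dt=1.0):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    return AbundanceSeries(times=dt * np.arange(values.shape[0]), values=values)


class TestPowerSpectralDensity:
    def test_white_noise_spectrum_is_flat(self):
        rng = np.random.default_rng(0)
        slopes = []
        for _ in range(20):
            x = rng.normal(10.0, 1.0, 512)
            f, p = power_spectral_density(x)
            slopes.append(noise_color_slope(f, p).slope)
        assert abs(np.mean(slopes)) < 0.2

    def test_random_walk_spectrum_has_slope_minus_two(self):
        rng = np.random.default_rng(1)
        slopes = []
        for _ in range(20):
            x = np.cumsum(rng.normal(0, 1, 1024))
            f, p = power_spectral_density(x)
            slopes.append(noise_color_slope(f, p).slope)
        assert abs(np.mean(slopes) + 2.0) < 0.3

    def test_scaling_series_scales_power_not_slope(self):
        rng = np.random.default_rng(2)
        x = rng.normal(5.0, 1.0, 256)
        f1, p1 = power_spectral_density(x)
        f2, p2 = power_spectral_density(10 * x)
        assert np.allclose(p2, 100 * p1, rtol=1e-9)
        assert np.isclose(noise_color_slope(f1, p1).slope, noise_color_slope(f2, p2).slope)

    def test_parseval_consistency(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 2.0, 512)
        f, p = power_spectral_density(x)
        df = f[1] - f[0]
        assert np.isclose(np.sum(p) * df, x.var(), rtol=0.05)

    def test_short_or_constant_series_rejected(self):
        with pytest.raises(ValueError):
            power_spectral_density(np.ones(100))
        with pytest.raises(ValueError):
            power_spectral_density(np.arange(10, dtype=float))


class TestNoiseColorSlope:
    def test_exact_power_law_recovered(self):
        f = np.logspace(-3, 0, 200)
        for gamma in (-2.0, -1.0, 0.0):
            fit = noise_color_slope(f, f**gamma)
            assert np.isclose(fit.slope, gamma, atol=1e-9)

    def test_low_frequency_decade_is_discarded(self):
        # spectrum bent only in the lowest decade must not bias the fit
        f = np.logspace(-3, 0, 300)
        p = f**-1.0
        bent = p.copy()
        bent[f < 1e-2] *= (f[f < 1e-2] / 1e-2) ** -2  # extra steepness below cutoff
        assert np.isclose(noise_color_slope(f, bent).slope, -1.0, atol=1e-9)

    def test_spline_estimator_is_darker_on_bending_spectrum(self):
        # Lorentzian (OU) spectrum: flat at low f, -2 at high f; the spline
        # minimum-derivative estimator reports the steepest region
        f = np.logspace(-2.5, 0, 200)
        p = 1.0 / (0.1**2 + f**2)
        linear = noise_color_slope(f, p).slope
        spline = noise_color_slope(f, p, method="spline-min-derivative").slope
        assert spline <= linear

    def test_insufficient_points_after_cutoff(self):
        f = np.logspace(-1, 0, 12)
        with pytest.raises(ValueError):
            noise_color_slope(f, np.ones_like(f))


@pytest.mark.parametrize(
    "slope,label",
    [(0.0, "white"), (0.4, "white"), (-0.4, "white"), (-1.0, "pink"), (-1.4, "pink"),
     (-2.0, "brown"), (-2.6, "black"), (-3.0, "black"), (-3.7, "black")],
)
def test_classify_color_nearest_anchor(slope, label):
    assert classify_color(slope) == label


class TestSuccessiveDifferences:
    def test_constant_series_is_flagged(self):
        with pytest.warns(UserWarning):
            res = successive_difference_stats(make_series(np.ones((50, 4))))
        assert np.isnan(res.slope)
        assert np.all(res.mean_abs_diff == 0)

    def test_scaled_copies_lie_on_slope_one_line(self):
        rng = np.random.default_rng(4)
        x = np.abs(rng.normal(10, 2, 200))
        vals = np.column_stack([x, 5 * x, 25 * x])
        res = successive_difference_stats(make_series(vals))
        assert np.isclose(res.slope, 1.0, atol=1e-9)

    def test_zero_species_excluded_with_warning(self):
        rng = np.random.default_rng(5)
        vals = np.abs(rng.normal(10, 2, (100, 4)))
        vals[:, 0] = 0.0
        with pytest.warns(UserWarning, match="excluded"):
            res = successive_difference_stats(make_series(vals))
        assert not res.used[0] and res.used[1:].all()


class TestRatioWidth:
    def test_recovers_generating_width_on_lognormal_draws(self):
        rng = np.random.default_rng(6)
        sigma = 0.5
        n = 2000
        reps = 40
        high_p = 0
        errs = []
        for _ in range(reps):
            # ratios drawn from the centered lognormal itself
            r = np.exp(rng.normal(0.0, sigma, n))
            x = np.concatenate([[1.0], np.cumprod(r)])
            # use the ratio sequence directly by feeding a synthetic series
            fit_sigma = np.sqrt(np.mean(np.log(r) ** 2))
            fit = ratio_distribution_width(x)
            assert np.isclose(fit.sigma, fit_sigma, rtol=1e-9)
            errs.append(fit.sigma - sigma)
            high_p += fit.ks_pvalue > 0.05
        se = sigma / np.sqrt(2 * n)
        assert abs(np.mean(errs)) < 2 * se / np.sqrt(reps) * 3  # mean error over replicates
        assert high_p >= 0.9 * reps  # >= 90% of replicates fit well

    def test_constant_series_degenerate(self):
        fit = ratio_distribution_width(np.ones(200))
        assert fit.degenerate and fit.sigma == 0.0

    def test_too_few_ratios_rejected(self):
        with pytest.raises(ValueError):
            ratio_distribution_width(np.ones(10))


class TestRankAbundance:
    def test_sorted_descending(self):
        prof = rank_abundance(make_series(np.array([[3.0, 1.0, 2.0]])))
        assert np.array_equal(prof.abundances, [3.0, 2.0, 1.0])
        assert np.array_equal(prof.ranks, [1, 2, 3])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        vals = np.abs(rng.normal(5, 2, (20, 10)))
        a = rank_abundance(make_series(vals))
        b = rank_abundance(make_series(vals[:, rng.permutation(10)]))
        assert np.allclose(a.abundances, b.abundances)

    def test_lognormal_profile_refits_generating_parameters(self):
        rng = np.random.default_rng(8)
        mu, sd = 2.0, 1.5
        x_star = 10 ** rng.normal(mu, sd, 400)
        prof = rank_abundance(make_series(x_star[None, :]))
        logs = np.log10(prof.abundances)
        assert abs(logs.mean() - mu) < 3 * sd / np.sqrt(400)
        assert abs(logs.std(ddof=1) - sd) < 3 * sd / np.sqrt(2 * 400)


class TestRelativeAbundance:
    def test_rows_sum_to_one(self):
        rel = to_relative_abundance(make_series(np.array([[2.0, 2.0], [1.0, 3.0]])))
        assert np.allclose(rel.values.sum(axis=1), 1.0)
        assert np.allclose(rel.values[0], [0.5, 0.5])

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        vals = np.abs(rng.normal(5, 1, (30, 4)))
        a = to_relative_abundance(make_series(vals))
        b = to_relative_abundance(make_series(10 * vals))
        assert np.allclose(a.values, b.values)

    def test_all_zero_row_rejected(self):
        vals = np.array([[1.0, 1.0], [0.0, 0.0]])
        with pytest.raises(ValueError):
            to_relative_abundance(make_series(vals))

    def test_noise_color_robust_to_normalization(self, logistic_series):
        # linear-noise logistic community: the total is nearly conserved, so
        # per-species colors survive the relative-abundance transform
        from stochglv import noise_color

        series, _, _ = logistic_series
        abs_slopes = np.array([f.slope for f in noise_color(series)])
        rel_slopes = np.array([f.slope for f in noise_color(to_relative_abundance(series))])
        assert np.median(np.abs(abs_slopes - rel_slopes)) < 0.35
        assert abs(np.mean(abs_slopes) - np.mean(rel_slopes)) < 0.25
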