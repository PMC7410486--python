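"""Synthetic communities and parameter-scan experiments.

A :class:`CommunityBlueprint` bundles everything needed to draw a random
community and simulate it: the steady-state (rank abundance) generator,
the self-interaction generator, interaction strength, noise channels and
sampling plan.  The default "stool-like" blueprint emulates a dense gut
community observed by daily sequencing: a heavy-tailed lognormal
abundance profile spanning several orders of magnitude, growth rates in
the band that produces white-to-pink noise at daily sampling, and large
linear (environmental) noise.

On top of the blueprint sit the experiment drivers:

* :func:`calibrate_color_curve` — the monotone map from
  ``log10(self-interaction x mean abundance x sampling interval)`` (the
  growth rate, for logistic communities) to the noise-color slope;
* :func:`infer_self_interactions` — inversion of that map, estimating
  per-species self-interactions from observed noise colors and mean
  abundances;
* :func:`run_noise_mix_scan` — difference-scaling slopes and ratio widths
  across a grid of linear / square-root noise strengths;
* :func:`run_community_reproduction` — the end-to-end experiment: many
  replicate stool-like logistic communities, their full characteristics
  bundle, and the fraction classified as niche by the neutral covariance
  test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .characterize import (
    noise_color,
    rank_abundance,
    ratio_distribution_width,
    successive_difference_stats,
)
from .model import GLVParameters, InteractionSamplerConfig, SteadyState, impose_growth_rates, is_linearly_stable, sample_interaction_matrix
from .neutrality import kl_neutrality, neutral_covariance_test
from .simulate import AbundanceSeries, NoiseSpec, SimulationConfig, simulate

__all__ = [
    "CommunityBlueprint",
    "ColorCalibration",
    "child_rng",
    "generate_community",
    "simulate_blueprint",
    "calibrate_color_curve",
    "difference_scaling_experiment",
    "infer_self_interactions",
    "run_noise_mix_scan",
    "CHANNEL_REFERENCE_SIGMA",
    "run_community_reproduction",
]


#: reference strengths of the three noise channels for the stool-like
#: community: sigma_lin gives ratio widths of order one at the median growth
#: rate; sigma_sqrt is sqrt(division rate + death rate) for turnover of about
#: 12 events per individual per day; sigma_add is immigration noise of order
#: one individual per day
CHANNEL_REFERENCE_SIGMA = {"linear": 1.4, "sqrt": 3.5, "additive": 1.0}


def child_rng(seed: int | None, *key: int) -> np.random.Generator:
    """Deterministic child generator ``seed -> (k0, k1, ...)``.

    Each replicate / grid point draws from its own spawn key, so any
    single replicate can be reproduced in isolation.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


@dataclass
class CommunityBlueprint:
    """Recipe for random communities and their simulation.

    Defaults describe the stool-like reference community: 100 species,
    lognormal steady states with log10 standard deviation 1.5 around a
    median of 100 (sequencing-count scale, so the rare tail sits at the
    single-individual level), per-species growth rates log-uniform in
    [0.5, 5]/day (the white-to-pink noise band at daily sampling),
    self-interactions derived as ``omega_ii = -g_i / x*_i`` and therefore
    spanning many orders of magnitude, no interspecies interactions, and
    large linear noise (``sigma_lin = 1.4`` gives successive-ratio widths
    of order one).
    """

    n_species: int = 100
    abundance_profile: str = "lognormal"  # "lognormal" | "equal"
    log10_abundance_median: float = 2.0
    log10_abundance_sd: float = 1.5
    self_interaction_mode: str = "growth-band"  # "growth-band" | "log-uniform" | "constant"
    growth_band: tuple[float, float] = (0.5, 5.0)  # 1/time, log-uniform
    self_interaction_range: tuple[float, float] = (1e-4, 1e-1)  # magnitudes, log-uniform
    self_interaction_value: float = 1.0
    interaction_strength: float = 0.0  # alpha, std of off-diagonal omega
    sigma_lin: float | np.ndarray = 1.4
    sigma_sqrt: float | np.ndarray = 0.0
    sigma_add: float | np.ndarray = 0.0
    sampling_interval: float = 1.0
    n_samples: int = 1000
    dt: float | None = None
    seed: int | None = None
    max_retries: int = 20

    def noise_spec(self) -> NoiseSpec:
        return NoiseSpec(sigma_lin=self.sigma_lin, sigma_sqrt=self.sigma_sqrt,
                         sigma_add=self.sigma_add)

    def simulation_config(self, seed: int | None = None) -> SimulationConfig:
        return SimulationConfig(
            total_time=self.n_samples * self.sampling_interval,
            sampling_interval=self.sampling_interval,
            dt=self.dt,
            seed=self.seed if seed is None else seed,
        )


def _draw_steady_state(bp: CommunityBlueprint, rng: np.random.Generator) -> np.ndarray:
    S = bp.n_species
    if bp.abundance_profile == "lognormal":
        return 10.0 ** rng.normal(bp.log10_abundance_median, bp.log10_abundance_sd, S)
    if bp.abundance_profile == "equal":
        return np.full(S, 10.0 ** bp.log10_abundance_median)
    raise ValueError(f"unknown abundance profile {bp.abundance_profile!r}")


def _draw_self_interactions(bp: CommunityBlueprint, x_star: np.ndarray,
                            rng: np.random.Generator) -> np.ndarray:
    S = bp.n_species
    if bp.self_interaction_mode == "growth-band":
        lo, hi = bp.growth_band
        g = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), S)
        return -g / x_star
    if bp.self_interaction_mode == "log-uniform":
        lo, hi = bp.self_interaction_range
        return -(10.0 ** rng.uniform(np.log10(lo), np.log10(hi), S))
    if bp.self_interaction_mode == "constant":
        return np.full(S, -abs(bp.self_interaction_value))
    raise ValueError(f"unknown self-interaction mode {bp.self_interaction_mode!r}")


def generate_community(
    bp: CommunityBlueprint, rng: np.random.Generator | None = None
) -> tuple[GLVParameters, SteadyState, NoiseSpec]:
    """Draw one community from a blueprint.

    The steady state is drawn first, self-interactions second, random
    off-diagonal interactions third, and the growth rates are imposed so
    the drawn abundance vector is an exact fixed point.  Draws whose fixed
    point is linearly unstable are rejected and resampled (capped retry).
    """
    if rng is None:
        rng = child_rng(bp.seed, 0)
    last_err = None
    for _ in range(bp.max_retries):
        x_star = _draw_steady_state(bp, rng)
        self_int = _draw_self_interactions(bp, x_star, rng)
        cfg = InteractionSamplerConfig(offdiag_std=bp.interaction_strength,
                                       self_interactions=self_int)
        omega = sample_interaction_matrix(cfg, bp.n_species, rng=rng)
        g = impose_growth_rates(omega, x_star)
        params = GLVParameters(growth=g, interactions=omega)
        stable, _ = is_linearly_stable(params, x_star)
        if stable:
            return params, SteadyState(abundances=x_star, provenance="imposed"), bp.noise_spec()
        last_err = "linearly unstable fixed point"
    raise RuntimeError(
        f"no feasible stable community after {bp.max_retries} draws ({last_err}); "
        "reduce the interaction strength"
    )


def simulate_blueprint(
    bp: CommunityBlueprint, replicate: int = 0
) -> tuple[AbundanceSeries, GLVParameters, SteadyState]:
    """Draw and simulate replicate ``replicate`` of a blueprint."""
    params, ss, noise = generate_community(bp, rng=child_rng(bp.seed, 0, replicate))
    series = simulate(params, noise, bp.simulation_config(),
                      x_star=ss.abundances, rng=child_rng(bp.seed, 1, replicate))
    return series, params, ss


@dataclass
class ColorCalibration:
    """Monotone map between log10(g * delta_t) and the noise-color slope.

    ``log10_products`` are grid values of the product of self-interaction
    magnitude, mean abundance and sampling interval (for a logistic
    species this is the dimensionless growth rate ``g * delta_t``);
    ``mean_slope``/``slope_sd`` are replicate statistics of the fitted PSD
    slope at each grid point, and ``fitted_slope`` is the isotonic
    (monotone non-decreasing) fit used for inversion.
    """

    log10_products: np.ndarray
    mean_slope: np.ndarray
    slope_sd: np.ndarray
    fitted_slope: np.ndarray
    sampling_interval: float
    interaction_strength: float = 0.0
    metadata: dict = field(default_factory=dict)

    def slope_at(self, log10_product: np.ndarray | float) -> np.ndarray:
        return np.interp(log10_product, self.log10_products, self.fitted_slope)

    @property
    def invertible_range(self) -> tuple[float, float]:
        return float(self.fitted_slope.min()), float(self.fitted_slope.max())

    def invert(self, slope: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
        """Map observed slopes back to ``log10(g * delta_t)``.

        Returns ``(log10_product, uncertainty)``; slopes outside the
        calibrated slope range give NaN.  The uncertainty is the grid
        dispersion divided by the local steepness of the curve, so flat
        regions of the calibration (very white or very brown colors)
        report larger uncertainties.
        """
        slope = np.atleast_1d(np.asarray(slope, dtype=float))
        lo, hi = self.invertible_range
        # strictly increasing version for interpolation
        ys = np.maximum.accumulate(self.fitted_slope + 1e-9 * np.arange(self.fitted_slope.size))
        est = np.interp(slope, ys, self.log10_products)
        deriv = np.gradient(self.fitted_slope, self.log10_products)
        local_deriv = np.interp(est, self.log10_products, deriv)
        local_sd = np.interp(est, self.log10_products, self.slope_sd)
        with np.errstate(divide="ignore"):
            unc = local_sd / np.abs(local_deriv)
        out_of_range = (slope < lo) | (slope > hi)
        est[out_of_range] = np.nan
        unc[out_of_range] = np.nan
        return est, unc


def calibrate_color_curve(
    grid: np.ndarray | None = None,
    replicates: int = 5,
    n_samples: int = 1000,
    sampling_interval: float = 1.0,
    sigma_lin: float = 0.2,
    seed: int | None = None,
    cutoff_decades: float = 1.0,
) -> ColorCalibration:
    """Measure the noise color of noninteracting species across growth rates.

    Each grid point ``log10(g * delta_t)`` is realized as an independent
    logistic species with unit carrying capacity; all grid points and
    replicates are integrated together as one noninteracting community
    (they are statistically independent).  The raw replicate means are
    smoothed by an isotonic regression, since the underlying
    Ornstein-Uhlenbeck spectrum guarantees a monotone curve (white at
    fast relaxation, brown at slow relaxation).
    """
    if grid is None:
        grid = np.linspace(-1.6, 1.6, 17)
    grid = np.asarray(grid, dtype=float)
    g_values = np.repeat(10.0 ** grid / sampling_interval, replicates)
    S = g_values.size
    params = GLVParameters(growth=g_values, interactions=np.diag(-g_values))
    x_star = np.ones(S)
    cfg = SimulationConfig(total_time=n_samples * sampling_interval,
                           sampling_interval=sampling_interval, seed=seed)
    series = simulate(params, NoiseSpec(sigma_lin=sigma_lin), cfg,
                      x_star=x_star, rng=child_rng(seed, 2))
    slopes = np.array([fit.slope for fit in noise_color(series, cutoff_decades=cutoff_decades)])
    slopes = slopes.reshape(grid.size, replicates)
    mean_slope = slopes.mean(axis=1)
    slope_sd = slopes.std(axis=1, ddof=1) if replicates > 1 else np.full(grid.size, np.nan)
    iso = IsotonicRegression(increasing=True)
    fitted = iso.fit_transform(grid, mean_slope)
    return ColorCalibration(
        log10_products=grid, mean_slope=mean_slope, slope_sd=slope_sd,
        fitted_slope=fitted, sampling_interval=sampling_interval,
        metadata={"replicates": replicates, "n_samples": n_samples,
                  "sigma_lin": sigma_lin, "seed": seed},
    )


def infer_self_interactions(
    slopes: np.ndarray,
    mean_abundances: np.ndarray,
    calibration: ColorCalibration,
) -> pd.DataFrame:
    """Estimate self-interaction magnitudes from noise colors.

    Inverts the calibration curve: a species with PSD slope ``c`` and mean
    abundance ``<x>`` has ``|omega_ii| = 10^inv(c) / (delta_t * <x>)``.
    Returns a data frame with log10 estimates, uncertainties and an
    ``in_range`` flag; out-of-range colors yield withheld (NaN) estimates.
    """
    slopes = np.asarray(slopes, dtype=float)
    mean_abundances = np.asarray(mean_abundances, dtype=float)
    log10_prod, unc = calibration.invert(slopes)
    log10_omega = log10_prod - np.log10(calibration.sampling_interval) - np.log10(mean_abundances)
    return pd.DataFrame({
        "slope": slopes,
        "mean_abundance": mean_abundances,
        "log10_self_interaction": log10_omega,
        "log10_uncertainty": unc,
        "in_range": np.isfinite(log10_prod),
    })


def difference_scaling_experiment(
    channel: str,
    n_species: int = 50,
    n_samples: int = 1000,
    replicates: int = 5,
    seed: int | None = None,
    blueprint: CommunityBlueprint | None = None,
) -> np.ndarray:
    """Cross-species difference-scaling slopes for one pure noise channel.

    Each replicate draws a fresh noninteracting stool-like community,
    simulates it under a single noise channel at the blueprint's default
    strength, and regresses log10 of the mean absolute successive
    difference on log10 of the mean abundance across species.  Returns the
    per-replicate slopes: about 1 for linear noise, about 2/3 for
    square-root (demographic) noise, and about 0 for additive noise.
    """
    base = blueprint if blueprint is not None else CommunityBlueprint()
    if channel not in CHANNEL_REFERENCE_SIGMA:
        raise ValueError(f"unknown channel {channel!r}")
    sigmas = {"sigma_lin": 0.0, "sigma_sqrt": 0.0, "sigma_add": 0.0}
    sigmas[{"linear": "sigma_lin", "sqrt": "sigma_sqrt", "additive": "sigma_add"}[channel]] = (
        CHANNEL_REFERENCE_SIGMA[channel]
    )
    bp = replace(base, n_species=n_species, n_samples=n_samples,
                 interaction_strength=0.0, seed=seed, **sigmas)
    slopes = np.empty(replicates)
    for rep in range(replicates):
        series, _, _ = simulate_blueprint(bp, replicate=rep)
        slopes[rep] = successive_difference_stats(series).slope
    return slopes


def run_noise_mix_scan(
    sigma_lin_grid: np.ndarray | None = None,
    sigma_sqrt_grid: np.ndarray | None = None,
    blueprint: CommunityBlueprint | None = None,
    replicates: int = 3,
    seed: int | None = None,
) -> pd.DataFrame:
    """Difference-scaling slope and ratio width across a noise-mix grid.

    For every combination of linear and square-root noise strength,
    simulate replicate noninteracting stool-like communities and record
    the cross-species difference-scaling slope, the median ratio width and
    the median Kolmogorov-Smirnov p-value.  Pure linear noise gives slope
    1, pure square-root noise about 2/3, mixtures interpolate.
    """
    if blueprint is None:
        blueprint = CommunityBlueprint(seed=seed)
    if sigma_lin_grid is None:
        sigma_lin_grid = np.array([0.0, 0.35, 0.7, 1.05, 1.4])
    if sigma_sqrt_grid is None:
        sigma_sqrt_grid = np.array([0.0, 0.875, 1.75, 2.625, 3.5])
    rows = []
    for i, slin in enumerate(np.asarray(sigma_lin_grid, dtype=float)):
        for j, ssqrt in enumerate(np.asarray(sigma_sqrt_grid, dtype=float)):
            if slin == 0 and ssqrt == 0:
                continue
            bp = replace(blueprint, sigma_lin=slin, sigma_sqrt=ssqrt, sigma_add=0.0,
                         seed=seed if seed is not None else blueprint.seed)
            for rep in range(replicates):
                series, _, _ = simulate_blueprint(bp, replicate=(i * 1000 + j * 10 + rep))
                diff = successive_difference_stats(series)
                widths, ps = [], []
                for k in range(series.n_species):
                    try:
                        fit = ratio_distribution_width(series.values[:, k])
                    except ValueError:
                        continue
                    if not fit.degenerate:
                        widths.append(fit.sigma)
                        ps.append(fit.ks_pvalue)
                rows.append({
                    "sigma_lin": slin, "sigma_sqrt": ssqrt, "replicate": rep,
                    "diff_slope": diff.slope,
                    "median_width": float(np.median(widths)) if widths else np.nan,
                    "median_ks_p": float(np.median(ps)) if ps else np.nan,
                })
    return pd.DataFrame(rows)


def run_community_reproduction(
    blueprint: CommunityBlueprint | None = None,
    replicates: int = 100,
    n_null: int = 100,
    seed: int | None = None,
    nct_alpha: float = 0.05,
) -> dict:
    """End-to-end reproduction experiment with the stool-like blueprint.

    For each replicate community: simulate, compute the rank abundance
    profile, per-species noise colors, the difference-scaling slope,
    ratio widths, the KL distance to neutrality and the neutral
    covariance test p-value.  Returns the per-replicate table, the first
    replicate's series (for plotting/inspection) and the niche fraction
    (share of replicates with NCT p below ``nct_alpha``).
    """
    if blueprint is None:
        blueprint = CommunityBlueprint(seed=seed)
    if seed is not None:
        blueprint = replace(blueprint, seed=seed)
    rows = []
    first_series = None
    first_profile = None
    for rep in range(replicates):
        series, params, ss = simulate_blueprint(blueprint, replicate=rep)
        if first_series is None:
            first_series = series
            first_profile = rank_abundance(series)
        diff = successive_difference_stats(series)
        colors = noise_color(series)
        widths = []
        for k in range(series.n_species):
            try:
                fit = ratio_distribution_width(series.values[:, k])
            except ValueError:
                continue
            if not fit.degenerate:
                widths.append(fit.sigma)
        kl = kl_neutrality(series)
        p_nct = neutral_covariance_test(series, n_null=n_null,
                                        rng=child_rng(blueprint.seed, 3, rep))
        rows.append({
            "replicate": rep,
            "diff_slope": diff.slope,
            "median_color_slope": float(np.median([c.slope for c in colors])),
            "median_width": float(np.median(widths)) if widths else np.nan,
            "kl_divergence": kl,
            "nct_p": p_nct,
            "niche": p_nct < nct_alpha,
        })
    table = pd.DataFrame(rows)
    return {
        "table": table,
        "niche_fraction": float(table["niche"].mean()),
        "first_series": first_series,
        "rank_profile": first_profile,
    }
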