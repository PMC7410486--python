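"""Descriptive statistics of abundance time series.

The statistics collected here summarize the stochastic structure of a
community time series:

* **noise color** — the slope of the power spectral density on log-log
  axes (white 0, pink -1, brown -2, black -3); darker noise means more
  temporal structure.
* **successive differences** — the scaling of the mean absolute jump
  ``<|x(t+dt) - x(t)|>`` with the mean abundance across species; its
  log-log slope fingerprints the noise type (1 linear, ~2/3 demographic,
  0 additive).
* **ratio widths** — the width of the lognormal fitted (mean fixed at
  one) to successive-abundance ratios ``x(t+dt)/x(t)``; an
  abundance-free measure of fluctuation size.
* **rank abundance** — time-averaged abundances by rank, heavy-tailed in
  real communities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .simulate import AbundanceSeries

__all__ = [
    "PSDFit",
    "SuccessiveDiffStats",
    "RatioFit",
    "RankAbundanceProfile",
    "power_spectral_density",
    "noise_color_slope",
    "classify_color",
    "noise_color",
    "successive_difference_stats",
    "ratio_distribution_width",
    "rank_abundance",
    "to_relative_abundance",
]

COLOR_ANCHORS = {"white": 0.0, "pink": -1.0, "brown": -2.0, "black": -3.0}


@dataclass
class PSDFit:
    """Periodogram of one species with its fitted log-log slope."""

    frequencies: np.ndarray
    power: np.ndarray
    slope: float
    method: str  # "linear-cutoff" | "spline-min-derivative"
    cutoff_frequency: float
    color: str = ""

    def __post_init__(self) -> None:
        if not self.color:
            self.color = classify_color(self.slope)


@dataclass
class SuccessiveDiffStats:
    """Per-species jump statistics and the cross-species scaling fit."""

    mean_abs_diff: np.ndarray
    mean_abundance: np.ndarray
    slope: float
    intercept: float
    used: np.ndarray  # mask of species entering the regression


@dataclass
class RatioFit:
    """Lognormal (mean = 1) fit to successive-abundance ratios."""

    sigma: float
    ks_pvalue: float
    n_ratios: int
    degenerate: bool = False


@dataclass
class RankAbundanceProfile:
    ranks: np.ndarray
    abundances: np.ndarray  # descending time-averaged abundances
    per_time: np.ndarray | None = None  # optional (T x S) sorted profiles


def power_spectral_density(
    x: np.ndarray, sampling_interval: float = 1.0, taper: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-removed periodogram of a single uniformly sampled trajectory.

    Returns positive Fourier frequencies up to Nyquist and the associated
    power.  No taper is applied by default; the windowing bias is handled
    downstream by discarding the lowest frequency decade before fitting.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a single-species trajectory")
    if x.size < 64:
        raise ValueError("need at least 64 uniformly spaced points for a spectrum")
    if np.ptp(x) == 0:
        raise ValueError("constant series has a degenerate spectrum")
    window = "hann" if taper else "boxcar"
    f, p = signal.periodogram(x, fs=1.0 / sampling_interval, window=window,
                              detrend="constant")
    return f[1:], p[1:]


def noise_color_slope(
    frequencies: np.ndarray,
    power: np.ndarray,
    cutoff_decades: float = 1.0,
    method: str = "linear-cutoff",
) -> PSDFit:
    """Fit the log-log slope of a power spectrum.

    ``linear-cutoff`` (default): ordinary least squares of log10(power) on
    log10(frequency) after discarding the lowest ``cutoff_decades`` decades
    of frequencies, which are biased by the finite observation window.

    ``spline-min-derivative`` (experimental): smoothing spline on log-log
    axes; the reported slope is the minimum of its derivative, which tends
    to be darker than the linear fit when the spectrum bends at low
    frequency.
    """
    f = np.asarray(frequencies, dtype=float)
    p = np.asarray(power, dtype=float)
    if f.shape != p.shape or f.ndim != 1:
        raise ValueError("frequencies and power must be matching 1-D arrays")
    cutoff = f.min() * 10.0 ** cutoff_decades
    keep = (f >= cutoff) & (p > 0)
    if keep.sum() < 10:
        raise ValueError("fewer than 10 frequency points remain after the low-frequency cutoff")
    lf, lp = np.log10(f[keep]), np.log10(p[keep])
    if method == "linear-cutoff":
        slope = float(np.polyfit(lf, lp, 1)[0])
    elif method == "spline-min-derivative":
        from scipy.interpolate import UnivariateSpline

        order = np.argsort(lf)
        lf_s, lp_s = lf[order], lp[order]
        # smoothing proportional to the scatter of the log-periodogram
        spl = UnivariateSpline(lf_s, lp_s, k=3, s=len(lf_s) * np.var(lp_s) * 0.5)
        grid = np.linspace(lf_s[0], lf_s[-1], 256)
        slope = float(np.min(spl.derivative()(grid)))
    else:
        raise ValueError(f"unknown fit method {method!r}")
    return PSDFit(frequencies=f, power=p, slope=slope, method=method,
                  cutoff_frequency=float(cutoff))


def classify_color(slope: float) -> str:
    """Map a spectral slope to the nearest canonical noise color.

    Anchors are white 0, pink -1, brown -2, black -3 with bin edges at
    -0.5, -1.5 and -2.5; slopes above 0 are white and below -3 black.
    """
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    if slope > -0.5:
        return "white"
    if slope > -1.5:
        return "pink"
    if slope > -2.5:
        return "brown"
    return "black"


def noise_color(
    series: AbundanceSeries,
    cutoff_decades: float = 1.0,
    method: str = "linear-cutoff",
) -> list[PSDFit]:
    """Per-species PSD fits for every species of a series."""
    out = []
    for i in range(series.n_species):
        f, p = power_spectral_density(series.values[:, i], series.sampling_interval)
        out.append(noise_color_slope(f, p, cutoff_decades=cutoff_decades, method=method))
    return out


def successive_difference_stats(series: AbundanceSeries) -> SuccessiveDiffStats:
    """Mean absolute jumps vs mean abundances, with the cross-species fit.

    Species whose mean abundance or mean jump is zero carry no information
    about the scaling and are excluded from the log-log regression (with a
    warning).
    """
    v = series.values
    if v.shape[0] < 2:
        raise ValueError("need at least 2 time points")
    mean_abs_diff = np.abs(np.diff(v, axis=0)).mean(axis=0)
    mean_abundance = v.mean(axis=0)
    used = (mean_abs_diff > 0) & (mean_abundance > 0)
    if used.sum() < v.shape[1]:
        warnings.warn(
            f"excluded {v.shape[1] - used.sum()} species with zero mean abundance or "
            "zero fluctuation from the difference-scaling regression"
        )
    if used.sum() >= 3:
        fit = stats.linregress(np.log10(mean_abundance[used]), np.log10(mean_abs_diff[used]))
        slope, intercept = float(fit.slope), float(fit.intercept)
    else:
        warnings.warn("fewer than 3 usable species; difference-scaling slope undefined")
        slope, intercept = float("nan"), float("nan")
    return SuccessiveDiffStats(mean_abs_diff=mean_abs_diff, mean_abundance=mean_abundance,
                               slope=slope, intercept=intercept, used=used)


def ratio_distribution_width(x: np.ndarray, min_ratios: int = 50) -> RatioFit:
    """Width of the lognormal (centered at one) fitted to successive ratios.

    Fluctuations around steady state are symmetric on the log scale: the
    log-ratios ``ln(x(t+dt)/x(t))`` of a stationary series average zero,
    so the fitted lognormal is pinned at ratio one by fixing its
    log-location to 0 and fitting only the width.  The maximum-likelihood
    width is then ``sigma^2 = mean(ln^2 r)`` in closed form.  Goodness of
    fit is the two-sided Kolmogorov-Smirnov p-value of the ratios against
    the fitted lognormal.

    (Fixing the *arithmetic* mean of the lognormal at one instead is
    incompatible with stationary multiplicative dynamics: for widths of
    order one the arithmetic mean of observed ratios is far above one
    while the log-mean stays at zero, and the Kolmogorov-Smirnov test
    rejects the shifted fit however strong the noise.)
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a single-species trajectory")
    ok = (x[1:] > 0) & (x[:-1] > 0)
    r = x[1:][ok] / x[:-1][ok]
    if r.size < min_ratios:
        raise ValueError(f"only {r.size} valid ratios; need at least {min_ratios}")
    y = np.log(r)
    if np.ptp(y) == 0 and y[0] == 0:
        return RatioFit(sigma=0.0, ks_pvalue=float("nan"), n_ratios=r.size, degenerate=True)
    sigma = float(np.sqrt(np.mean(y * y)))
    ks = stats.kstest(r, "lognorm", args=(sigma, 0.0, 1.0))
    return RatioFit(sigma=sigma, ks_pvalue=float(ks.pvalue), n_ratios=int(r.size))


def rank_abundance(series: AbundanceSeries, per_time: bool = False) -> RankAbundanceProfile:
    """Time-averaged abundances sorted from most to least abundant."""
    mean = series.values.mean(axis=0)
    profile = np.sort(mean)[::-1]
    pt = -np.sort(-series.values, axis=1) if per_time else None
    return RankAbundanceProfile(ranks=np.arange(1, mean.size + 1), abundances=profile,
                                per_time=pt)


def to_relative_abundance(series: AbundanceSeries) -> AbundanceSeries:
    """Row-normalize so every time point sums to one."""
    totals = series.values.sum(axis=1)
    if np.any(totals <= 0):
        bad = int(np.argmax(totals <= 0))
        raise ValueError(f"time point {bad} has non-positive total abundance")
    return AbundanceSeries(times=series.times, values=series.values / totals[:, None],
                           species_labels=list(series.species_labels),
                           metadata={**series.metadata, "relative": True})
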