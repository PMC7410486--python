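"""Neutrality measures for community time series.

Two complementary tests ask whether fluctuations could come from neutral
drift (all species equivalent) rather than species-specific niches:

* the **Kullback-Leibler distance to neutrality**: summarize the series by
  a multivariate Gaussian (mean vector, covariance matrix), project the
  summary onto the exchangeable manifold (all means equal, all variances
  equal, all covariances equal), and compute the closed-form Gaussian KL
  divergence between the two.  Zero means statistically exchangeable
  species; large values indicate the niche regime.

* the **neutral covariance test (NCT)**: a grouping-invariance test
  against a Wright-Fisher null.  In a Wright-Fisher community of effective
  size N, any aggregate of species with relative abundance f has increment
  variance f(1-f)/N — the per-capita drift rate is invariant under
  grouping.  The test measures the dispersion of drift-rate estimates over
  many random species bipartitions and calibrates it against simulated
  Wright-Fisher communities matched on species number, series length and
  effective size, yielding a p-value that is approximately uniform under
  the neutral null.  Small p rejects neutrality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .characterize import to_relative_abundance
from .simulate import AbundanceSeries

__all__ = [
    "GaussianSummary",
    "NeutralityResult",
    "gaussian_summary",
    "neutral_projection",
    "kl_divergence_gaussian",
    "kl_neutrality",
    "wright_fisher_simulate",
    "neutral_covariance_test",
    "neutrality_report",
]


@dataclass
class GaussianSummary:
    """Mean vector and covariance matrix of a community series."""

    mean: np.ndarray
    covariance: np.ndarray
    n_samples: int = 0

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        S = self.mean.size
        if self.covariance.shape != (S, S):
            raise ValueError("covariance shape must match mean length")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")

    @property
    def n_species(self) -> int:
        return self.mean.size


@dataclass
class NeutralityResult:
    """KL distance to neutrality and NCT p-value with regime labels."""

    kl_divergence: float
    nct_p_value: float
    kl_threshold: float | None = None
    nct_alpha: float = 0.05

    @property
    def kl_regime(self) -> str:
        if self.kl_threshold is None:
            return "unlabelled"
        return "niche" if self.kl_divergence > self.kl_threshold else "neutral"

    @property
    def nct_regime(self) -> str:
        return "niche" if self.nct_p_value < self.nct_alpha else "neutral"


def gaussian_summary(series: AbundanceSeries) -> GaussianSummary:
    """Sample mean and covariance of the abundance vectors over time."""
    v = series.values
    if v.shape[0] < 3:
        raise ValueError("need at least 3 time points for a covariance estimate")
    if v.shape[0] <= v.shape[1]:
        warnings.warn("fewer time points than species; covariance estimate is singular")
    mean = v.mean(axis=0)
    cov = np.cov(v, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    return GaussianSummary(mean=mean, covariance=cov, n_samples=v.shape[0])


def neutral_projection(summary: GaussianSummary) -> GaussianSummary:
    """Project a Gaussian summary onto the exchangeable (neutral) manifold.

    All means are replaced by their average, all variances by the average
    variance, and all covariances by the average off-diagonal covariance.
    The projection is idempotent and permutation invariant.
    """
    S = summary.n_species
    if S < 2:
        raise ValueError("neutral projection needs at least 2 species")
    mu = float(summary.mean.mean())
    diag = float(np.trace(summary.covariance) / S)
    off_sum = float(summary.covariance.sum() - np.trace(summary.covariance))
    off = off_sum / (S * (S - 1))
    K = np.full((S, S), off)
    np.fill_diagonal(K, diag)
    return GaussianSummary(mean=np.full(S, mu), covariance=K, n_samples=summary.n_samples)


def kl_divergence_gaussian(
    P: GaussianSummary, Q: GaussianSummary, regularization: float = 1e-8
) -> float:
    """Closed-form KL divergence D(P || Q) between multivariate Gaussians.

    ``D = 1/2 (ln det K_Q / det K_P - n + Tr(K_Q^-1 K_P)
    + (mu_Q - mu_P)^T K_Q^-1 (mu_Q - mu_P))``.

    Near-singular covariances (long series of near-collinear species) are
    stabilized by adding ``regularization * mean(diag)`` to both diagonals.
    """
    if P.n_species != Q.n_species:
        raise ValueError("dimension mismatch between P and Q")
    if np.array_equal(P.mean, Q.mean) and np.array_equal(P.covariance, Q.covariance):
        return 0.0
    n = P.n_species
    KP = P.covariance.copy()
    KQ = Q.covariance.copy()
    scale = max(np.mean(np.diag(KQ)), np.mean(np.diag(KP)), 1e-300)
    eps = regularization * scale
    KP[np.diag_indices(n)] += eps
    KQ[np.diag_indices(n)] += eps
    sign_q, logdet_q = np.linalg.slogdet(KQ)
    sign_p, logdet_p = np.linalg.slogdet(KP)
    if sign_q <= 0 or sign_p <= 0:
        raise ValueError("covariance matrix not positive definite after regularization")
    KQ_inv = np.linalg.inv(KQ)
    dmu = Q.mean - P.mean
    d = 0.5 * (logdet_q - logdet_p - n + np.trace(KQ_inv @ KP) + dmu @ KQ_inv @ dmu)
    return float(max(d, 0.0))


def kl_neutrality(series: AbundanceSeries, relative: bool = False) -> float:
    """KL distance from the series' Gaussian summary to its neutral projection."""
    if relative:
        series = to_relative_abundance(series)
    P = gaussian_summary(series)
    return kl_divergence_gaussian(P, neutral_projection(P))


# ---------------------------------------------------------------------------
# neutral covariance test
# ---------------------------------------------------------------------------


def wright_fisher_simulate(
    initial_freq: np.ndarray,
    n_steps: int,
    community_size: int,
    rng: np.random.Generator,
    n_replicates: int = 1,
) -> np.ndarray:
    """Neutral Wright-Fisher drift: multinomial resampling at fixed total.

    Returns frequencies of shape ``(n_replicates, n_steps + 1, S)``.
    """
    f0 = np.asarray(initial_freq, dtype=float)
    f0 = f0 / f0.sum()
    S = f0.size
    out = np.empty((n_replicates, n_steps + 1, S))
    out[:, 0] = f0
    current = np.broadcast_to(f0, (n_replicates, S)).copy()
    for t in range(1, n_steps + 1):
        counts = rng.multinomial(community_size, current)
        current = counts / community_size
        out[:, t] = current
    return out


def _drift_dispersion(freqs: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Dispersion of per-group drift-rate estimates across bipartitions.

    ``freqs``: (m, T, S) relative-abundance trajectories.
    ``groups``: (G, S) boolean membership of each random bipartition.

    For each group g the Wright-Fisher drift rate is estimated as
    ``v_g = mean_t[(df_g)^2 / (f_g (1 - f_g))]``; under neutral drift every
    ``v_g`` estimates 1/N, so the statistic -- the standard deviation of
    ``log v_g`` across groups -- is small; niche-structured noise makes the
    per-group rates composition-dependent and the dispersion large.
    Returns one statistic per trajectory (shape ``(m,)``).
    """
    # aggregate: (m, T, G)
    f_g = np.einsum("mts,gs->mtg", freqs, groups.astype(float))
    f_mid = f_g[:, :-1, :]
    num = np.diff(f_g, axis=1) ** 2
    # steps where the aggregate is absorbed at 0 or 1 carry no drift signal
    valid = (f_mid > 0.0) & (f_mid < 1.0)
    denom = np.where(valid, f_mid * (1.0 - f_mid), 1.0)
    contrib = np.where(valid, num / denom, 0.0)
    counts = valid.sum(axis=1)  # (m, G)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        v = contrib.sum(axis=1) / counts
        v = np.where((counts >= 5) & (v > 0), v, np.nan)
        logv = np.log(v)
        return np.nanstd(logv, axis=1)


def _random_bipartitions(S: int, n_partitions: int, rng: np.random.Generator) -> np.ndarray:
    groups = np.zeros((n_partitions, S), dtype=bool)
    for k in range(n_partitions):
        size = int(rng.integers(1, S))
        idx = rng.choice(S, size=size, replace=False)
        groups[k, idx] = True
    return groups


def neutral_covariance_test(
    series: AbundanceSeries,
    n_null: int = 100,
    n_partitions: int = 64,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Grouping-invariance test of neutrality against a Wright-Fisher null.

    The series is converted to relative abundances.  The observed
    statistic is the dispersion of drift-rate estimates over random
    species bipartitions (see ``_drift_dispersion``); its null
    distribution comes from ``n_null`` simulated Wright-Fisher communities
    matched on species number, series length, initial composition and
    effective community size (estimated from the observed increments).
    Returns ``p = (1 + #{null >= observed}) / (n_null + 1)``; small p
    rejects neutrality (niche regime).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if series.n_species < 3:
        raise ValueError("neutral covariance test needs at least 3 species")
    if series.n_times < 10:
        raise ValueError("neutral covariance test needs at least 10 time points")
    rel = to_relative_abundance(series)
    f = rel.values[None, :, :]  # (1, T, S)
    S = series.n_species
    T = series.n_times

    # effective community size from pooled per-species increment variances,
    # using only steps where the species is segregating (0 < f < 1) -- the
    # same masking the test statistic applies to absorbed aggregates
    f_mid = f[0, :-1, :]
    seg = (f_mid > 0) & (f_mid < 1)
    if not seg.any():
        raise ValueError("series shows no fluctuations; test undefined")
    v_sp = (np.diff(f[0], axis=0)[seg] ** 2 / (f_mid[seg] * (1 - f_mid[seg]))).mean()
    if v_sp <= 0:
        raise ValueError("series shows no fluctuations; test undefined")
    n_eff = int(np.clip(1.0 / v_sp, 10, 1e7))

    groups = _random_bipartitions(S, n_partitions, rng)
    observed = _drift_dispersion(f, groups)[0]

    # null trajectories launch from the observed initial composition, so the
    # extinction dynamics of rare species are matched between data and null
    f0 = f[0, 0, :]
    if f0.min() <= 0:
        f0 = f0 + 0.5 / n_eff  # pseudocount for species absent at the first sample
    null_freqs = wright_fisher_simulate(f0, T - 1, n_eff, rng, n_replicates=n_null)
    null_stats = _drift_dispersion(null_freqs, groups)
    p = (1.0 + np.sum(null_stats >= observed)) / (n_null + 1.0)
    return float(p)


def neutrality_report(
    series: AbundanceSeries,
    n_null: int = 100,
    seed: int | None = None,
    kl_relative: bool = False,
    kl_threshold: float | None = None,
    nct_alpha: float = 0.05,
) -> NeutralityResult:
    """Run both neutrality measures on one series."""
    rng = np.random.default_rng(seed)
    return NeutralityResult(
        kl_divergence=kl_neutrality(series, relative=kl_relative),
        nct_p_value=neutral_covariance_test(series, n_null=n_null, rng=rng),
        kl_threshold=kl_threshold,
        nct_alpha=nct_alpha,
    )
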