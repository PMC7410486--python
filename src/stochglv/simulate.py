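"""Euler-Maruyama integration of stochastic Lotka-Volterra dynamics.

Three independent noise channels can act on each species:

* **linear** (extrinsic, growth-rate fluctuations): ``sigma_lin_i x_i dW``
* **square-root** (intrinsic, demographic birth/death): ``sigma_sqrt_i sqrt(x_i) dW'``
* **additive** (fluctuating immigration): ``sigma_add_i dW''``

Each Wiener increment is independent per species and per channel, with
variance ``dt``.  The square-root channel is shut off for abundances below
one: its derivation rests on Poisson counting statistics of discrete
individuals, which is meaningless below a single individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import GLVParameters, solve_steady_state

__all__ = ["NoiseSpec", "SimulationConfig", "AbundanceSeries", "simulate", "sqrt_noise_amplitude"]

#: abundance below which the demographic (square-root) channel is suppressed
SQRT_NOISE_FLOOR = 1.0


@dataclass
class NoiseSpec:
    """Per-species strengths of the three noise channels.

    Scalars broadcast over species.  Units: ``sigma_lin`` 1/sqrt(time),
    ``sigma_sqrt`` sqrt(abundance)/sqrt(time), ``sigma_add``
    abundance/sqrt(time).
    """

    sigma_lin: np.ndarray | float = 0.0
    sigma_sqrt: np.ndarray | float = 0.0
    sigma_add: np.ndarray | float = 0.0

    def broadcast(self, S: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        out = []
        for name in ("sigma_lin", "sigma_sqrt", "sigma_add"):
            v = np.broadcast_to(np.asarray(getattr(self, name), dtype=float), (S,)).copy()
            if np.any(v < 0):
                raise ValueError(f"{name} must be >= 0")
            out.append(v)
        return tuple(out)


@dataclass
class SimulationConfig:
    """Integration and sampling plan.

    ``sampling_interval`` (delta t) is the spacing of emitted samples and
    must be an integer multiple of the integration step ``dt`` (default
    ``sampling_interval / 100``).  ``initial_state`` is either an abundance
    vector or the string ``"steady_state"``.  ``negativity_policy`` is
    ``"clip"`` (project onto 0 after each step) or ``"reject-step"``
    (redraw the offending species' noise, falling back to clipping).
    """

    total_time: float
    sampling_interval: float = 1.0
    dt: float | None = None
    initial_state: np.ndarray | str = "steady_state"
    transient_discard: float = 0.0
    seed: int | None = None
    negativity_policy: str = "clip"

    def __post_init__(self) -> None:
        if self.dt is None:
            self.dt = self.sampling_interval / 100.0
        if not (0 < self.dt <= self.sampling_interval <= self.total_time):
            raise ValueError("need 0 < dt <= sampling_interval <= total_time")
        ratio = self.sampling_interval / self.dt
        if abs(ratio - round(ratio)) > 1e-9 * ratio:
            raise ValueError("sampling_interval must be an integer multiple of dt")
        if self.negativity_policy not in ("clip", "reject-step"):
            raise ValueError("negativity_policy must be 'clip' or 'reject-step'")


@dataclass
class AbundanceSeries:
    """Uniformly sampled time x species abundance matrix.

    ``values[t, i]`` is the abundance of species i at ``times[t]``; entries
    are non-negative and the time grid is uniform.
    """

    times: np.ndarray
    values: np.ndarray
    species_labels: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.times.ndim != 1:
            raise ValueError("values must be 2-D (time x species), times 1-D")
        if self.values.shape[0] != self.times.size:
            raise ValueError("times and values disagree on the number of time points")
        if self.times.size >= 2:
            steps = np.diff(self.times)
            if np.any(np.abs(steps - steps[0]) > 1e-6 * max(abs(steps[0]), 1e-300)):
                raise ValueError("time points must be uniformly spaced")
            if steps[0] <= 0:
                raise ValueError("times must be strictly increasing")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("abundances contain non-finite values")
        if np.any(self.values < 0):
            raise ValueError("abundances must be non-negative")
        if not self.species_labels:
            self.species_labels = [f"sp_{i}" for i in range(self.values.shape[1])]
        if len(self.species_labels) != self.values.shape[1]:
            raise ValueError("species_labels length mismatch")

    @property
    def n_times(self) -> int:
        return self.times.size

    @property
    def n_species(self) -> int:
        return self.values.shape[1]

    @property
    def sampling_interval(self) -> float:
        if self.times.size < 2:
            raise ValueError("need at least two time points")
        return float(self.times[1] - self.times[0])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=pd.Index(self.times, name="time"),
                            columns=self.species_labels)


def sqrt_noise_amplitude(x: np.ndarray, sigma_sqrt: np.ndarray) -> np.ndarray:
    """Demographic-noise amplitude with the small-abundance guard.

    Returns ``sigma_sqrt * sqrt(x)`` where ``x >= 1`` and 0 below: Poisson
    birth-death statistics only make sense for at least one individual.
    """
    x = np.asarray(x, dtype=float)
    amp = sigma_sqrt * np.sqrt(np.clip(x, 0.0, None))
    return np.where(x < SQRT_NOISE_FLOOR, 0.0, amp)


def simulate(
    params: GLVParameters,
    noise: NoiseSpec,
    cfg: SimulationConfig,
    x_star: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> AbundanceSeries:
    """Integrate the stochastic gLV equations and emit sampled abundances.

    Euler-Maruyama with fixed step ``cfg.dt``; every
    ``cfg.sampling_interval / cfg.dt``-th state is recorded after the
    transient.  With all noise strengths zero and the initial state at a
    fixed point, the output is constant.

    Parameters
    ----------
    x_star:
        Fixed point used when ``cfg.initial_state == "steady_state"``; if
        omitted it is solved from ``params``.
    rng:
        Overrides ``cfg.seed``.
    """
    S = params.species_count
    sig_lin, sig_sqrt, sig_add = noise.broadcast(S)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    if isinstance(cfg.initial_state, str):
        if cfg.initial_state != "steady_state":
            raise ValueError(f"unknown initial_state {cfg.initial_state!r}")
        if x_star is None:
            x_star = solve_steady_state(params).abundances
        x0 = np.asarray(x_star, dtype=float).copy()
    else:
        x0 = np.asarray(cfg.initial_state, dtype=float).copy()
    if x0.shape != (S,):
        raise ValueError("initial state length must match species count")
    if np.any(x0 < 0):
        raise ValueError("initial state must be non-negative")

    dt = cfg.dt
    stride = int(round(cfg.sampling_interval / dt))
    n_samples = int(np.floor((cfg.total_time - cfg.transient_discard) / cfg.sampling_interval)) + 1
    n_transient = int(round(cfg.transient_discard / dt))
    n_steps = n_transient + (n_samples - 1) * stride

    use_lin = bool(np.any(sig_lin > 0))
    use_sqrt = bool(np.any(sig_sqrt > 0))
    use_add = bool(np.any(sig_add > 0))
    sqrt_dt = np.sqrt(dt)

    g = params.growth
    omega = params.interactions
    lam = params.immigration
    diag = np.diag(omega).copy()
    diagonal_only = not np.any(omega - np.diag(diag))  # logistic fast path
    reject = cfg.negativity_policy == "reject-step"

    out = np.empty((n_samples, S))
    x = x0
    sample_idx = 0
    if n_transient == 0:
        out[0] = x
        sample_idx = 1

    # draw noise in blocks to amortize RNG overhead
    block = 1024
    n_channels = use_lin + use_sqrt + use_add
    noise_buf = None
    buf_pos = block

    for step in range(1, n_steps + 1):
        drift = lam + x * (g + (diag * x if diagonal_only else omega @ x))
        dx = drift * dt
        if n_channels:
            if buf_pos >= block:
                noise_buf = rng.standard_normal((block, n_channels, S))
                buf_pos = 0
            z = noise_buf[buf_pos]
            buf_pos += 1
            ch = 0
            stoch = np.zeros(S)
            if use_lin:
                stoch += sig_lin * x * z[ch]
                ch += 1
            if use_sqrt:
                stoch += sqrt_noise_amplitude(x, sig_sqrt) * z[ch]
                ch += 1
            if use_add:
                stoch += sig_add * z[ch]
            dx = dx + stoch * sqrt_dt
        x_new = x + dx
        if reject and n_channels:
            # redraw increments for species that would cross zero
            for _ in range(10):
                bad = x_new < 0
                if not bad.any():
                    break
                z2 = rng.standard_normal((n_channels, bad.sum()))
                ch = 0
                stoch_b = np.zeros(bad.sum())
                xb = x[bad]
                if use_lin:
                    stoch_b += sig_lin[bad] * xb * z2[ch]
                    ch += 1
                if use_sqrt:
                    stoch_b += sqrt_noise_amplitude(xb, sig_sqrt[bad]) * z2[ch]
                    ch += 1
                if use_add:
                    stoch_b += sig_add[bad] * z2[ch]
                x_new[bad] = xb + drift[bad] * dt + stoch_b * sqrt_dt
        np.clip(x_new, 0.0, None, out=x_new)
        x = x_new
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"integration blew up at step {step} (t={step * dt:g})")
        if step >= n_transient and (step - n_transient) % stride == 0:
            out[sample_idx] = x
            sample_idx += 1

    times = cfg.transient_discard + cfg.sampling_interval * np.arange(n_samples)
    meta = {
        "seed": cfg.seed,
        "dt": dt,
        "sampling_interval": cfg.sampling_interval,
        "negativity_policy": cfg.negativity_policy,
    }
    return AbundanceSeries(times=times, values=out, species_labels=list(params.species_labels),
                           metadata=meta)
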