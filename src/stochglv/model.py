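"""Generalized Lotka-Volterra parameter sets.

The deterministic skeleton of the community model is

    dx_i/dt = lambda_i + g_i x_i + sum_j omega_ij x_i x_j

with abundances ``x_i``, immigration rates ``lambda_i``, growth rates
``g_i`` and interaction coefficients ``omega_ij`` (the effect of species j
on species i).  Self-interactions ``omega_ii`` must be negative so that
every species is self-limiting; the special case of a diagonal interaction
matrix is the logistic model, where each species relaxes to its carrying
capacity ``g_i / |omega_ii|`` independently of the others.

This module builds, validates and interrogates such parameter sets:
random off-diagonal interaction sampling, imposing growth rates so that a
prescribed abundance vector is a fixed point, solving for fixed points, and
linear stability analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GLVParameters",
    "SteadyState",
    "InteractionSamplerConfig",
    "sample_interaction_matrix",
    "impose_growth_rates",
    "solve_steady_state",
    "is_linearly_stable",
    "glv_drift",
    "jacobian",
]


def _as_vector(v, n: int, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(v, dtype=float), (n,)).copy()
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class GLVParameters:
    """Growth / interaction / immigration bundle for S species.

    Parameters
    ----------
    growth:
        Vector ``g_i`` of intrinsic growth rates (1/time).
    interactions:
        Matrix ``omega_ij`` (1/(abundance*time)); ``omega_ij`` is the
        effect of species j on species i.  All diagonal entries must be
        strictly negative.
    immigration:
        Vector ``lambda_i`` (abundance/time), non-negative.  Defaults to 0.
    species_labels:
        Identifiers; default ``sp_0 .. sp_{S-1}``.
    """

    growth: np.ndarray
    interactions: np.ndarray
    immigration: np.ndarray | float = 0.0
    species_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.interactions = np.asarray(self.interactions, dtype=float)
        if self.interactions.ndim != 2 or self.interactions.shape[0] != self.interactions.shape[1]:
            raise ValueError("interaction matrix must be square")
        S = self.interactions.shape[0]
        self.growth = _as_vector(self.growth, S, "growth")
        self.immigration = _as_vector(self.immigration, S, "immigration")
        if np.any(np.diag(self.interactions) >= 0):
            raise ValueError("all self-interactions (diagonal entries) must be negative")
        if np.any(self.immigration < 0):
            raise ValueError("immigration rates must be non-negative")
        if not self.species_labels:
            self.species_labels = [f"sp_{i}" for i in range(S)]
        if len(self.species_labels) != S:
            raise ValueError("species_labels length does not match species count")

    @property
    def species_count(self) -> int:
        return self.interactions.shape[0]

    @property
    def self_interactions(self) -> np.ndarray:
        return np.diag(self.interactions).copy()


@dataclass
class SteadyState:
    """A fixed point of the deterministic dynamics.

    ``provenance`` records whether the abundances were imposed by the user
    (growth rates derived from them) or solved from the parameters.
    """

    abundances: np.ndarray
    provenance: str = "imposed"  # "imposed" | "solved"

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if np.any(self.abundances < 0):
            raise ValueError("steady-state abundances must be non-negative")
        if self.provenance not in ("imposed", "solved"):
            raise ValueError("provenance must be 'imposed' or 'solved'")


@dataclass
class InteractionSamplerConfig:
    """Configuration of the random interaction sampler.

    Off-diagonal entries are i.i.d. Normal(0, alpha^2); the diagonal is
    supplied explicitly because self-interactions in real communities span
    several orders of magnitude and are never well modelled by a single
    scale.
    """

    offdiag_std: float
    self_interactions: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.offdiag_std < 0:
            raise ValueError("offdiag_std (alpha) must be >= 0")
        self.self_interactions = np.asarray(self.self_interactions, dtype=float)
        if np.any(self.self_interactions >= 0):
            raise ValueError("self-interactions must be strictly negative")


def sample_interaction_matrix(
    cfg: InteractionSamplerConfig, S: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw a random interaction matrix with prescribed diagonal.

    Off-diagonal entries are i.i.d. Normal(0, alpha^2) with
    ``alpha = cfg.offdiag_std``; the diagonal equals
    ``cfg.self_interactions`` exactly.  Reproducible given ``cfg.seed`` or
    an explicit ``rng``.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    if cfg.self_interactions.shape != (S,):
        raise ValueError("cfg.self_interactions must have length S")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    omega = rng.normal(0.0, cfg.offdiag_std, size=(S, S)) if cfg.offdiag_std > 0 else np.zeros((S, S))
    np.fill_diagonal(omega, cfg.self_interactions)
    return omega


def impose_growth_rates(omega: np.ndarray, x_star: np.ndarray) -> np.ndarray:
    """Growth rates that make ``x_star`` a fixed point (with no immigration).

    Setting ``g = -omega @ x_star`` guarantees that the drift
    ``g_i x_i + sum_j omega_ij x_i x_j`` vanishes at ``x = x_star``.  This is
    how a prescribed (e.g. heavy-tailed) rank abundance profile is imposed
    on an otherwise random community.
    """
    omega = np.asarray(omega, dtype=float)
    x_star = np.asarray(x_star, dtype=float)
    if omega.ndim != 2 or omega.shape[0] != omega.shape[1]:
        raise ValueError("omega must be a square matrix")
    if x_star.shape != (omega.shape[0],):
        raise ValueError("x_star length must match omega")
    if np.any(x_star < 0):
        raise ValueError("x_star must be non-negative")
    return -omega @ x_star


def solve_steady_state(params: GLVParameters) -> SteadyState:
    """Solve the interior fixed point ``omega @ x = -g`` (immigration-free).

    Raises if the interaction matrix is singular or the solution has a
    negative component (infeasible community).
    """
    if np.any(params.immigration != 0):
        raise ValueError("steady-state solver assumes zero immigration")
    try:
        x = np.linalg.solve(params.interactions, -params.growth)
    except np.linalg.LinAlgError as exc:
        raise ValueError("interaction matrix is singular; no unique fixed point") from exc
    if np.any(x < 0):
        raise ValueError("infeasible fixed point: negative abundance component")
    return SteadyState(abundances=x, provenance="solved")


def glv_drift(params: GLVParameters, x: np.ndarray) -> np.ndarray:
    """Deterministic right-hand side ``lambda + g*x + (omega @ x)*x``."""
    x = np.asarray(x, dtype=float)
    return params.immigration + x * (params.growth + params.interactions @ x)


def jacobian(params: GLVParameters, x_star: np.ndarray) -> np.ndarray:
    """Jacobian of the drift at ``x_star``.

    ``J_ij = delta_ij (g_i + sum_k omega_ik x*_k) + omega_ij x*_i``; at an
    interior fixed point without immigration the first term vanishes and
    ``J = diag(x*) @ omega``.
    """
    x_star = np.asarray(x_star, dtype=float)
    S = params.species_count
    if x_star.shape != (S,):
        raise ValueError("x_star length must match species count")
    J = np.diag(params.growth + params.interactions @ x_star) + x_star[:, None] * params.interactions
    return J


def is_linearly_stable(params: GLVParameters, x_star: np.ndarray) -> tuple[bool, float]:
    """Linear stability of a fixed point.

    Returns ``(stable, leading_real_part)`` where ``stable`` is True iff all
    eigenvalues of the Jacobian at ``x_star`` have negative real part.
    """
    eigvals = np.linalg.eigvals(jacobian(params, x_star))
    leading = float(np.max(eigvals.real))
    return leading < 0, leading
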