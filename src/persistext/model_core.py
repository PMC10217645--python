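"""Two-phenotype population model: parameters, mean-field dynamics, fixed points.

The population consists of *normals* (count ``n``), which divide logistically at
per-capita rate ``B(t)(1 - n/K)`` and die at unit rate, and *persisters*
(count ``m``), which neither divide nor die. Normals switch to persisters at
rate ``alpha`` and persisters revert at rate ``beta``. All rates are per hour;
the death rate of normals is the unit of time and is fixed at 1/hour.

This module covers the deterministic (mean-field) level: the rate equations,
their fixed points, the relaxation time near the viable fixed point, and the
near-bifurcation closed-form estimate of the mean time to extinction (MTE).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "DEATH_RATE",
    "ModelParams",
    "MeanFieldState",
    "FixedPointSet",
    "mean_field_rhs",
    "fixed_points",
    "relaxation_time",
    "closed_form_mte",
    "integrate_mean_field",
    "default_initial_counts",
]

#: Death rate of normals (per hour). All other rates are measured in its units.
DEATH_RATE = 1.0


@dataclass(frozen=True)
class ModelParams:
    """Rate constants and carrying capacity of the two-phenotype model.

    Parameters
    ----------
    B_ref : float
        Reference birth rate of normals per hour (``B`` for a constant
        environment, ``B0`` for a sinusoidally modulated one).
    K : int
        Carrying capacity of normals; the large parameter of the WKB
        expansion.
    alpha : float
        Switching rate normals -> persisters, per hour.
    beta : float
        Switching rate persisters -> normals, per hour.
    """

    B_ref: float
    K: int
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError(f"carrying capacity K must be >= 1, got {self.K}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.B_ref < 0:
            raise ValueError(f"B_ref must be >= 0, got {self.B_ref}")
        if self.delta <= 0:
            warnings.warn(
                "B_ref <= 1: the viable fixed point is unstable and most of "
                "the escape-time theory assumes B > 1",
                stacklevel=2,
            )

    @property
    def Gamma(self) -> float:
        """Switching-rate ratio Γ = α/β (mean persister/normal abundance ratio)."""
        if self.beta == 0:
            raise ZeroDivisionError("Gamma = alpha/beta requires beta > 0")
        return self.alpha / self.beta

    @property
    def delta(self) -> float:
        """Distance from the transcritical bifurcation, δ = B_ref − 1."""
        return self.B_ref - DEATH_RATE


@dataclass(frozen=True)
class MeanFieldState:
    """Mean numbers of normals and persisters."""

    n_bar: float
    m_bar: float

    def __iter__(self):
        return iter((self.n_bar, self.m_bar))


@dataclass(frozen=True)
class FixedPointSet:
    """The extinct fixed point F0=(0,0) and the viable fixed point FM.

    ``FM = (K(1-1/B), Γ K(1-1/B))``; it is stable iff B > 1 (transcritical
    bifurcation at B = 1). For B < 1 its components are negative and it is
    unphysical.
    """

    F0: tuple[float, float]
    FM: tuple[float, float]
    FM_stable: bool
    FM_physical: bool


def mean_field_rhs(
    state: MeanFieldState | tuple[float, float], B: float, params: ModelParams
) -> tuple[float, float]:
    """Right-hand side of the mean-field rate equations.

    dn̄/dt = B n̄ (1 − n̄/K) − n̄ − α n̄ + β m̄
    dm̄/dt = α n̄ − β m̄
    """
    n, m = state
    dn = B * n * (1.0 - n / params.K) - n - params.alpha * n + params.beta * m
    dm = params.alpha * n - params.beta * m
    return dn, dm


def fixed_points(B: float, params: ModelParams) -> FixedPointSet:
    """Fixed points of the mean-field flow for birth rate ``B``.

    Raises
    ------
    ValueError
        If ``B <= 0`` or ``beta == 0`` (Γ undefined).
    """
    if B <= 0:
        raise ValueError(f"fixed points require B > 0, got B={B}")
    if params.beta <= 0:
        raise ValueError("fixed points require beta > 0")
    nM = params.K * (1.0 - 1.0 / B)
    Gamma = params.alpha / params.beta
    mM = Gamma * nM
    return FixedPointSet(
        F0=(0.0, 0.0),
        FM=(nM, mM),
        FM_stable=B > 1.0,
        FM_physical=nM >= 0.0,
    )


def _jacobian_at_FM(B: float, params: ModelParams) -> np.ndarray:
    nM = params.K * (1.0 - 1.0 / B)
    # d/dn [B n (1-n/K)] = B(1 - 2n/K); at nM this is 2 - B.
    j11 = B * (1.0 - 2.0 * nM / params.K) - 1.0 - params.alpha
    return np.array(
        [[j11, params.beta], [params.alpha, -params.beta]], dtype=float
    )


def relaxation_time(B: float, params: ModelParams, mode: str = "fast") -> float:
    """Relaxation time near FM from the Jacobian eigenvalues.

    The Jacobian at FM has two negative eigenvalues. ``mode="fast"``
    (default) returns 1/|λ₋| for the larger-magnitude one — the rate at
    which the normals relax onto the slow persister manifold, which obeys
    t_r ≈ 1/δ (δ = B − 1) for α, β ≪ δ and is the timescale against which
    environmental frequencies are compared. ``mode="slow"`` returns 1/|λ₊|
    for the least-negative eigenvalue — the (much longer, ≈1/β for slow
    switching) timescale of the final approach along the persister
    direction. Only defined for B > 1, where FM is stable.
    """
    if B <= 1.0:
        raise ValueError(
            f"relaxation_time requires B > 1 (FM stable), got B={B}"
        )
    eigvals = np.sort(np.linalg.eigvals(_jacobian_at_FM(B, params)).real)
    lam = eigvals[0] if mode == "fast" else eigvals[-1]
    if mode not in ("fast", "slow"):
        raise ValueError(f"mode must be 'fast' or 'slow', got {mode!r}")
    if lam >= 0:
        raise ArithmeticError(
            f"FM not attracting at B={B}: eigenvalue {lam}"
        )
    return 1.0 / abs(lam)


def closed_form_mte(params: ModelParams) -> tuple[float, float]:
    """Near-bifurcation closed-form estimate of the extinction barrier and MTE.

    Returns ``(S_cf, tau_cf)`` with ``S_cf = δ²(1/2 + Γ)`` and
    ``tau_cf = exp(K S_cf)``. Derived for small δ = B − 1 by timescale
    separation between fast normals and slow persisters; used here as an
    order-of-magnitude scale (e.g. for default simulation horizons) and as a
    near-bifurcation check on the instanton action.
    """
    S_cf = params.delta**2 * (0.5 + params.Gamma)
    # exp(K*S) overflows for production-size K at large delta; that is fine,
    # the log-scale value S_cf is the primary quantity.
    try:
        tau_cf = math.exp(params.K * S_cf)
    except OverflowError:
        tau_cf = math.inf
    return S_cf, tau_cf


def integrate_mean_field(
    init: MeanFieldState | tuple[float, float],
    B,
    t_max: float,
    params: ModelParams,
    rtol: float = 1e-9,
    atol: float = 1e-12,
):
    """Integrate the mean-field rate equations up to ``t_max``.

    Parameters
    ----------
    B : float or callable
        Constant birth rate or a function ``B(t)``.

    Returns
    -------
    scipy.integrate.OdeResult with fields ``t`` and ``y`` (shape (2, nt)).
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    Bfun = B if callable(B) else (lambda t: B)

    def rhs(t, z):
        return mean_field_rhs((z[0], z[1]), Bfun(t), params)

    sol = solve_ivp(
        rhs, (0.0, t_max), list(init), method="LSODA", rtol=rtol, atol=atol
    )
    if not sol.success:
        raise RuntimeError(f"mean-field integration failed: {sol.message}")
    return sol


def default_initial_counts(K: int) -> tuple[int, int]:
    """Default initial condition (n0, m0) = (⌊0.7 K/2⌋, ⌊0.3 K/2⌋)."""
    return int(0.7 * K / 2), int(0.3 * K / 2)
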