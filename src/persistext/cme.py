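"""Finite-truncation master-equation solver: the small-system oracle.

The chemical master equation for the reaction network is solved exactly on a
truncated lattice (n <= n_max, m <= m_max), optionally augmented with the
telegraph state zeta = +-1 for dichotomous Markov noise. This provides
brute-force reference values (mean absorption times, quasi-stationary
distributions, survival curves) against which the stochastic samplers and,
qualitatively, the WKB scaling are validated. It is a small-K instrument:
production carrying capacities (K ~ 500-1000) are far outside its reach.

Convention: the generator Q acts on probability column vectors, dP/dt = Q P,
so every column sums to zero and off-diagonal entries Q[j, i] are the rates
i -> j.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import eigs, expm_multiply, spsolve

from .environment import EnvironmentSpec
from .model_core import ModelParams

__all__ = [
    "TruncatedStateSpace",
    "build_generator",
    "mean_absorption_time",
    "qsd_eigenvector",
    "transient_propagate",
    "default_state_space",
]


@dataclass(frozen=True)
class TruncatedStateSpace:
    """Enumeration of (n, m[, zeta]) states with a flat index.

    Index layout: ``[zeta-block] * (n_max+1)*(m_max+1) + n*(m_max+1) + m``
    with zeta=-1 in block 0 and zeta=+1 in block 1 when ``dmn`` is set.
    """

    n_max: int
    m_max: int
    dmn: bool = False

    @property
    def block(self) -> int:
        return (self.n_max + 1) * (self.m_max + 1)

    @property
    def size(self) -> int:
        return self.block * (2 if self.dmn else 1)

    def index(self, n: int, m: int, zeta: int = 1) -> int:
        if not (0 <= n <= self.n_max and 0 <= m <= self.m_max):
            raise IndexError(f"state ({n},{m}) outside truncation")
        base = n * (self.m_max + 1) + m
        if self.dmn:
            return ((zeta + 1) // 2) * self.block + base
        return base

    def absorbing_indices(self) -> np.ndarray:
        """Indices of the absorbing state n = m = 0 (one per zeta block)."""
        if self.dmn:
            return np.array([self.index(0, 0, -1), self.index(0, 0, 1)])
        return np.array([self.index(0, 0)])

    def boundary_indices(self) -> np.ndarray:
        """States on the truncation boundary (n = n_max or m = m_max)."""
        idx = []
        zetas = (-1, 1) if self.dmn else (1,)
        for z in zetas:
            for m in range(self.m_max + 1):
                idx.append(self.index(self.n_max, m, z))
            for n in range(self.n_max):
                idx.append(self.index(n, self.m_max, z))
        return np.asarray(idx)


def default_state_space(
    params: ModelParams, dmn: bool = False, n_margin: float = 1.5
) -> TruncatedStateSpace:
    """Heuristic truncation: n_max ~ 1.5 K, m_max ~ 4 Gamma K.

    The persister marginal decays quickly beyond Gamma * n_M, so 4 Gamma K
    leaves negligible boundary mass; the truncation loss should be audited
    post hoc via :func:`qsd_eigenvector`.
    """
    n_max = int(math.ceil(n_margin * params.K)) + 5
    Gamma = params.alpha / params.beta if params.beta > 0 else 0.0
    m_max = int(math.ceil(4.0 * max(Gamma, 0.25) * params.K)) + 5
    return TruncatedStateSpace(n_max=n_max, m_max=m_max, dmn=dmn)


def _add_reactions(rows, cols, vals, space, B, zeta, params):
    """Append reaction rates for one zeta block (or the only block)."""
    K = params.K
    for n in range(space.n_max + 1):
        for m in range(space.m_max + 1):
            i = space.index(n, m, zeta)
            birth = max(0.0, B * n * (1.0 - n / K))
            if birth > 0 and n < space.n_max:
                rows.append(space.index(n + 1, m, zeta)); cols.append(i); vals.append(birth)
            if n > 0:
                rows.append(space.index(n - 1, m, zeta)); cols.append(i); vals.append(float(n))
            sw = params.alpha * n
            if sw > 0 and m < space.m_max:
                rows.append(space.index(n - 1, m + 1, zeta)); cols.append(i); vals.append(sw)
            rev = params.beta * m
            if rev > 0 and n < space.n_max:
                rows.append(space.index(n + 1, m - 1, zeta)); cols.append(i); vals.append(rev)


def build_generator(
    params: ModelParams,
    B_or_env: float | EnvironmentSpec,
    space: TruncatedStateSpace,
) -> sp.csc_matrix:
    """Sparse generator Q (columns sum to zero) on the truncated space.

    ``B_or_env`` is either a constant birth rate (plain space) or a DMN
    EnvironmentSpec (zeta-augmented space, flips at rates nu+/nu-). Reactions
    that would leave the truncation are dropped; audit the induced loss with
    :func:`qsd_eigenvector`.
    """
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    if isinstance(B_or_env, EnvironmentSpec):
        env = B_or_env
        if env.kind not in ("SDMN", "ADMN"):
            raise ValueError("build_generator accepts a constant B or a DMN spec")
        if not space.dmn:
            raise ValueError("DMN generator needs a zeta-augmented state space")
        _add_reactions(rows, cols, vals, space, env.B_plus, 1, params)
        _add_reactions(rows, cols, vals, space, env.B_minus, -1, params)
        for n in range(space.n_max + 1):
            for m in range(space.m_max + 1):
                ip = space.index(n, m, 1)
                im = space.index(n, m, -1)
                rows.append(im); cols.append(ip); vals.append(env.nu_plus)
                rows.append(ip); cols.append(im); vals.append(env.nu_minus)
    else:
        if space.dmn:
            raise ValueError("constant-B generator on a zeta-augmented space")
        _add_reactions(rows, cols, vals, space, float(B_or_env), 1, params)
    Q = sp.coo_matrix((vals, (rows, cols)), shape=(space.size, space.size)).tocsc()
    Q = Q - sp.diags(np.asarray(Q.sum(axis=0)).ravel())
    return Q.tocsc()


def _transient_mask(space: TruncatedStateSpace) -> np.ndarray:
    mask = np.ones(space.size, dtype=bool)
    mask[space.absorbing_indices()] = False
    return mask


def mean_absorption_profile(Q: sp.spmatrix, space: TruncatedStateSpace) -> np.ndarray:
    """Expected absorption time from every state (zero at the absorbing state).

    Solves Q_tt^T tau = -1 over the transient block; the QSD-weighted average
    of this profile equals the reciprocal decay rate when the spectral gap is
    large.
    """
    mask = _transient_mask(space)
    Qtt = Q[np.ix_(mask, mask)].tocsc()
    tau = np.zeros(space.size)
    tau[mask] = spsolve(Qtt.T.tocsc(), -np.ones(int(mask.sum())))
    return tau


def mean_absorption_time(
    Q: sp.spmatrix,
    space: TruncatedStateSpace,
    init: tuple[int, int],
    zeta_dist: tuple[float, float] | None = None,
) -> float:
    """Expected time to reach n = m = 0 from ``init`` = (n0, m0).

    Solves the linear system Q_tt^T tau = -1 over the transient block. For a
    DMN-augmented space, ``zeta_dist = (P(-1), P(+1))`` weights the initial
    environment (defaults to equal weights).
    """
    mask = _transient_mask(space)
    Qtt = Q[np.ix_(mask, mask)].tocsc()
    rhs = -np.ones(int(mask.sum()))
    with warnings.catch_warnings():
        warnings.simplefilter("error", sp.linalg.MatrixRankWarning)
        try:
            tau_t = spsolve(Qtt.T.tocsc(), rhs)
        except sp.linalg.MatrixRankWarning as exc:  # pragma: no cover
            raise np.linalg.LinAlgError(
                "transient generator is singular: absorbing state unreachable "
                "from part of the truncated space"
            ) from exc
    tau = np.zeros(space.size)
    tau[mask] = tau_t
    n0, m0 = init
    if space.dmn:
        w = zeta_dist if zeta_dist is not None else (0.5, 0.5)
        return float(
            w[0] * tau[space.index(n0, m0, -1)] + w[1] * tau[space.index(n0, m0, 1)]
        )
    return float(tau[space.index(n0, m0)])


def qsd_eigenvector(
    Q: sp.spmatrix, space: TruncatedStateSpace
) -> tuple[np.ndarray, float, float]:
    """Quasi-stationary distribution and decay rate of the transient block.

    Returns ``(pi, decay_rate, boundary_mass)`` where ``pi`` (length
    space.size, zero at absorbing states) is the principal right eigenvector
    of the transient generator normalized to sum 1, ``decay_rate = -lambda_1``
    so that P(survive to t) ~ exp(-decay_rate * t), and ``boundary_mass`` is
    the QSD mass on the truncation boundary (warned about above 1e-8).
    """
    mask = _transient_mask(space)
    Qtt = Q[np.ix_(mask, mask)].tocsc()
    if Qtt.shape[0] < 50:
        dvals, dvecs = np.linalg.eig(Qtt.toarray())
        k = int(np.argmax(dvals.real))
        lam, v = dvals[k].real, dvecs[:, k].real
    else:
        vals, vecs = eigs(Qtt, k=1, sigma=1e-12, which="LM")
        lam = vals[0].real
        v = vecs[:, 0].real
    v = np.abs(v)
    v /= v.sum()
    pi = np.zeros(space.size)
    pi[mask] = v
    boundary_mass = float(pi[space.boundary_indices()].sum())
    if boundary_mass > 1e-8:
        warnings.warn(
            f"QSD truncation-boundary mass {boundary_mass:.2e} > 1e-8; "
            "enlarge the state space",
            stacklevel=2,
        )
    return pi, float(-lam), boundary_mass


def marginal_total_size(pi: np.ndarray, space: TruncatedStateSpace) -> np.ndarray:
    """Marginal distribution of N = n + m implied by a state distribution."""
    out = np.zeros(space.n_max + space.m_max + 1)
    zetas = (-1, 1) if space.dmn else (1,)
    for z in zetas:
        for n in range(space.n_max + 1):
            for m in range(space.m_max + 1):
                out[n + m] += pi[space.index(n, m, z)]
    return out


def transient_propagate(
    params: ModelParams,
    space: TruncatedStateSpace,
    B,
    init: tuple[int, int],
    horizon: float,
    dt: float | None = None,
    stop_survival: float = 1e-4,
) -> dict:
    """Propagate the truncated master equation with time-dependent B(t).

    ``B`` may be a constant or a callable t -> B(t). The propagation uses
    piecewise-constant midpoint freezing of B over steps ``dt`` (exact for a
    constant B) with sparse matrix exponentials. Returns a dict with the
    survival curve, the MTE  integral of S(t) dt  (tail-corrected using the
    terminal log-slope), and a probability-conservation diagnostic.

    The MTE is reliable only if the survival has decayed below
    ``stop_survival`` within ``horizon`` (warned otherwise).
    """
    if space.dmn:
        raise ValueError("transient_propagate expects a plain (n, m) space")
    Q0 = build_generator(params, 0.0, space)        # death + switching
    Q1 = build_generator(params, 1.0, space)        # + unit-B birth
    Qb = (Q1 - Q0).tocsc()                           # birth structure
    Bfun = B if callable(B) else (lambda t, _B=float(B): _B)
    if dt is None:
        dt = max(horizon / 2000.0, 1e-3)
    P = np.zeros(space.size)
    P[space.index(*init)] = 1.0
    absorbing = space.absorbing_indices()
    times = [0.0]
    survival = [1.0]
    t = 0.0
    while t < horizon:
        step = min(dt, horizon - t)
        Bmid = Bfun(t + 0.5 * step)
        A = (Q0 + Bmid * Qb) * step
        P = expm_multiply(A, P)
        t += step
        times.append(t)
        survival.append(1.0 - float(P[absorbing].sum()))
        if survival[-1] < stop_survival:
            break
    times_a = np.asarray(times)
    surv_a = np.asarray(survival)
    mass_err = abs(float(P.sum()) - 1.0)
    if mass_err > 1e-8:
        warnings.warn(f"probability mass error {mass_err:.2e}", stacklevel=2)
    mte = float(np.trapezoid(surv_a, times_a))
    tail = 0.0
    if surv_a[-1] > 0 and len(surv_a) > 2 and surv_a[-2] > surv_a[-1] > 0:
        rate = math.log(surv_a[-2] / surv_a[-1]) / (times_a[-1] - times_a[-2])
        if rate > 0:
            tail = surv_a[-1] / rate
    mte += tail
    if surv_a[-1] > stop_survival:
        warnings.warn(
            f"horizon {horizon:g} too short: survival still {surv_a[-1]:.3g}; "
            "MTE relies on the exponential tail extrapolation",
            stacklevel=2,
        )
    return {
        "times": times_a,
        "survival": surv_a,
        "mte": mte,
        "tail_correction": tail,
        "mass_error": mass_err,
    }
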