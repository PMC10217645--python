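"""Exact stochastic simulation of the two-phenotype birth-death-switch model.

This module is the package's synthetic-data generator: every downstream
observable (MTE estimates, quasi-stationary histograms, escape-time
distributions) consumes the trajectory ensembles produced here.

Samplers
--------
ssa_constant
    Standard Gillespie for a constant birth rate.
ssa_dmn
    Standard Gillespie for dichotomous Markov noise; the environment flip is
    a fifth reaction channel, so the joint (n, m, zeta) chain is
    time-homogeneous and the sampling is exact.
ssa_time_dependent
    Modified Gillespie for explicitly time-dependent B(t) (sinusoid or
    rectangular wave): the next event time inverts the cumulative total
    hazard against a unit exponential.
ssa_next_reaction
    Modified next-reaction method (per-channel internal clocks) for
    rectangular/square waves; agrees in law with ssa_time_dependent.
run_ensemble
    Dispatches on the environment kind and runs independent, reproducibly
    seeded trajectories.

Extinction means n = m = 0 simultaneously; n = 0 with m > 0 is not absorbing
because persister reversion (rate beta m) revives normals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from ._kernels import (
    ENV_CONSTANT,
    ENV_RECT,
    ENV_SINUSOID,
    STATUS_BUFFER_FULL,
    STATUS_CENSORED,
    STATUS_EXTINCT,
)
from .environment import EnvironmentSpec
from .model_core import ModelParams, closed_form_mte, default_initial_counts

__all__ = [
    "Trajectory",
    "Ensemble",
    "propensities",
    "ssa_constant",
    "ssa_dmn",
    "ssa_time_dependent",
    "ssa_next_reaction",
    "run_ensemble",
    "default_t_max",
]

_CHUNK = 1 << 20  # record-buffer chunk (events)
_EMPTY_F = np.empty(0, dtype=np.float64)
_EMPTY_I = np.empty(0, dtype=np.int64)


@dataclass
class Trajectory:
    """Event-stamped sample path of (n, m[, zeta]) until absorption or cutoff."""

    times: np.ndarray
    n: np.ndarray
    m: np.ndarray
    zeta: np.ndarray
    status: str  # 'extinct' | 'censored'
    seed: int
    t_max: float
    final_time: float
    final_state: tuple[int, int]

    @property
    def extinct(self) -> bool:
        return self.status == "extinct"

    @property
    def escape_time(self) -> float:
        """Absorption time; NaN if the trajectory was censored."""
        return self.final_time if self.extinct else math.nan

    def total_size(self) -> np.ndarray:
        return self.n + self.m

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.times, self.n, self.m, self.zeta])
        np.savetxt(
            path, arr, delimiter=",", header="time,n,m,zeta", comments="",
            fmt=("%.10g", "%d", "%d", "%d"),
        )


@dataclass
class Ensemble:
    """Summary of an ensemble of independent trajectories.

    ``escape_times`` holds the absorption times of the uncensored
    trajectories only; ``n_censored`` counts trajectories that hit ``t_max``
    alive and are excluded from MTE estimation.
    """

    escape_times: np.ndarray
    n_censored: int
    seeds: np.ndarray
    t_max: float
    method: str
    trajectories: list[Trajectory] | None = None
    hist: np.ndarray | None = None
    hist_window: tuple[float, float] | None = None
    n_surviving_window: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return self.escape_times.size + self.n_censored


def propensities(
    state: tuple[int, int], B: float, params: ModelParams
) -> tuple[float, float, float, float]:
    """Reaction propensities (birth, death, N->M, M->N) at a given state.

    The birth propensity ``B n (1 - n/K)`` is clipped at zero (n may exceed K
    transiently through persister reversion).
    """
    n, m = state
    birth = max(0.0, B * n * (1.0 - n / params.K))
    return birth, float(n), params.alpha * n, params.beta * m


def default_t_max(params: ModelParams) -> float:
    """Default horizon: 50x the closed-form MTE scale, at least 1000 h."""
    _, tau_cf = closed_form_mte(params)
    if math.isinf(tau_cf):
        return 1e12
    return max(50.0 * tau_cf, 1000.0)


def _finish(kernel_caller, seed_rng, kernel_seed, init, t_max, record, hist, window):
    """Drive a kernel to completion, resuming across full record buffers.

    ``kernel_caller(n, m, t0, seed, t_remaining, bufs)`` must run the kernel
    with the environment shifted to absolute time ``t0`` and return
    ``(t_rel, n, m, zeta, status, nrec, bufs_used)``.
    """
    chunks_t, chunks_n, chunks_m, chunks_z = [], [], [], []
    n, m = init
    t_abs = 0.0
    seed_k = kernel_seed
    while True:
        t_rel, n, m, zeta, status, nrec, bufs = kernel_caller(
            n, m, t_abs, seed_k, t_max - t_abs
        )
        if record and nrec:
            bt, bn, bm, bz = bufs
            chunks_t.append(bt[:nrec] + t_abs)
            chunks_n.append(bn[:nrec].copy())
            chunks_m.append(bm[:nrec].copy())
            chunks_z.append(bz[:nrec].copy())
        t_abs += t_rel
        if status != STATUS_BUFFER_FULL:
            break
        seed_k = int(seed_rng.integers(1, 2**31))
    if record:
        times = np.concatenate(chunks_t) if chunks_t else _EMPTY_F.copy()
        nn = np.concatenate(chunks_n) if chunks_n else _EMPTY_I.copy()
        mm = np.concatenate(chunks_m) if chunks_m else _EMPTY_I.copy()
        zz = np.concatenate(chunks_z) if chunks_z else _EMPTY_I.copy()
    else:
        times = nn = mm = zz = _EMPTY_F
    return times, nn, mm, zz, t_abs, (n, m), status


def _alloc(record):
    if record:
        return (
            np.empty(_CHUNK, dtype=np.float64),
            np.empty(_CHUNK, dtype=np.int64),
            np.empty(_CHUNK, dtype=np.int64),
            np.empty(_CHUNK, dtype=np.int64),
        )
    return _EMPTY_F, _EMPTY_I, _EMPTY_I, _EMPTY_I


def _hist_args(hist, window, t_abs):
    if hist is None:
        return _EMPTY_F, 0.0, 0.0
    return hist, window[0] - t_abs, window[1] - t_abs


def ssa_constant(
    params: ModelParams,
    B: float,
    init: tuple[int, int] | None = None,
    seed: int = 0,
    t_max: float | None = None,
    record: bool = True,
    _hist=None,
    _window=None,
) -> Trajectory:
    """Exact CTMC sample under a constant birth rate B."""
    init = default_initial_counts(params.K) if init is None else init
    t_max = default_t_max(params) if t_max is None else t_max
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    kseed = int(rng.integers(1, 2**31))

    def call(n, m, t_abs, s, t_rem):
        bufs = _alloc(record)
        h, ta, tb = _hist_args(_hist, _window, t_abs)
        t, n2, m2, z, status, nrec = _kernels.ssa_homogeneous(
            n, m, 1, B, B, 0.0, 0.0,
            float(params.K), params.alpha, params.beta, t_rem, s,
            record, *bufs, h, ta, tb,
        )
        return t, n2, m2, z, status, nrec, bufs

    times, nn, mm, zz, t_fin, fin, status = _finish(
        call, rng, kseed, init, t_max, record, _hist, _window
    )
    return Trajectory(
        times, nn, mm, zz,
        "extinct" if status == STATUS_EXTINCT else "censored",
        seed, t_max, t_fin, fin,
    )


def ssa_dmn(
    params: ModelParams,
    env: EnvironmentSpec,
    init: tuple[int, int] | None = None,
    seed: int = 0,
    t_max: float | None = None,
    record: bool = True,
    zeta0: int | None = None,
    _hist=None,
    _window=None,
) -> Trajectory:
    """Exact sample of the joint (n, m, zeta) chain under DMN.

    The initial environment is drawn with P(+1) = gamma (the duty cycle)
    unless ``zeta0`` or ``env.phase`` (+-1) overrides it.
    """
    if env.kind not in ("SDMN", "ADMN"):
        raise ValueError(f"ssa_dmn requires a DMN environment, got {env.kind}")
    init = default_initial_counts(params.K) if init is None else init
    t_max = default_t_max(params) if t_max is None else t_max
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if zeta0 is None:
        if env.phase is not None:
            zeta0 = int(env.phase)
            if zeta0 not in (-1, 1):
                raise ValueError("DMN phase override must be +1 or -1")
        else:
            zeta0 = 1 if rng.random() < env.gamma else -1
    kseed = int(rng.integers(1, 2**31))
    state_z = [zeta0]

    def call(n, m, t_abs, s, t_rem):
        bufs = _alloc(record)
        h, ta, tb = _hist_args(_hist, _window, t_abs)
        t, n2, m2, z, status, nrec = _kernels.ssa_homogeneous(
            n, m, state_z[0], env.B_plus, env.B_minus,
            env.nu_plus, env.nu_minus,
            float(params.K), params.alpha, params.beta, t_rem, s,
            record, *bufs, h, ta, tb,
        )
        state_z[0] = z
        return t, n2, m2, z, status, nrec, bufs

    times, nn, mm, zz, t_fin, fin, status = _finish(
        call, rng, kseed, init, t_max, record, _hist, _window
    )
    return Trajectory(
        times, nn, mm, zz,
        "extinct" if status == STATUS_EXTINCT else "censored",
        seed, t_max, t_fin, fin,
    )


def _timedep_args(env: EnvironmentSpec, rng) -> tuple:
    """(env_code, b_mid, b_amp, omega, phi, nu_p, nu_m, toff) for a spec."""
    if env.kind == "constant":
        return ENV_CONSTANT, env.B0, 0.0, 1.0, 0.0, 1.0, 1.0, 0.0
    if env.kind == "sinusoidal":
        phi = env.phase if env.phase is not None else float(rng.uniform(0.0, 2 * math.pi))
        return ENV_SINUSOID, env.B0, env.epsilon, env.omega, phi, 1.0, 1.0, 0.0
    if env.kind in ("square", "rectangular"):
        toff = env.phase if env.phase is not None else float(rng.uniform(0.0, env.period))
        b_mid = 0.5 * (env.B_plus + env.B_minus)
        b_amp = 0.5 * (env.B_plus - env.B_minus)
        return ENV_RECT, b_mid, b_amp, 1.0, 0.0, env.nu_plus, env.nu_minus, toff
    raise ValueError(f"unsupported environment kind {env.kind}")


def ssa_time_dependent(
    params: ModelParams,
    env: EnvironmentSpec,
    init: tuple[int, int] | None = None,
    seed: int = 0,
    t_max: float | None = None,
    record: bool = True,
    _hist=None,
    _window=None,
) -> Trajectory:
    """Modified Gillespie sample under a deterministic B(t).

    Supports sinusoidal and rectangular/square environments (and the
    constant degenerate case). The sinusoidal sampler requires
    epsilon <= B0 so that B(t) >= 0 everywhere.
    """
    if env.kind == "sinusoidal" and env.epsilon > env.B0:
        raise ValueError("sinusoidal SSA requires epsilon <= B0 (B(t) >= 0)")
    init = default_initial_counts(params.K) if init is None else init
    t_max = default_t_max(params) if t_max is None else t_max
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    env_code, b_mid, b_amp, omega, phi, nu_p, nu_m, toff = _timedep_args(env, rng)
    kseed = int(rng.integers(1, 2**31))

    def call(n, m, t_abs, s, t_rem):
        bufs = _alloc(record)
        h, ta, tb = _hist_args(_hist, _window, t_abs)
        # shift the drive so the kernel can restart its clock at zero
        phi_eff = phi + omega * t_abs if env_code == ENV_SINUSOID else phi
        toff_eff = toff - t_abs if env_code == ENV_RECT else toff
        t, n2, m2, status, nrec = _kernels.ssa_timedep(
            n, m, env_code, b_mid, b_amp, omega, phi_eff,
            nu_p, nu_m, toff_eff,
            float(params.K), params.alpha, params.beta, t_rem, s,
            record, *bufs, h, ta, tb,
        )
        return t, n2, m2, 0, status, nrec, bufs

    times, nn, mm, zz, t_fin, fin, status = _finish(
        call, rng, kseed, init, t_max, record, _hist, _window
    )
    return Trajectory(
        times, nn, mm, zz,
        "extinct" if status == STATUS_EXTINCT else "censored",
        seed, t_max, t_fin, fin,
    )


def ssa_next_reaction(
    params: ModelParams,
    env: EnvironmentSpec,
    init: tuple[int, int] | None = None,
    seed: int = 0,
    t_max: float | None = None,
    record: bool = True,
    _hist=None,
    _window=None,
) -> Trajectory:
    """Modified next-reaction sample under a rectangular/square wave."""
    if env.kind not in ("square", "rectangular"):
        raise ValueError(
            f"ssa_next_reaction requires a square/rectangular environment, got {env.kind}"
        )
    init = default_initial_counts(params.K) if init is None else init
    t_max = default_t_max(params) if t_max is None else t_max
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    toff = env.phase if env.phase is not None else float(rng.uniform(0.0, env.period))
    kseed = int(rng.integers(1, 2**31))

    def call(n, m, t_abs, s, t_rem):
        bufs = _alloc(record)
        h, ta, tb = _hist_args(_hist, _window, t_abs)
        t, n2, m2, status, nrec = _kernels.ssa_next_reaction(
            n, m, env.B_plus, env.B_minus, env.nu_plus, env.nu_minus,
            toff - t_abs,
            float(params.K), params.alpha, params.beta, t_rem, s,
            record, *bufs, h, ta, tb,
        )
        return t, n2, m2, 0, status, nrec, bufs

    times, nn, mm, zz, t_fin, fin, status = _finish(
        call, rng, kseed, init, t_max, record, _hist, _window
    )
    return Trajectory(
        times, nn, mm, zz,
        "extinct" if status == STATUS_EXTINCT else "censored",
        seed, t_max, t_fin, fin,
    )


def _dispatch_runner(env: EnvironmentSpec, method: str):
    if method == "auto":
        if env.kind == "constant":
            method = "constant"
        elif env.kind in ("SDMN", "ADMN"):
            method = "dmn"
        elif env.kind == "sinusoidal":
            method = "time_dependent"
        else:
            method = "next_reaction"
    table = {
        "constant": lambda p, e, **kw: ssa_constant(p, e.B0, **kw),
        "dmn": ssa_dmn,
        "time_dependent": ssa_time_dependent,
        "next_reaction": ssa_next_reaction,
    }
    if method not in table:
        raise ValueError(f"unknown method {method!r}")
    return method, table[method]


def run_ensemble(
    params: ModelParams,
    env: EnvironmentSpec,
    n_traj: int,
    seed: int = 0,
    t_max: float | None = None,
    method: str = "auto",
    init: tuple[int, int] | None = None,
    record: bool = False,
    hist_window: tuple[float, float] | None = None,
    hist_size: int | None = None,
) -> Ensemble:
    """Run ``n_traj`` independent trajectories and collect escape times.

    Seeding is per-trajectory via ``SeedSequence(seed).spawn``, so ensembles
    are bitwise reproducible and order-independent. Censored trajectories
    (alive at ``t_max``) are excluded from ``escape_times`` with a warning.

    If ``hist_window = (ta, tb)`` is given, a time-weighted occupancy
    histogram of N = n + m over the window is accumulated across
    trajectories (the quasi-stationary distribution estimator);
    ``n_surviving_window`` counts trajectories alive at ``tb``.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    t_max = default_t_max(params) if t_max is None else t_max
    init = default_initial_counts(params.K) if init is None else init
    method, runner = _dispatch_runner(env, method)
    children = np.random.SeedSequence(seed).spawn(n_traj)
    hist = None
    if hist_window is not None:
        size = hist_size if hist_size is not None else 4 * params.K
        hist = np.zeros(size, dtype=np.float64)
    escape_times = []
    trajectories = [] if record else None
    seeds = np.empty(n_traj, dtype=np.int64)
    n_censored = 0
    n_surviving = 0
    for i, child in enumerate(children):
        tseed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        seeds[i] = tseed
        traj = runner(
            params, env, init=init, seed=tseed, t_max=t_max,
            record=record, _hist=hist, _window=hist_window,
        )
        if traj.extinct:
            escape_times.append(traj.final_time)
            if hist_window is not None and traj.final_time >= hist_window[1]:
                n_surviving += 1
        else:
            n_censored += 1
            if hist_window is not None:
                n_surviving += 1
        if record:
            trajectories.append(traj)
    if n_censored:
        warnings.warn(
            f"{n_censored}/{n_traj} trajectories censored at t_max={t_max:g}; "
            "they are excluded from MTE estimation",
            stacklevel=2,
        )
    return Ensemble(
        escape_times=np.asarray(escape_times),
        n_censored=n_censored,
        seeds=seeds,
        t_max=t_max,
        method=method,
        trajectories=trajectories,
        hist=hist,
        hist_window=hist_window,
        n_surviving_window=n_surviving,
        meta={"env": env.to_dict(), "K": params.K, "alpha": params.alpha,
              "beta": params.beta, "B_ref": params.B_ref, "init": list(init),
              "seed": seed},
    )
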