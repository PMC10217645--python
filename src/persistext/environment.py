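"""Environmental drive signals B(t).

The birth rate of normals is modulated by the environment in one of three
ways:

* **dichotomous Markov noise** (DMN, telegraph noise): B jumps between B₊ and
  B₋ with exponential holding times, leaving the +1 state at rate ν₊ and the
  −1 state at rate ν₋; symmetric (SDMN) when ν₊ = ν₋, asymmetric (ADMN)
  otherwise;
* **periodic rectangular wave** with period T = 1/ν₊ + 1/ν₋ spending 1/ν₊ per
  period in the +1 state (a square wave when symmetric);
* **sinusoid** B(t) = B0 + ε sin(ωt + φ).

Conventions: ν = (ν₊+ν₋)/2 is the mean switching rate, Δ = (ν₋−ν₊)/(2ν) the
asymmetry, γ = ν₋/(ν₊+ν₋) the duty cycle (stationary fraction of time in the
favourable +1 state). The sinusoid matching a DMN/rectangular drive has
ω = πν, B0 = (B₊+B₋)/2, ε = (B₊−B₋)/2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EnvironmentSpec",
    "EnvironmentPath",
    "zeta_rect",
    "birth_rate_at",
    "sample_dmn_path",
    "dmn_to_sinusoid_params",
    "average_birth_rate",
]

_SWITCHING_KINDS = ("SDMN", "ADMN", "square", "rectangular")
_KINDS = ("constant",) + _SWITCHING_KINDS + ("sinusoidal",)


@dataclass(frozen=True)
class EnvironmentSpec:
    """Specification of one environmental drive.

    Use the constructors :meth:`constant`, :meth:`sdmn`, :meth:`admn`,
    :meth:`square`, :meth:`rectangular`, :meth:`sinusoidal` rather than the
    raw dataclass.
    """

    kind: str
    B_plus: float = math.nan
    B_minus: float = math.nan
    nu_plus: float = math.nan
    nu_minus: float = math.nan
    B0: float = math.nan
    epsilon: float = math.nan
    omega: float = math.nan
    #: fixed initial phase; None means "draw per trajectory" (uniform phase
    #: for sinusoid/rectangular, stationary ζ with P(+1)=γ for DMN).
    phase: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown environment kind {self.kind!r}")
        if self.kind in _SWITCHING_KINDS:
            if not (self.nu_plus > 0 and self.nu_minus > 0):
                raise ValueError("switching environments require nu_plus, nu_minus > 0")
            if self.B_minus > self.B_plus:
                raise ValueError("require B_minus <= B_plus")
        if self.kind == "sinusoidal":
            if self.omega <= 0:
                raise ValueError("sinusoid requires omega > 0")
            if self.epsilon < 0:
                raise ValueError("sinusoid requires epsilon >= 0")
            if self.B0 - self.epsilon < 0:
                warnings.warn(
                    "epsilon > B0: instantaneous birth rate would go negative "
                    "and will be clipped at 0",
                    stacklevel=2,
                )

    # ---- constructors -------------------------------------------------
    @classmethod
    def constant(cls, B: float) -> "EnvironmentSpec":
        return cls(kind="constant", B0=B)

    @classmethod
    def sdmn(cls, B_plus: float, B_minus: float, nu: float) -> "EnvironmentSpec":
        """Symmetric dichotomous Markov noise with flip rate ν in both states."""
        return cls(kind="SDMN", B_plus=B_plus, B_minus=B_minus, nu_plus=nu, nu_minus=nu)

    @classmethod
    def admn(
        cls, B_plus: float, B_minus: float, nu_plus: float, nu_minus: float
    ) -> "EnvironmentSpec":
        return cls(
            kind="ADMN", B_plus=B_plus, B_minus=B_minus,
            nu_plus=nu_plus, nu_minus=nu_minus,
        )

    @classmethod
    def square(
        cls, B_plus: float, B_minus: float, nu: float, phase: float | None = None
    ) -> "EnvironmentSpec":
        """Symmetric square wave, ζ(t) = sign sin(πνt) at zero phase."""
        return cls(
            kind="square", B_plus=B_plus, B_minus=B_minus,
            nu_plus=nu, nu_minus=nu, phase=phase,
        )

    @classmethod
    def rectangular(
        cls,
        B_plus: float,
        B_minus: float,
        nu_plus: float,
        nu_minus: float,
        phase: float | None = None,
    ) -> "EnvironmentSpec":
        return cls(
            kind="rectangular", B_plus=B_plus, B_minus=B_minus,
            nu_plus=nu_plus, nu_minus=nu_minus, phase=phase,
        )

    @classmethod
    def from_duty_cycle(
        cls,
        B_plus: float,
        B_minus: float,
        nu: float,
        gamma: float,
        kind: str = "rectangular",
        phase: float | None = None,
    ) -> "EnvironmentSpec":
        """Build a rectangular/ADMN spec from mean rate ν and duty cycle γ.

        Uses (ν₊, ν₋) = (2ν(1−γ), 2νγ), which gives duty cycle γ and mean
        switching rate ν.
        """
        if not 0 < gamma < 1:
            raise ValueError("duty cycle gamma must be in (0, 1)")
        nu_plus, nu_minus = 2 * nu * (1 - gamma), 2 * nu * gamma
        if kind == "ADMN":
            return cls.admn(B_plus, B_minus, nu_plus, nu_minus)
        return cls.rectangular(B_plus, B_minus, nu_plus, nu_minus, phase=phase)

    @classmethod
    def sinusoidal(
        cls, B0: float, epsilon: float, omega: float, phase: float | None = None
    ) -> "EnvironmentSpec":
        return cls(kind="sinusoidal", B0=B0, epsilon=epsilon, omega=omega, phase=phase)

    # ---- derived statistics -------------------------------------------
    @property
    def nu(self) -> float:
        """Mean switching rate ν = (ν₊+ν₋)/2."""
        return 0.5 * (self.nu_plus + self.nu_minus)

    @property
    def Delta(self) -> float:
        """Asymmetry Δ = (ν₋−ν₊)/(2ν) = stationary mean of ζ."""
        return (self.nu_minus - self.nu_plus) / (2.0 * self.nu)

    @property
    def gamma(self) -> float:
        """Duty cycle γ = ν₋/(ν₊+ν₋), stationary occupancy of ζ=+1."""
        return self.nu_minus / (self.nu_plus + self.nu_minus)

    @property
    def period(self) -> float:
        """Rectangular-wave period T = 1/ν₊ + 1/ν₋."""
        return 1.0 / self.nu_plus + 1.0 / self.nu_minus

    def with_phase(self, phase: float) -> "EnvironmentSpec":
        return replace(self, phase=phase)

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        for k in ("B_plus", "B_minus", "nu_plus", "nu_minus", "B0", "epsilon", "omega"):
            v = getattr(self, k)
            if not math.isnan(v):
                d[k] = v
        if self.phase is not None:
            d["phase"] = self.phase
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EnvironmentSpec":
        return cls(**d)


@dataclass
class EnvironmentPath:
    """A realized telegraph path: ζ constant on half-open intervals.

    ``zeta[i]`` holds on ``[switch_times[i], switch_times[i+1])``; the last
    value holds to ``t_max``.
    """

    switch_times: np.ndarray
    zeta: np.ndarray
    t_max: float = field(default=math.nan)

    def zeta_at(self, t: float) -> int:
        i = int(np.searchsorted(self.switch_times, t, side="right")) - 1
        return int(self.zeta[max(i, 0)])

    def occupancy_plus(self) -> float:
        """Fraction of [0, t_max] spent in ζ=+1 (time-weighted)."""
        edges = np.append(self.switch_times, self.t_max)
        dur = np.diff(edges)
        return float(dur[self.zeta > 0].sum() / (self.t_max - self.switch_times[0]))

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.switch_times, self.zeta])
        np.savetxt(path, arr, delimiter=",", header="switch_time,zeta", comments="")


def zeta_rect(t: float, spec: EnvironmentSpec) -> int:
    """Periodic rectangular wave ζ_p(t) ∈ {−1, 0, +1}.

    Each period of length T = 1/ν₊ + 1/ν₋ starts (at zero phase) with ζ=+1
    for a duration 1/ν₊ followed by ζ=−1 for 1/ν₋, so the duty cycle is
    γ = ν₋/(ν₊+ν₋) and the symmetric case reduces to sign{sin(πνt)}. The
    measure-zero interval edges evaluate to 0 (rect(±1/2) = 0).
    """
    if spec.kind not in ("square", "rectangular"):
        raise ValueError(f"zeta_rect requires a square/rectangular spec, got {spec.kind}")
    T = spec.period
    t_plus = 1.0 / spec.nu_plus
    u = math.fmod(t - (spec.phase or 0.0), T)
    if u < 0:
        u += T
    if u == 0.0 or u == t_plus:
        return 0
    return 1 if u < t_plus else -1


def birth_rate_at(
    t: float, spec: EnvironmentSpec, zeta: int | None = None
) -> float:
    """Instantaneous birth rate B(t) for a given environment.

    For DMN the realized ζ(t) must be supplied (the spec alone does not fix
    the random path); for rectangular waves ζ is computed from the phase if
    not given. Negative values (possible only for ε > B0) are clipped to 0
    with a warning.
    """
    if spec.kind == "constant":
        return spec.B0
    if spec.kind == "sinusoidal":
        B = spec.B0 + spec.epsilon * math.sin(spec.omega * t + (spec.phase or 0.0))
        if B < 0:
            warnings.warn("negative instantaneous birth rate clipped to 0", stacklevel=2)
            return 0.0
        return B
    if zeta is None:
        if spec.kind in ("square", "rectangular"):
            zeta = zeta_rect(t, spec)
        else:
            raise ValueError("DMN birth rate needs the realized zeta(t)")
    mid = 0.5 * (spec.B_plus + spec.B_minus)
    amp = 0.5 * (spec.B_plus - spec.B_minus)
    return mid + zeta * amp


def sample_dmn_path(
    spec: EnvironmentSpec,
    t_max: float,
    rng: np.random.Generator | int | None = None,
    zeta0: int | None = None,
) -> EnvironmentPath:
    """Sample a telegraph path on [0, t_max].

    Holding times are exponential with rate ν₊ in state +1 and ν₋ in state
    −1. The initial state is drawn from the stationary law P(+1)=γ unless
    ``zeta0`` is given.
    """
    if spec.kind not in ("SDMN", "ADMN"):
        raise ValueError(f"sample_dmn_path requires a DMN spec, got {spec.kind}")
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    rng = np.random.default_rng(rng)
    if zeta0 is None:
        zeta0 = 1 if rng.random() < spec.gamma else -1
    times = [0.0]
    zetas = [zeta0]
    t, z = 0.0, zeta0
    while True:
        rate = spec.nu_plus if z > 0 else spec.nu_minus
        t += rng.exponential(1.0 / rate)
        if t >= t_max:
            break
        z = -z
        times.append(t)
        zetas.append(z)
    return EnvironmentPath(np.asarray(times), np.asarray(zetas, dtype=int), t_max=t_max)


def dmn_to_sinusoid_params(spec: EnvironmentSpec) -> tuple[float, float, float]:
    """Sinusoid parameters (ω, B0, ε) matched to a DMN/rectangular drive.

    ω = πν, B0 = (B₊+B₋)/2, ε = (B₊−B₋)/2.
    """
    if spec.kind not in _SWITCHING_KINDS:
        raise ValueError("requires a DMN or rectangular spec")
    return (
        math.pi * spec.nu,
        0.5 * (spec.B_plus + spec.B_minus),
        0.5 * (spec.B_plus - spec.B_minus),
    )


def average_birth_rate(spec: EnvironmentSpec) -> float:
    """Duty-cycle-weighted mean birth rate B_av = γB₊ + (1−γ)B₋."""
    if spec.kind == "constant":
        return spec.B0
    if spec.kind == "sinusoidal":
        return spec.B0
    g = spec.gamma
    return g * spec.B_plus + (1.0 - g) * spec.B_minus
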