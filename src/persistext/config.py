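"""Run configuration, serialization, and reproducibility plumbing.

Configs are flat key=value files or YAML mappings; every emitted result file
carries the config hash, the seed list, and the package version, so any run
is reproducible from its outputs alone.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .environment import EnvironmentSpec
from .model_core import ModelParams, default_initial_counts

__all__ = ["RunConfig", "parse_config", "config_hash", "write_results"]

_MODEL_KEYS = {"B", "K", "alpha", "beta"}
_ENV_KEYS = {
    "kind", "B_plus", "B_minus", "nu_plus", "nu_minus", "B0", "epsilon",
    "omega", "phase", "nu", "gamma",
}
_RUN_KEYS = {"method", "n_traj", "seed", "t_max", "n0", "m0", "out"}
_KNOWN = _MODEL_KEYS | _ENV_KEYS | _RUN_KEYS


@dataclass(frozen=True)
class RunConfig:
    """Validated model + environment + runner configuration."""

    params: ModelParams
    env: EnvironmentSpec
    method: str = "auto"
    n_traj: int = 2400
    seed: int = 0
    t_max: float | None = None
    init: tuple[int, int] = field(default=None)  # type: ignore[assignment]
    out: str | None = None

    def to_dict(self) -> dict:
        d = {
            "B": self.params.B_ref, "K": self.params.K,
            "alpha": self.params.alpha, "beta": self.params.beta,
            "method": self.method, "n_traj": self.n_traj, "seed": self.seed,
            "n0": self.init[0], "m0": self.init[1],
        }
        if self.t_max is not None:
            d["t_max"] = self.t_max
        if self.out is not None:
            d["out"] = self.out
        d.update(self.env.to_dict())
        return d

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())


def config_hash(d: dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(d, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    return value


def _load_mapping(source) -> dict:
    if isinstance(source, dict):
        return dict(source)
    text = Path(source).read_text()
    stripped = [
        ln for ln in text.splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if all("=" in ln for ln in stripped):
        return {
            k.strip(): _coerce(v.strip())
            for k, v in (ln.split("=", 1) for ln in stripped)
        }
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {source} is not a mapping")
    return data


def parse_config(source, **overrides) -> RunConfig:
    """Parse and validate a config file (flat key=value or YAML) or dict.

    Unknown keys are rejected with their names; missing keys fall back to
    documented defaults (death rate 1/h is fixed; the initial condition is
    (0.7 K/2, 0.3 K/2)).
    """
    d = _load_mapping(source)
    d.update(overrides)
    unknown = set(d) - _KNOWN
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    missing = {"K", "B"} - set(d)
    if missing:
        raise ValueError(f"config missing required keys: {sorted(missing)}")
    params = ModelParams(
        B_ref=float(d["B"]), K=int(d["K"]),
        alpha=float(d.get("alpha", 0.02)), beta=float(d.get("beta", 0.02)),
    )
    kind = d.get("kind", "constant")
    if kind == "constant":
        env = EnvironmentSpec.constant(float(d["B"]))
    elif kind == "sinusoidal":
        env = EnvironmentSpec.sinusoidal(
            B0=float(d.get("B0", d["B"])), epsilon=float(d["epsilon"]),
            omega=float(d["omega"]), phase=d.get("phase"),
        )
    elif kind in ("SDMN", "square") and "nu" in d:
        ctor = EnvironmentSpec.sdmn if kind == "SDMN" else EnvironmentSpec.square
        env = ctor(float(d["B_plus"]), float(d["B_minus"]), float(d["nu"]))
    elif kind in ("ADMN", "rectangular") and "gamma" in d:
        env = EnvironmentSpec.from_duty_cycle(
            float(d["B_plus"]), float(d["B_minus"]), float(d["nu"]),
            float(d["gamma"]), kind=kind,
        )
    elif kind in ("SDMN", "ADMN", "square", "rectangular"):
        env = EnvironmentSpec(
            kind=kind, B_plus=float(d["B_plus"]), B_minus=float(d["B_minus"]),
            nu_plus=float(d["nu_plus"]), nu_minus=float(d["nu_minus"]),
            phase=d.get("phase"),
        )
    else:
        raise ValueError(f"unknown environment kind {kind!r}")
    n0 = int(d.get("n0", default_initial_counts(params.K)[0]))
    m0 = int(d.get("m0", default_initial_counts(params.K)[1]))
    t_max = d.get("t_max")
    return RunConfig(
        params=params, env=env, method=str(d.get("method", "auto")),
        n_traj=int(d.get("n_traj", 2400)), seed=int(d.get("seed", 0)),
        t_max=float(t_max) if t_max is not None else None,
        init=(n0, m0), out=d.get("out"),
    )


def _provenance_lines(cfg_hash: str, seeds, version: str) -> list[str]:
    seeds = list(np.asarray(seeds).ravel()[:16])
    return [
        f"# config_hash: {cfg_hash}",
        f"# seeds: {seeds}",
        f"# persistext_version: {version}",
    ]


def write_results(
    tables: dict[str, "pd.DataFrame"],  # noqa: F821
    summaries: dict[str, dict],
    out_dir,
    cfg_hash: str = "",
    seeds=(),
) -> list[Path]:
    """Write tables as commented CSV and summaries as JSON.

    Every file carries the config hash, seed list, and package version in a
    '#'-comment header (CSV) or a ``provenance`` field (JSON).
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    header = _provenance_lines(cfg_hash, seeds, __version__)
    for name, df in tables.items():
        path = out_dir / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write("\n".join(header) + "\n")
            df.to_csv(fh, index=False)
        written.append(path)
    for name, summary in summaries.items():
        path = out_dir / f"{name}.json"
        payload = dict(summary)
        payload["provenance"] = {
            "config_hash": cfg_hash,
            "seeds": [int(s) for s in np.asarray(seeds).ravel()[:16]],
            "version": __version__,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=_json_default)
        written.append(path)
    return written


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, float) and math.isnan(o):
        return None
    raise TypeError(f"not JSON serializable: {type(o)}")
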