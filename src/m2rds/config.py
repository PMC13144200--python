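"""Flat TOML run configuration for the command-line drivers.

Unknown keys are rejected; missing keys take the documented defaults; the
resolved configuration is echoed into every metrics sidecar so runs are
reproducible from their outputs alone.
"""

from __future__ import annotations

import dataclasses
import math
import tomllib
from dataclasses import dataclass

from .rds_m2 import DiagMetricParams, RDSParams, stable_timestep

__all__ = ["RunConfig", "load_config"]

_DEFAULTS = {
    "n_orientations": 32,
    "wavelet_size": 33,
    "xi": 0.1,
    "zeta_D": 1.0,
    "zeta_M": 1.0,
    "lam": 1.0,
    "nu_reg": 1.0,
    "sigma_reg": 1.0,
    "rho_reg": 1.0,
    "theta_reg": 0.0,
    "epsilon_S": 0.0,   # 0 means automatic (1% of the score dynamic range)
    "tau": 0.0,         # 0 means automatic (0.9x the stability bound)
    "T": 1.0,
    "frame": "invariant",
    "seed": 0,
}


@dataclass(frozen=True)
class RunConfig:
    n_orientations: int
    wavelet_size: int
    xi: float
    zeta_D: float
    zeta_M: float
    lam: float
    nu_reg: float
    sigma_reg: float
    rho_reg: float
    theta_reg: float
    epsilon_S: float
    tau: float
    T: float
    frame: str
    seed: int

    def rds_params(self) -> RDSParams:
        return RDSParams(
            metric_D=DiagMetricParams(self.xi, self.zeta_D),
            metric_M=DiagMetricParams(self.xi, self.zeta_M),
            metric_g=DiagMetricParams(self.xi, 1.0),
            metric_S=DiagMetricParams(self.xi, 1.0),
            lam=self.lam,
            nu_reg=self.nu_reg,
            sigma_reg=self.sigma_reg,
            rho_reg=self.rho_reg,
            theta_reg=self.theta_reg,
            epsilon_S=self.epsilon_S or None,
            tau=self.tau or None,
            T=self.T,
            frame_mode=self.frame,
        )

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Parse a flat TOML config; CLI ``overrides`` take precedence over file
    values, which take precedence over defaults."""
    values = dict(_DEFAULTS)
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        unknown = set(data) - set(_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values.update(data)
    if overrides:
        values.update({k: v for k, v in overrides.items() if v is not None})
    cfg = RunConfig(**values)
    _validate(cfg)
    return cfg


def _validate(cfg: RunConfig) -> None:
    if cfg.n_orientations < 4:
        raise ValueError("n_orientations must be at least 4")
    if cfg.xi <= 0 or cfg.zeta_D <= 0 or cfg.zeta_M <= 0:
        raise ValueError("xi and zeta values must be positive (zeta = 0 is degenerate)")
    if cfg.frame not in ("invariant", "gauge"):
        raise ValueError("frame must be 'invariant' or 'gauge'")
    if cfg.tau:
        dtheta = 2 * math.pi / cfg.n_orientations
        bound = stable_timestep(
            DiagMetricParams(cfg.xi, cfg.zeta_D),
            DiagMetricParams(cfg.xi, cfg.zeta_M),
            DiagMetricParams(cfg.xi, 1.0),
            1.0,
            dtheta,
        )
        if cfg.tau > bound:
            raise ValueError(
                f"tau = {cfg.tau} exceeds the explicit-scheme stability bound "
                f"min(tau_D, tau_S) = {bound:.6g}; the max-min principle would be lost"
            )
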