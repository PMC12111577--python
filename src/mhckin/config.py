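"""Flat YAML/JSON run configuration with strict schema validation.

A configuration file is a single flat mapping.  Every key is optional;
missing keys fall back to the reference defaults of
:func:`mhckin.synthetic.default_parameters`.  Unknown keys are rejected by
name so typos cannot silently change a run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

from .estimation import GridSpec
from .kinetics import HeatingParameters, KineticParameters
from .synthetic import NoiseModel, SamplingDesign, default_parameters

__all__ = ["ConfigError", "RunConfig", "load_config", "save_config", "config_digest"]


class ConfigError(ValueError):
    """Configuration file violates the schema."""


_PARAM_KEYS = ("k1", "k2", "T1", "d", "T_opt", "beta")
_HEAT_KEYS = ("alpha", "T_max", "T_init")
_DESIGN_KEYS = ("times", "replicates")
_NOISE_KEYS = ("noise_kind", "noise_sd", "truncate_at_zero", "renormalize")
_GRID_KEYS = (
    "k1_bounds",
    "k1_step",
    "k2_bounds",
    "k2_step",
    "beta_bounds",
    "beta_step",
    "refinement_levels",
    "shrink_factor",
)
_OTHER_KEYS = ("seed", "outdir")
ALLOWED_KEYS = frozenset(
    _PARAM_KEYS + _HEAT_KEYS + _DESIGN_KEYS + _NOISE_KEYS + _GRID_KEYS + _OTHER_KEYS
)


@dataclass(frozen=True)
class RunConfig:
    """Validated bundle of everything a pipeline run needs."""

    kinetics: KineticParameters
    heating: HeatingParameters
    design: SamplingDesign
    noise: NoiseModel
    grid: GridSpec
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "RunConfig":
        unknown = sorted(set(data) - ALLOWED_KEYS)
        if unknown:
            raise ConfigError(f"unknown configuration key: {unknown[0]!r}")
        k0, h0, design0 = default_parameters()
        try:
            kin = KineticParameters(
                **{key: float(data.get(key, getattr(k0, key))) for key in _PARAM_KEYS}
            )
            heat = HeatingParameters(
                **{key: float(data.get(key, getattr(h0, key))) for key in _HEAT_KEYS}
            )
            design = SamplingDesign(
                times=tuple(data.get("times", design0.times)),
                replicates=int(data.get("replicates", design0.replicates)),
            )
            noise0 = NoiseModel()
            noise = NoiseModel(
                kind=data.get("noise_kind", noise0.kind),
                sd=float(data.get("noise_sd", noise0.sd)),
                truncate_at_zero=bool(data.get("truncate_at_zero", noise0.truncate_at_zero)),
                renormalize=bool(data.get("renormalize", noise0.renormalize)),
            )
            grid0 = GridSpec()
            grid = GridSpec(
                k1_bounds=tuple(data.get("k1_bounds", grid0.k1_bounds)),
                k1_step=float(data.get("k1_step", grid0.k1_step)),
                k2_bounds=tuple(data.get("k2_bounds", grid0.k2_bounds)),
                k2_step=float(data.get("k2_step", grid0.k2_step)),
                beta_bounds=tuple(data.get("beta_bounds", grid0.beta_bounds)),
                beta_step=float(data.get("beta_step", grid0.beta_step)),
                refinement_levels=int(
                    data.get("refinement_levels", grid0.refinement_levels)
                ),
                shrink_factor=float(data.get("shrink_factor", grid0.shrink_factor)),
            )
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
        outdir = data.get("outdir")
        return cls(
            kinetics=kin,
            heating=heat,
            design=design,
            noise=noise,
            grid=grid,
            seed=int(data.get("seed", 0)),
            outdir=str(outdir) if outdir is not None else None,
        )

    def to_mapping(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for key in _PARAM_KEYS:
            out[key] = getattr(self.kinetics, key)
        for key in _HEAT_KEYS:
            out[key] = getattr(self.heating, key)
        out["times"] = list(self.design.times)
        out["replicates"] = self.design.replicates
        out["noise_kind"] = self.noise.kind
        out["noise_sd"] = self.noise.sd
        out["truncate_at_zero"] = self.noise.truncate_at_zero
        out["renormalize"] = self.noise.renormalize
        for key in _GRID_KEYS:
            value = getattr(self.grid, key)
            out[key] = list(value) if isinstance(value, tuple) else value
        out["seed"] = self.seed
        if self.outdir is not None:
            out["outdir"] = self.outdir
        return out


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML (or JSON) run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    data = yaml.safe_load(path.read_text())
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ConfigError("configuration must be a flat mapping")
    return RunConfig.from_mapping(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_mapping(), sort_keys=True))


def config_digest(cfg: RunConfig) -> str:
    """Short stable hash of the configuration, for provenance headers."""
    payload = json.dumps(cfg.to_mapping(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
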