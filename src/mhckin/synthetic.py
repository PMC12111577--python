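"""Seedable generators for synthetic densitometry and calibration data.

The generators emulate the numeric outputs of the wet-lab workflow the model
is fitted to — normalized SDS-PAGE band-intensity time courses for the
reduced and non-reduced channels, a thermal denaturation curve for the
unfolding sigmoid, and a logged core-temperature heating curve — so that
every estimation stage can be exercised and validated without laboratory
data.  They emulate band-intensity *tables* only: gel-image artifacts
(smearing, background, saturation) are out of scope.

Every generator is a pure function of its parameters and an integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .estimation import DenaturationCurve, NormalizationError, ObservationSet
from .kinetics import (
    DEFAULT_DT,
    HeatingParameters,
    KineticParameters,
    _integrate_channels,
    polymerization_rate_factor,
    temperature_at,
)

__all__ = [
    "NoiseModel",
    "SamplingDesign",
    "TemperatureLog",
    "default_parameters",
    "make_observations",
    "make_denaturation_curve",
    "make_temperature_log",
]

#: Heating durations (min) of the time-course sampling design.
DEFAULT_SAMPLING_TIMES = (2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0, 18.0, 20.0, 30.0, 40.0, 60.0)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description for generated intensities.

    Additive Gaussian noise on the normalized intensity scale is the
    default emulation of densitometry replicate scatter (sd = 0.05 unless
    stated otherwise by the caller).  ``truncate_at_zero`` clips negative
    draws; ``renormalize`` re-applies the t = 0 normalization after noise,
    restoring an exact reference of 1.
    """

    kind: Literal["none", "additive_gaussian"] = "additive_gaussian"
    sd: float = 0.05
    truncate_at_zero: bool = True
    renormalize: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("none", "additive_gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass(frozen=True)
class SamplingDesign:
    """Sampling times (min, strictly increasing, > 0) and replicate count."""

    times: tuple[float, ...] = DEFAULT_SAMPLING_TIMES
    replicates: int = 3

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        if t.size == 0 or np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be positive and strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        object.__setattr__(self, "times", tuple(float(x) for x in t))


@dataclass(frozen=True)
class TemperatureLog:
    """Logged core-temperature series (times in min, temperatures in °C)."""

    times: np.ndarray
    temperatures: np.ndarray


def default_parameters() -> tuple[KineticParameters, HeatingParameters, SamplingDesign]:
    """Reference parameter set for golden threadfin bream surimi at 60 °C.

    Rate constants estimated from reduced/non-reduced band-intensity time
    courses (k1 = 0.044/min, k2 = 0.053/min, beta = 0.214 °C), sigmoid
    unfolding parameters from thermal denaturation of MHC (T1 = 29.61 °C,
    d = 22.34), degradation optimum 60 °C, and first-order heating with
    alpha = 0.3/min toward a 60 °C bath from ice temperature.
    """
    k = KineticParameters(k1=0.044, k2=0.053, T1=29.61, d=22.34, T_opt=60.0, beta=0.214)
    h = HeatingParameters(alpha=0.3, T_max=60.0, T_init=0.0)
    return k, h, SamplingDesign()


def _apply_noise(curve: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    if noise.kind == "none":
        return curve.copy()
    out = curve + rng.normal(0.0, noise.sd, size=curve.shape)
    if noise.truncate_at_zero:
        out = np.clip(out, 0.0, None)
    if noise.renormalize:
        if out[0] <= 0:
            raise NormalizationError("noisy t=0 reference is not positive")
        out = out / out[0]
    return out


def make_observations(
    k: KineticParameters,
    h: HeatingParameters,
    design: SamplingDesign,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    dt: float = DEFAULT_DT,
) -> ObservationSet:
    """Simulate both channels at the design times and add replicate noise.

    The t = 0 point (value 1 by normalization) is included in the output
    grid.  Per replicate, noise is drawn first for the reduced then for the
    non-reduced channel; the draw order is fixed so results are
    bit-reproducible for a given seed.
    """
    times = np.concatenate(([0.0], np.asarray(design.times, float)))
    X, XP = _integrate_channels(k.k1, k.k2, k.beta, k.T1, k.d, k.T_opt, h, times, dt)
    rng = np.random.default_rng(seed)
    red = np.empty((design.replicates, times.size))
    non = np.empty((design.replicates, times.size))
    for r in range(design.replicates):
        red[r] = _apply_noise(XP, noise, rng)
        non[r] = _apply_noise(X, noise, rng)
    ids = tuple(f"rep{r + 1}" for r in range(design.replicates))
    return ObservationSet(times=times, reduced=red, non_reduced=non, replicate_id=ids)


def make_denaturation_curve(
    T1: float,
    d: float,
    T_lo: float = 10.0,
    T_hi: float = 60.0,
    step: float = 1.0,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> DenaturationCurve:
    """Sigmoid denatured-fraction curve on a regular temperature grid.

    Optional additive Gaussian noise is clipped to [0, 1] (fractions cannot
    leave the unit interval).  A grid that does not span T1 leaves the
    midpoint unconstrained; a warning is emitted rather than an error.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if not T_lo < T1 < T_hi:
        warnings.warn(
            f"temperature range [{T_lo}, {T_hi}] does not span T1={T1}; "
            "the sigmoid midpoint is poorly constrained",
            stacklevel=2,
        )
    T = np.arange(T_lo, T_hi + step / 2, step, dtype=float)
    y = np.asarray(polymerization_rate_factor(T, T1, d), float)
    if noise is not None and noise.kind != "none":
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise.sd, size=y.shape)
    return DenaturationCurve(temperatures=T, denatured_fraction=np.clip(y, 0.0, 1.0))


def make_temperature_log(
    h: HeatingParameters,
    times: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TemperatureLog:
    """Closed-form heating curve at given times plus optional Gaussian noise."""
    t = np.asarray(times, float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    temps = np.asarray(temperature_at(t, h), float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        temps = temps + rng.normal(0.0, noise_sd, size=temps.shape)
    return TemperatureLog(times=t, temperatures=temps)
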