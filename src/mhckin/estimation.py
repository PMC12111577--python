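"""Parameter estimation for the MHC polymerization/degradation model.

Three fitting problems arise in practice:

1. The rate constants ``(k1, k2, beta)`` are estimated from normalized
   band-intensity time courses of both electrophoresis channels by a
   multi-resolution grid search minimizing the residual sum of squares
   (RSS), with the unfolding-sigmoid parameters and the degradation optimum
   held fixed.
2. The sigmoid parameters ``(T1, d)`` are estimated from a thermal
   denaturation curve (temperature vs. denatured fraction) by damped least
   squares with multi-start over the steepness.
3. The heating rate ``alpha`` is estimated from a logged core-temperature
   time series with the bath temperature fixed.

Grid search is deliberately simple and derivative-free: the RSS surface is
cheap to evaluate in batch (the model is linear in (X, P) given the
temperature program, so thousands of parameter triples integrate in one
vectorized pass) and the search is fully deterministic, with ties broken
toward the lexicographically smallest (k1, k2, beta).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .kinetics import (
    DEFAULT_DT,
    HeatingParameters,
    KineticParameters,
    _integrate_channels,
    polymerization_rate_factor,
)

__all__ = [
    "FitError",
    "NormalizationError",
    "ObservationSet",
    "GridSpec",
    "FitResult",
    "DenaturationCurve",
    "RecoveryResult",
    "normalize_series",
    "residual_sum_squares",
    "grid_search_fit",
    "fit_sigmoid",
    "fit_heating",
    "recovery_experiment",
]


class FitError(RuntimeError):
    """A fit could not be carried out or produced no finite objective."""


class NormalizationError(ValueError):
    """Raised when a series cannot be normalized to its t = 0 reference."""


@dataclass(frozen=True)
class ObservationSet:
    """Normalized band intensities for both channels on one time grid.

    ``reduced`` and ``non_reduced`` are arrays of shape
    (n_replicates, n_times); one-dimensional input is treated as a single
    replicate.  Intensities are normalized so the t = 0 reference is 1.
    """

    times: np.ndarray
    reduced: np.ndarray
    non_reduced: np.ndarray
    replicate_id: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, float)
        red = np.atleast_2d(np.asarray(self.reduced, float))
        non = np.atleast_2d(np.asarray(self.non_reduced, float))
        if times.ndim != 1 or np.any(np.diff(times) <= 0) or np.any(times < 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if red.shape != non.shape or red.shape[1] != times.size:
            raise ValueError(
                "both channels must share the shape (n_replicates, n_times)"
            )
        if np.any(red < 0) or np.any(non < 0):
            raise ValueError("intensities must be >= 0")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "reduced", red)
        object.__setattr__(self, "non_reduced", non)

    @property
    def n_replicates(self) -> int:
        return self.reduced.shape[0]


@dataclass(frozen=True)
class DenaturationCurve:
    """Thermal denaturation data: temperature (°C) vs denatured fraction."""

    temperatures: np.ndarray
    denatured_fraction: np.ndarray

    def __post_init__(self) -> None:
        T = np.asarray(self.temperatures, float)
        y = np.asarray(self.denatured_fraction, float)
        if T.ndim != 1 or y.shape != T.shape:
            raise ValueError("temperatures and fractions must be matching 1-D arrays")
        if np.any(np.diff(T) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.any((y < 0) | (y > 1)):
            raise ValueError("denatured fractions must lie in [0, 1]")
        object.__setattr__(self, "temperatures", T)
        object.__setattr__(self, "denatured_fraction", y)


@dataclass(frozen=True)
class GridSpec:
    """Coarse-to-fine search grid over (k1, k2, beta).

    Each refinement level re-centres the grid on the current best point and
    contracts every axis range by ``shrink_factor`` (clipped to the original
    bounds), keeping the number of points per axis constant.  With the
    defaults the final effective resolution is <= 0.001 on every axis
    (k1/k2: 0.01·0.2³ = 8e-5; beta: 0.0995·0.2³ ≈ 8e-4).
    """

    k1_bounds: tuple[float, float] = (0.0, 0.2)
    k1_step: float = 0.01
    k2_bounds: tuple[float, float] = (0.0, 0.2)
    k2_step: float = 0.01
    beta_bounds: tuple[float, float] = (0.01, 2.0)
    beta_step: float = 0.0995
    refinement_levels: int = 4
    shrink_factor: float = 0.2

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "beta"):
            lo, hi = getattr(self, f"{name}_bounds")
            step = getattr(self, f"{name}_step")
            if lo > hi:
                raise ValueError(f"{name}_bounds must satisfy lower <= upper")
            if step <= 0:
                raise ValueError(f"{name}_step must be > 0")
        if self.refinement_levels < 1:
            raise ValueError("refinement_levels must be >= 1")
        if not 0 < self.shrink_factor < 1:
            raise ValueError("shrink_factor must lie in (0, 1)")

    def _n_points(self, name: str) -> int:
        lo, hi = getattr(self, f"{name}_bounds")
        step = getattr(self, f"{name}_step")
        return max(1, int(round((hi - lo) / step))) + 1 if hi > lo else 1

    def final_resolution(self, name: str) -> float:
        """Effective step of the last refinement level for one axis."""
        return getattr(self, f"{name}_step") * self.shrink_factor ** (
            self.refinement_levels - 1
        )


@dataclass(frozen=True)
class FitResult:
    """Outcome of a grid search: best parameters, RSS and provenance."""

    best: KineticParameters
    rss: float
    evaluations: int
    history: tuple[dict, ...] = field(default_factory=tuple)


def normalize_series(raw: Sequence[float]) -> np.ndarray:
    """Normalize a raw intensity series to its first (t = 0) value."""
    raw = np.asarray(raw, float)
    if raw.size == 0:
        raise NormalizationError("cannot normalize an empty series")
    if raw[0] <= 0:
        raise NormalizationError(
            f"t=0 reference must be > 0, got {raw[0]}"
        )
    return raw / raw[0]


def residual_sum_squares(
    k: KineticParameters,
    h: HeatingParameters,
    obs: ObservationSet,
    dt: float = DEFAULT_DT,
) -> float:
    """RSS between the model and both channels at the observation times.

    Every point carries equal weight; replicates enter individually.
    """
    X, XP = _integrate_channels(
        k.k1, k.k2, k.beta, k.T1, k.d, k.T_opt, h, obs.times, dt
    )
    return float(
        np.sum((XP - obs.reduced) ** 2) + np.sum((X - obs.non_reduced) ** 2)
    )


def _axis(lo: float, hi: float, n: int) -> np.ndarray:
    return np.linspace(lo, hi, n) if hi > lo else np.array([lo])


def grid_search_fit(
    obs: ObservationSet,
    grid: GridSpec,
    h: HeatingParameters,
    fixed: Mapping[str, float],
    dt: float = DEFAULT_DT,
) -> FitResult:
    """Fit (k1, k2, beta) by coarse-to-fine grid search on the joint RSS.

    ``fixed`` must supply ``T1``, ``d`` and ``T_opt``, which are held
    constant during the search (they are identified from independent
    denaturation and protease-activity data, not from the time courses).
    Deterministic: identical inputs yield identical results; exact RSS ties
    resolve to the lexicographically smallest (k1, k2, beta).
    """
    for key in ("T1", "d", "T_opt"):
        if key not in fixed:
            raise ValueError(f"fixed parameters must include {key!r}")
    T1, d, T_opt = float(fixed["T1"]), float(fixed["d"]), float(fixed["T_opt"])

    bounds = {
        "k1": tuple(grid.k1_bounds),
        "k2": tuple(grid.k2_bounds),
        "beta": tuple(grid.beta_bounds),
    }
    spans = {name: bounds[name] for name in ("k1", "k2", "beta")}
    n_pts = {name: grid._n_points(name) for name in ("k1", "k2", "beta")}

    evaluations = 0
    history: list[dict] = []
    best = None
    best_rss = math.inf
    for level in range(1, grid.refinement_levels + 1):
        ax = {name: _axis(*spans[name], n_pts[name]) for name in spans}
        k1g = ax["k1"][:, None, None]
        k2g = ax["k2"][None, :, None]
        bg = ax["beta"][None, None, :]
        X, XP = _integrate_channels(k1g, k2g, bg, T1, d, T_opt, h, obs.times, dt)
        rss = (
            (XP[..., None, :] - obs.reduced) ** 2
            + (X[..., None, :] - obs.non_reduced) ** 2
        ).sum(axis=(-1, -2))
        evaluations += rss.size
        if not np.isfinite(rss).any():
            raise FitError("residual sum of squares is non-finite on the whole grid")
        # argmin on C-ordered (k1, k2, beta) axes == lexicographic tie-break
        i, j, m = np.unravel_index(int(np.argmin(rss)), rss.shape)
        best = (float(ax["k1"][i]), float(ax["k2"][j]), float(ax["beta"][m]))
        best_rss = float(rss[i, j, m])
        history.append(
            {
                "level": level,
                "best": {"k1": best[0], "k2": best[1], "beta": best[2]},
                "rss": best_rss,
                "bounds": {name: spans[name] for name in spans},
            }
        )
        if level < grid.refinement_levels:
            for idx, name in enumerate(("k1", "k2", "beta")):
                lo, hi = spans[name]
                half = grid.shrink_factor * (hi - lo) / 2.0
                c = best[idx]
                spans[name] = (
                    max(bounds[name][0], c - half),
                    min(bounds[name][1], c + half),
                )
    params = KineticParameters(
        k1=best[0], k2=best[1], T1=T1, d=d, T_opt=T_opt, beta=best[2]
    )
    return FitResult(
        best=params, rss=best_rss, evaluations=evaluations, history=tuple(history)
    )


def fit_sigmoid(curve: DenaturationCurve) -> tuple[float, float]:
    """Estimate (T1, d) of the unfolding sigmoid from a denaturation curve.

    Damped least squares (trust-region reflective) with multi-start over
    five log-spaced initial steepness values; steep sigmoids have narrow
    basins of attraction in ``d`` and a single start is unreliable.
    """
    T = curve.temperatures
    y = curve.denatured_fraction
    if T.size < 3:
        raise FitError("sigmoid fit needs at least 3 points")
    if np.ptp(y) == 0:
        raise FitError("sigmoid fit needs non-constant denatured fractions")
    if y.max() <= 0.5 or y.min() >= 0.5:
        raise FitError("denaturation curve must span the 0.5 level")

    T1_0 = float(T[int(np.argmin(np.abs(y - 0.5)))])

    def resid(p):
        return polymerization_rate_factor(T, p[0], p[1]) - y

    best = None
    for d0 in np.logspace(0, 2, 5):
        try:
            res = least_squares(
                resid,
                x0=[T1_0, d0],
                bounds=([1e-6, 1e-6], [np.inf, np.inf]),
                method="trf",
            )
        except Exception:  # singular start; other starts cover it
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.isfinite(best.cost):
        raise FitError("sigmoid fit failed from every start")
    return float(best.x[0]), float(best.x[1])


def fit_heating(
    times: Sequence[float], temperatures: Sequence[float], T_max: float
) -> float:
    """Estimate the heating rate alpha from a core-temperature log.

    The first logged point anchors the initial temperature; the model is
    ``T(t) = T_max - (T_max - T(t0)) exp(-alpha (t - t0))`` with ``T_max``
    (the bath temperature) fixed.
    """
    t = np.asarray(times, float)
    y = np.asarray(temperatures, float)
    if t.size < 2 or y.shape != t.shape:
        raise FitError("heating fit needs at least 2 (time, temperature) points")
    t0, T_init = float(t[0]), float(y[0])
    gap0 = T_max - T_init
    if gap0 <= 0 or np.all(np.isclose(y, T_max)):
        raise FitError("log is saturated at T_max; alpha is unidentifiable")

    # initial guess by algebraic inversion at the most informative point
    rel = (T_max - y[1:]) / gap0
    usable = np.flatnonzero((rel > 1e-12) & (rel < 1))
    if usable.size:
        m = usable[usable.size // 2] + 1
        alpha0 = -math.log(rel[m - 1]) / (t[m] - t0)
    else:
        alpha0 = 0.1

    def resid(p):
        return T_max - gap0 * np.exp(-p[0] * (t - t0)) - y

    res = least_squares(resid, x0=[alpha0], bounds=([1e-9], [np.inf]), method="trf")
    if not np.isfinite(res.cost):
        raise FitError("heating fit failed")
    return float(res.x[0])


@dataclass(frozen=True)
class RecoveryResult:
    """Parameter-recovery summary over synthetic replicated experiments."""

    estimates: pd.DataFrame  # one row per replicate, columns k1/k2/beta
    summary: pd.DataFrame  # rows k1/k2/beta, columns true/mean/bias/rmse


def recovery_experiment(
    true_k: KineticParameters,
    h: HeatingParameters,
    noise_sd: float,
    reps: int,
    seed: int,
    design=None,
    grid: GridSpec | None = None,
    dt: float = DEFAULT_DT,
) -> RecoveryResult:
    """Generate-fit round trips quantifying estimator bias and RMSE.

    For each replicate experiment a fresh synthetic observation set is drawn
    (additive Gaussian noise of standard deviation ``noise_sd`` on the
    normalized intensities, renormalized to the t = 0 anchor), the grid
    search is run, and the recovered (k1, k2, beta) recorded.  Bias is the
    mean estimate minus truth; RMSE the root-mean-square deviation.  Fully
    reproducible: replicate seeds derive from ``seed``.
    """
    from .synthetic import NoiseModel, SamplingDesign, make_observations

    if reps < 1:
        raise ValueError("reps must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if design is None:
        design = SamplingDesign()
    if grid is None:
        grid = GridSpec()
    noise = NoiseModel(
        kind="none" if noise_sd == 0 else "additive_gaussian", sd=noise_sd
    )
    fixed = {"T1": true_k.T1, "d": true_k.d, "T_opt": true_k.T_opt}

    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=reps)
    rows = []
    for r, child in enumerate(child_seeds):
        try:
            obs = make_observations(true_k, h, design, noise, seed=int(child))
            fit = grid_search_fit(obs, grid, h, fixed, dt=dt)
        except (FitError, ValueError) as exc:
            raise FitError(f"replicate {r}: {exc}") from exc
        rows.append(
            {"replicate": r, "k1": fit.best.k1, "k2": fit.best.k2, "beta": fit.best.beta}
        )
    estimates = pd.DataFrame(rows).set_index("replicate")
    truth = {"k1": true_k.k1, "k2": true_k.k2, "beta": true_k.beta}
    summary = pd.DataFrame(
        {
            "true": truth,
            "mean": estimates.mean(),
            "bias": estimates.mean() - pd.Series(truth),
            "rmse": np.sqrt(((estimates - pd.Series(truth)) ** 2).mean()),
        }
    )
    return RecoveryResult(estimates=estimates, summary=summary)
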