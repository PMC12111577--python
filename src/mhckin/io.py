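"""File formats: trajectory CSV, long-format observation CSV, result JSON.

All outputs carry '#'-prefixed provenance comment lines (package version,
seed, configuration hash); readers skip comment lines.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .estimation import FitResult, ObservationSet
from .kinetics import Trajectory

__all__ = [
    "provenance_lines",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_observations_csv",
    "read_observations_csv",
    "write_fit_json",
    "write_json",
]


def provenance_lines(meta: Mapping[str, Any] | None = None) -> list[str]:
    lines = [f"# mhckin {__version__}"]
    for key, value in (meta or {}).items():
        lines.append(f"# {key}: {value}")
    return lines


def _write_frame(frame: pd.DataFrame, path: Path, meta: Mapping[str, Any] | None) -> None:
    with open(path, "w", newline="") as fh:
        for line in provenance_lines(meta):
            fh.write(line + "\n")
        frame.to_csv(fh, index=False)


def write_trajectory_csv(
    traj: Trajectory, path: str | Path, meta: Mapping[str, Any] | None = None
) -> None:
    """Columns: time_min, X, P, T, reduced, non_reduced."""
    _write_frame(traj.to_frame(), Path(path), meta)


def read_trajectory_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_observations_csv(
    obs: ObservationSet, path: str | Path, meta: Mapping[str, Any] | None = None
) -> None:
    """Long format: time_min, channel, replicate, intensity."""
    ids = obs.replicate_id or tuple(
        f"rep{r + 1}" for r in range(obs.n_replicates)
    )
    rows = []
    for channel, values in (("reduced", obs.reduced), ("non_reduced", obs.non_reduced)):
        for r in range(obs.n_replicates):
            for t, v in zip(obs.times, values[r]):
                rows.append(
                    {"time_min": t, "channel": channel, "replicate": ids[r], "intensity": v}
                )
    _write_frame(pd.DataFrame(rows), Path(path), meta)


def read_observations_csv(path: str | Path) -> ObservationSet:
    frame = pd.read_csv(path, comment="#")
    required = {"time_min", "channel", "replicate", "intensity"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"observation CSV lacks columns: {sorted(missing)}")
    ids = tuple(pd.unique(frame["replicate"]))
    times = np.sort(pd.unique(frame["time_min"]))
    channels = {}
    for channel in ("reduced", "non_reduced"):
        sub = frame[frame["channel"] == channel]
        wide = sub.pivot(index="replicate", columns="time_min", values="intensity")
        wide = wide.loc[list(ids), times]
        channels[channel] = wide.to_numpy()
    return ObservationSet(
        times=times,
        reduced=channels["reduced"],
        non_reduced=channels["non_reduced"],
        replicate_id=tuple(str(i) for i in ids),
    )


def write_json(
    payload: Mapping[str, Any], path: str | Path, meta: Mapping[str, Any] | None = None
) -> None:
    out = dict(payload)
    out["_provenance"] = {"package": f"mhckin {__version__}", **(meta or {})}
    Path(path).write_text(json.dumps(out, indent=2, sort_keys=True) + "\n")


def write_fit_json(
    fit: FitResult, path: str | Path, meta: Mapping[str, Any] | None = None
) -> None:
    best = fit.best
    payload = {
        "best": {
            "k1": best.k1,
            "k2": best.k2,
            "beta": best.beta,
            "T1": best.T1,
            "d": best.d,
            "T_opt": best.T_opt,
        },
        "rss": fit.rss,
        "evaluations": fit.evaluations,
        "history": list(fit.history),
    }
    write_json(payload, path, meta)
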