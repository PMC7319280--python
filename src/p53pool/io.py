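"""File formats: trajectory CSV, parameter/pool/means JSON, config YAML."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .clustering import PeakBasedMean
from .parameters import ModelParameters
from .pool import ModelPool
from .trajectories import Trajectory

__all__ = [
    "load_trajectories",
    "save_trajectories",
    "load_parameters",
    "save_parameters",
    "load_pool",
    "save_pool",
    "load_peak_based_means",
    "save_peak_based_means",
    "load_config",
    "save_config",
]

TRAJECTORY_COLUMNS = ("cell_id", "time_h", "intensity")


def load_trajectories(path: str | Path) -> list[Trajectory]:
    """Read a long-format trajectory table (``cell_id,time_h,intensity``).

    Validates monotone, duplicate-free time stamps per cell; rows are
    grouped per cell and sorted by time.
    """
    df = pd.read_csv(path)
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df[list(TRAJECTORY_COLUMNS)].isna().any().any():
        bad = int(df[df[list(TRAJECTORY_COLUMNS)].isna().any(axis=1)].index[0])
        raise ValueError(f"{path}: malformed row {bad}")
    out = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("time_h")
        times = grp["time_h"].to_numpy(dtype=float)
        if np.unique(times).size != times.size:
            dup = times[np.argmax(np.diff(times) == 0)]
            raise ValueError(f"{path}: duplicated time {dup} for cell {cell_id}")
        out.append(Trajectory(str(cell_id), times, grp["intensity"].to_numpy(dtype=float)))
    return out


def save_trajectories(trajectories: Sequence[Trajectory], path: str | Path) -> None:
    frames = [
        pd.DataFrame({"cell_id": t.cell_id, "time_h": t.times, "intensity": t.values})
        for t in trajectories
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    Path(path).write_text(json.dumps(params.as_dict(), indent=2))


def load_parameters(path: str | Path) -> ModelParameters:
    return ModelParameters.from_dict(json.loads(Path(path).read_text()))


def save_pool(pool: ModelPool, path: str | Path) -> None:
    Path(path).write_text(json.dumps(pool.to_dict(), indent=2))


def load_pool(path: str | Path) -> ModelPool:
    return ModelPool.from_dict(json.loads(Path(path).read_text()))


def save_peak_based_means(means: Sequence[PeakBasedMean], path: str | Path) -> None:
    Path(path).write_text(json.dumps([m.to_dict() for m in means], indent=2))


def load_peak_based_means(path: str | Path) -> list[PeakBasedMean]:
    return [PeakBasedMean.from_dict(d) for d in json.loads(Path(path).read_text())]


def save_config(config: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))


def load_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
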