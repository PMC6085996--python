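"""File formats: lap-event TSV, trajectory CSV, fit-summary JSON, YAML
config.  All text, UTF-8, '.' decimal separator; floats are written at
full (round-tripping) precision so write -> read is bit-exact."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .metrics import Trajectory

__all__ = [
    "write_laps_tsv",
    "read_laps_tsv",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_json",
    "read_json",
    "load_config",
]

_LAP_DTYPES = {
    "rat_id": "int64",
    "session_id": "string",
    "lap": "int64",
    "choice1": "string",
    "context": "string",
    "transition": "string",
    "choice2": "string",
    "end_state": "string",
    "delay_s": "float64",
    "reward": "float64",
}


def write_laps_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_laps_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col, dt in _LAP_DTYPES.items():
        if col in df.columns:
            df[col] = df[col].astype(dt)
    for col in ("session_id", "choice1", "context", "transition", "choice2", "end_state"):
        if col in df.columns:
            df[col] = df[col].astype(object)
    return df


def write_trajectory_csv(traj: Trajectory, path) -> None:
    pd.DataFrame(
        {
            "t_s": traj.t,
            "body_x": traj.body[:, 0],
            "body_y": traj.body[:, 1],
            "head_x": traj.head[:, 0],
            "head_y": traj.head[:, 1],
        }
    ).to_csv(path, index=False)


def read_trajectory_csv(path) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(
        df["t_s"].to_numpy(),
        df[["body_x", "body_y"]].to_numpy(),
        df[["head_x", "head_y"]].to_numpy(),
    )


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=default)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return cfg
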