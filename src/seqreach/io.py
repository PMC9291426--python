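"""Delimited-text trajectory files and tidy result tables.

The shared trajectory schema is a UTF-8 CSV with a mandatory header and
one row per sample:

    participant_id, group, day, trial, t_s, x_cm, y_cm

rows sorted by (participant_id, day, trial, t_s) with t_s strictly
increasing within a trial.  The synthetic generator writes the same
schema plus a ground-truth sidecar table (participant, trial, true_mt,
true_fusion, corrected, group).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .kinematics import Trajectory

__all__ = ["read_trajectories", "write_trajectories", "write_truth", "read_truth"]

REQUIRED_COLUMNS = ["participant_id", "group", "day", "trial", "t_s", "x_cm", "y_cm"]


def write_trajectories(path, trajectories: list[Trajectory]) -> None:
    """Write trials to the shared delimited-text schema."""
    frames = []
    for traj in trajectories:
        meta = traj.metadata
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": meta.get("participant", 1),
                    "group": meta.get("group", "na"),
                    "day": meta.get("day", 1),
                    "trial": meta.get("trial", 1),
                    "t_s": traj.sample_times,
                    "x_cm": traj.positions[:, 0],
                    "y_cm": traj.positions[:, 1],
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df = df.sort_values(["participant_id", "day", "trial"], kind="stable")
    df.to_csv(path, index=False)


def read_trajectories(path, strict: bool = False) -> list[Trajectory]:
    """Read trials from the shared schema.

    Malformed files raise :class:`DataError` naming the offending column
    or trial.  Rows out of order are re-sorted unless ``strict`` is set,
    in which case they are rejected.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as e:  # parse failures carry pandas' line diagnostics
        raise DataError(f"cannot parse {path}: {e}") from e
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s) {missing}")

    keys = ["participant_id", "day", "trial"]
    sorted_df = df.sort_values(keys + ["t_s"], kind="stable")
    if strict and not df[keys + ["t_s"]].reset_index(drop=True).equals(
        sorted_df[keys + ["t_s"]].reset_index(drop=True)
    ):
        raise DataError(f"{path}: rows are not sorted by (participant, day, trial, t_s)")

    out = []
    for (pid, day, trial), grp in sorted_df.groupby(keys, sort=True):
        t = grp["t_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise DataError(
                f"{path}: non-monotone t_s in participant {pid}, day {day}, trial {trial}"
            )
        out.append(
            Trajectory(
                t,
                np.column_stack([grp["x_cm"].to_numpy(float), grp["y_cm"].to_numpy(float)]),
                metadata={
                    "participant": pid,
                    "day": day,
                    "trial": trial,
                    "group": str(grp["group"].iloc[0]),
                },
            )
        )
    return out


def write_truth(path, truth: pd.DataFrame) -> None:
    truth.to_csv(path, index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path)
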