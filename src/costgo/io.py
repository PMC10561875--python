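"""Trajectory CSV schema and summary JSON serialization.

One CSV row per (trial, step).  The first line is a versioned schema marker
(`# costgo-trajectory-v1`); readers refuse unknown versions rather than
guessing.  Units are SI throughout and the time column is milliseconds from
movement onset.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

SCHEMA_MARKER = "# costgo-trajectory-v1"

#: fixed column order of the trajectory table
COLUMNS = [
    "trial", "t_ms",
    "px", "py", "vx", "vy", "Fx", "Fy", "Fext_x", "Fext_y",
    "ux", "uy",
    "xhat_px", "xhat_py", "xhat_vx", "xhat_vy",
    "xhat_Fx", "xhat_Fy", "xhat_Fext_x", "xhat_Fext_y",
    "option", "w2_t", "event",
]

__all__ = ["SCHEMA_MARKER", "COLUMNS", "write_trajectories", "read_trajectories",
           "write_summary", "read_external_table"]


def write_trajectories(records: Iterable, path: str | Path) -> pd.DataFrame:
    """Serialize trajectory records to the versioned CSV; returns the frame."""
    frames = [rec.to_dataframe() for rec in records]
    df = pd.concat(frames, ignore_index=True)[COLUMNS]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(SCHEMA_MARKER + "\n")
        df.to_csv(fh, index=False, lineterminator="\n", float_format="%.9g")
    return df


def read_trajectories(path: str | Path) -> pd.DataFrame:
    """Read a versioned trajectory CSV, rejecting unknown schema versions."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if first != SCHEMA_MARKER:
            raise ValueError(
                f"{path}: unknown trajectory schema {first!r}; expected {SCHEMA_MARKER!r}"
            )
        df = pd.read_csv(fh)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_summary(summary: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


#: minimal column set for externally supplied trial tables (reanalysis)
EXTERNAL_COLUMNS = ["trial", "t_ms", "x_pos", "final_target", "force", "reward_condition"]


def read_external_table(path: str | Path) -> pd.DataFrame:
    """Read an externally supplied trial table for the ROC reanalysis.

    Expects columns (trial, t_ms, x_pos, final_target, force,
    reward_condition); extra columns pass through untouched.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in EXTERNAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: external table missing columns {missing}")
    return df
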