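"""Trial-table CSV format, series sidecars and JSON configuration.

Trial tables are UTF-8 comma-separated files with a header comment line
stamping the schema version, one row per trial, angles in degrees and SI
units throughout.  Optional per-trial time series go to a long-format
sidecar CSV next to the table, keyed by subject and trial index.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = ["SCHEMA_VERSION", "TRIAL_COLUMNS", "write_trials", "read_trials",
           "write_config", "read_config"]

SCHEMA_VERSION = "hammersim-trials-v1"

TRIAL_COLUMNS = [
    "subject_id",
    "trial_index",
    "block",
    "phase",
    "condition",
    "rotation_direction",
    "visual_orientation",
    "dynamics_orientation",
    "probe_orientation",
    "head_mass",
    "required_peak_force",
    "peak_force_mag",
    "peak_force_dir",
    "peak_disp_mag",
    "peak_disp_angle",
]

_SERIES_COLUMNS = ["subject_id", "trial_index", "t", "fx", "fy", "x", "y"]


class SchemaError(ValueError):
    pass


def _validate(table: pd.DataFrame):
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"trial table missing column(s): {', '.join(missing)}")


def write_trials(
    table: pd.DataFrame,
    path,
    series: Optional[Dict[Tuple[str, int], pd.DataFrame]] = None,
) -> None:
    """Write a trial table (and optional series sidecar) to CSV."""
    _validate(table)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {SCHEMA_VERSION}\n")
        table[TRIAL_COLUMNS].to_csv(fh, index=False)
    if series:
        frames = []
        for (sid, idx), df in series.items():
            d = df.copy()
            d.insert(0, "trial_index", idx)
            d.insert(0, "subject_id", sid)
            frames.append(d)
        long = pd.concat(frames, ignore_index=True)
        long[_SERIES_COLUMNS].to_csv(path.with_suffix(".series.csv"), index=False)


def read_trials(path, load_series: bool = False):
    """Read a trial table written by :func:`write_trials`.

    Returns the table, or ``(table, series)`` when ``load_series`` is set.
    """
    path = Path(path)
    table = pd.read_csv(path, comment="#")
    _validate(table)
    if not load_series:
        return table
    spath = path.with_suffix(".series.csv")
    series: Dict[Tuple[str, int], pd.DataFrame] = {}
    if spath.exists():
        long = pd.read_csv(spath)
        for (sid, idx), grp in long.groupby(["subject_id", "trial_index"]):
            series[(sid, int(idx))] = grp.drop(
                columns=["subject_id", "trial_index"]
            ).reset_index(drop=True)
    return table, series


def write_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(config, fh, indent=1, default=_json_default)


def read_config(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
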