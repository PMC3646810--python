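"""Schema-validated readers and writers for the pipeline's CSV tables.

All timestamps are ISO-8601 and handled in UTC throughout. Validation
errors name the file, the offending row (1-based, counting the header as
row 1) and the field.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import read_ascii_grid, write_ascii_grid  # re-exported

__all__ = [
    "SchemaError",
    "read_fixes",
    "read_dives",
    "read_ascii_grid",
    "write_ascii_grid",
    "write_table",
    "write_run_log",
]

FIX_REQUIRED = ("seal_id", "timestamp", "lon", "lat", "n_satellites")
DIVE_REQUIRED = ("seal_id", "start_time", "end_time", "max_depth_m", "duration_s")


class SchemaError(ValueError):
    """A CSV file violates the expected schema."""


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def _parse_times(df: pd.DataFrame, column: str, path) -> pd.Series:
    try:
        parsed = pd.to_datetime(df[column], utc=True, format="ISO8601")
    except (ValueError, TypeError):
        parsed = pd.to_datetime(df[column], utc=True, errors="coerce")
    bad = parsed.isna() & df[column].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise SchemaError(
            f"{path}: row {row}: unparseable timestamp in field {column!r}"
        )
    return parsed


def read_fixes(path: str | Path) -> pd.DataFrame:
    """Read a GPS fix table, validating coordinates and timestamps."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, FIX_REQUIRED, path)
    df["timestamp"] = _parse_times(df, "timestamp", path)
    lat_bad = (df["lat"] < -90) | (df["lat"] > 90)
    lon_bad = (df["lon"] < -180) | (df["lon"] > 180)
    for name, bad in (("lat", lat_bad), ("lon", lon_bad)):
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise SchemaError(f"{path}: row {row}: {name} out of range")
    if (df["n_satellites"] < 0).any():
        row = int(np.flatnonzero((df["n_satellites"] < 0).to_numpy())[0]) + 2
        raise SchemaError(f"{path}: row {row}: negative n_satellites")
    return df


def read_dives(path: str | Path, require: tuple = DIVE_REQUIRED) -> pd.DataFrame:
    """Read a dive table (any pipeline stage), validating the basics."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, require, path)
    df["start_time"] = _parse_times(df, "start_time", path)
    df["end_time"] = _parse_times(df, "end_time", path)
    bad = df["end_time"] <= df["start_time"]
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise SchemaError(f"{path}: row {row}: end_time not after start_time")
    if (df["max_depth_m"] <= 1.5).any():
        row = int(np.flatnonzero((df["max_depth_m"] <= 1.5).to_numpy())[0]) + 2
        raise SchemaError(f"{path}: row {row}: max_depth_m below dive floor (1.5 m)")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a pipeline table, rendering timestamps as ISO-8601 UTC."""
    path = Path(path)
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%dT%H:%M:%S.%f%z")
    out.to_csv(path, index=False)
    return path


def write_run_log(entries: list[dict], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2)
    return path
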