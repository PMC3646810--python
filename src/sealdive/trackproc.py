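"""GPS fix quality filtering, dive location interpolation, and the
interpolated-location error bound.

Locations for dives falling between position fixes are derived by
straight-line (linear-in-time) interpolation on raw lon/lat, anchored on
the dive's temporal midpoint; great-circle (haversine) distances are
used only where metres are needed. The additional error attached to
interpolated locations is the potential travel distance between fixes at
the maximum recorded swimming speed, minus the realised distance, scaled
down by the mean number of dive cycles per fix gap:

    error = (s_max * t_bar - d_bar) / n_bar,
    n_bar = t_bar / (mean_dive_duration + mean_surface_duration)

The exact functional form is isolated in :func:`error_from_inputs` so it
can be swapped without touching the bookkeeping around it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "filter_fixes",
    "interpolate_dive_locations",
    "interpolation_error",
    "InterpolationErrorInputs",
    "error_from_inputs",
    "haversine_m",
]

EARTH_RADIUS_M = 6_371_000.0


def haversine_m(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in metres between lon/lat points (degrees)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return EARTH_RADIUS_M * 2 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


# ---------------------------------------------------------------------
# Fix filtering
# ---------------------------------------------------------------------

def filter_fixes(fixes: pd.DataFrame, min_satellites: int = 5) -> pd.DataFrame:
    """Keep fixes with ``n_satellites >= min_satellites``.

    Output is sorted by (seal_id, timestamp); duplicate timestamps within
    a seal collapse to the fix with the most satellites.
    """
    out = fixes[fixes["n_satellites"] >= min_satellites].copy()
    out = out.sort_values(
        ["seal_id", "timestamp", "n_satellites"],
        ascending=[True, True, False],
        kind="mergesort",
    )
    out = out.drop_duplicates(subset=["seal_id", "timestamp"], keep="first")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------
# Dive location interpolation
# ---------------------------------------------------------------------

def interpolate_dive_locations(
    fixes: pd.DataFrame, dives: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Attach an interpolated lon/lat to every dive that can carry one.

    The dive's temporal midpoint is bracketed between two retained
    fixes; each coordinate is interpolated linearly in time. Dives
    before the first or after the last fix of their seal are dropped, as
    are all dives of seals with fewer than two retained fixes. The
    second return value accounts for every dropped record.
    """
    drops = {"seal_too_few_fixes": 0, "before_first_fix": 0, "after_last_fix": 0}
    located = []
    for seal_id, seal_dives in dives.groupby("seal_id", sort=False):
        seal_fixes = fixes[fixes["seal_id"] == seal_id]
        if len(seal_fixes) < 2:
            warnings.warn(
                f"seal {seal_id}: {len(seal_fixes)} retained fixes; "
                f"dropping {len(seal_dives)} dives"
            )
            drops["seal_too_few_fixes"] += len(seal_dives)
            continue
        seal_fixes = seal_fixes.sort_values("timestamp")
        ft = seal_fixes["timestamp"].to_numpy(dtype="datetime64[ns]").astype(np.int64)
        flon = seal_fixes["lon"].to_numpy(dtype=float)
        flat = seal_fixes["lat"].to_numpy(dtype=float)

        start = seal_dives["start_time"].to_numpy(dtype="datetime64[ns]")
        end = seal_dives["end_time"].to_numpy(dtype="datetime64[ns]")
        tmid = start.astype(np.int64) + (end.astype(np.int64) - start.astype(np.int64)) // 2

        before = tmid < ft[0]
        after = tmid > ft[-1]
        drops["before_first_fix"] += int(before.sum())
        drops["after_last_fix"] += int(after.sum())
        inside = ~(before | after)
        if not inside.any():
            continue

        tm = tmid[inside]
        idx = np.searchsorted(ft, tm, side="right") - 1
        idx = np.clip(idx, 0, len(ft) - 2)
        span = (ft[idx + 1] - ft[idx]).astype(float)
        w = (tm - ft[idx]).astype(float) / span
        # (1-w)*a + w*b is exact at both endpoints (w in {0, 1})
        lon = (1.0 - w) * flon[idx] + w * flon[idx + 1]
        lat = (1.0 - w) * flat[idx] + w * flat[idx + 1]

        block = seal_dives.loc[inside].copy()
        block["lon"] = lon
        block["lat"] = lat
        located.append(block)

    if located:
        out = pd.concat(located, ignore_index=True)
    else:
        out = dives.iloc[0:0].copy()
        out["lon"] = pd.Series(dtype=float)
        out["lat"] = pd.Series(dtype=float)
    return out, drops


# ---------------------------------------------------------------------
# Interpolated-location error bound
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class InterpolationErrorInputs:
    """Per-track summary quantities entering the error bound."""

    t_bar: float  # mean inter-fix time gap, seconds
    d_bar: float  # mean inter-fix great-circle distance, metres
    s_max: float  # max observed inter-fix speed, m/s
    mean_dive_duration_s: float
    mean_surface_duration_s: float

    def __post_init__(self) -> None:
        for name in ("t_bar", "d_bar", "s_max",
                     "mean_dive_duration_s", "mean_surface_duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.s_max < self.d_bar / self.t_bar - 1e-9:
            raise ValueError("s_max cannot be below the mean observed speed")


def error_from_inputs(inputs: InterpolationErrorInputs) -> float:
    """Evaluate ``(s_max * t_bar - d_bar) / n_bar`` in metres.

    ``n_bar`` (mean dive cycles per fix gap) is clamped to 1 from below
    so the bound never exceeds the raw travel-distance slack.
    """
    n_bar = inputs.t_bar / (inputs.mean_dive_duration_s + inputs.mean_surface_duration_s)
    if n_bar < 1.0:
        warnings.warn(f"n_bar={n_bar:.3f} < 1; clamping to 1")
        n_bar = 1.0
    return (inputs.s_max * inputs.t_bar - inputs.d_bar) / n_bar


def _gap_stats(seal_fixes: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    ft = seal_fixes["timestamp"].to_numpy(dtype="datetime64[ns]").astype(np.int64)
    order = np.argsort(ft, kind="stable")
    ft = ft[order]
    lon = seal_fixes["lon"].to_numpy(dtype=float)[order]
    lat = seal_fixes["lat"].to_numpy(dtype=float)[order]
    dt = np.diff(ft) / 1e9
    dist = haversine_m(lon[:-1], lat[:-1], lon[1:], lat[1:])
    keep = dt > 0
    return dt[keep], dist[keep]


def _duration_stats(seal_dives: pd.DataFrame) -> tuple[float, float]:
    durs = seal_dives["duration_s"].to_numpy(dtype=float)
    start = seal_dives.sort_values("start_time")["start_time"].to_numpy(
        dtype="datetime64[ns]"
    ).astype(np.int64)
    end = seal_dives.sort_values("start_time")["end_time"].to_numpy(
        dtype="datetime64[ns]"
    ).astype(np.int64)
    gaps = (start[1:] - end[:-1]) / 1e9
    gaps = gaps[gaps > 0]
    mean_surface = float(gaps.mean()) if len(gaps) else float("nan")
    return float(durs.mean()), mean_surface


def interpolation_error(
    fixes: pd.DataFrame, dives: pd.DataFrame
) -> tuple[dict[str, float], float]:
    """Per-seal and pooled interpolated-location error bound in metres.

    ``s_max`` is the maximum inter-fix speed per seal; the pooled value
    pools gaps, dive durations and surface gaps across all seals and
    takes the overall maximum speed.
    """
    per_seal: dict[str, float] = {}
    all_dt, all_dist = [], []
    for seal_id, seal_fixes in fixes.groupby("seal_id", sort=False):
        seal_dives = dives[dives["seal_id"] == seal_id]
        if len(seal_fixes) < 2 or len(seal_dives) == 0:
            continue
        dt, dist = _gap_stats(seal_fixes)
        if len(dt) == 0:
            continue
        all_dt.append(dt)
        all_dist.append(dist)
        mean_dive, mean_surface = _duration_stats(seal_dives)
        if np.isnan(mean_surface):
            continue
        inputs = InterpolationErrorInputs(
            t_bar=float(dt.mean()),
            d_bar=max(float(dist.mean()), 1e-9),
            s_max=max(float((dist / dt).max()), 1e-9),
            mean_dive_duration_s=mean_dive,
            mean_surface_duration_s=mean_surface,
        )
        per_seal[seal_id] = error_from_inputs(inputs)

    if not all_dt:
        return per_seal, float("nan")
    dt = np.concatenate(all_dt)
    dist = np.concatenate(all_dist)
    mean_dive, mean_surface = _duration_stats(dives)
    pooled_inputs = InterpolationErrorInputs(
        t_bar=float(dt.mean()),
        d_bar=max(float(dist.mean()), 1e-9),
        s_max=max(float((dist / dt).max()), 1e-9),
        mean_dive_duration_s=mean_dive,
        mean_surface_duration_s=mean_surface,
    )
    return per_seal, error_from_inputs(pooled_inputs)
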