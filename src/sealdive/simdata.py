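"""Synthetic habitat rasters and seal tag datasets.

The simulator produces the statistical structure the downstream analysis
assumes: a correlated random walk over a coastal bathymetry gradient
with patchy sediment, dives alternating with surface intervals, surface-
conditional GPS fix attempts on a fixed schedule, and per-dive true
behavioural types drawn from configurable pelagic probabilities per
(sediment class, day/night) cell.
"""

from __future__ import annotations

import math
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import SEDIMENT_CODES, HabitatRaster
from .habitat import pool_sediment, sun_times_utc

__all__ = [
    "SimulationConfig",
    "generate_habitat",
    "simulate_seal",
    "simulate_dataset",
    "write_dataset",
    "DEFAULT_P_PELAGIC",
]

M_PER_DEG_LAT = 111_320.0

#: Depth (m) below which a dive is generated as "shallow" — matches the
#: classifier's default cutoff so recovery tests compare like with like.
SHALLOW_TRUTH_CUTOFF_M = 50.0

#: Pelagic probability per (sediment class, diel) cell. The mapped-class
#: values emulate the day/night frequencies the analysis is designed to
#: detect (fine > coarse > rock, night > day).
DEFAULT_P_PELAGIC = {
    ("fine", "day"): 0.36,
    ("fine", "night"): 0.52,
    ("coarse", "day"): 0.28,
    ("coarse", "night"): 0.39,
    ("rock", "day"): 0.20,
    ("rock", "night"): 0.39,
    ("unclassified", "day"): 0.30,
    ("unclassified", "night"): 0.45,
}

DEFAULT_START_TIME = pd.Timestamp("2009-03-01T00:00:00", tz="UTC")

FIX_COLUMNS = ["seal_id", "timestamp", "lon", "lat", "n_satellites"]
DIVE_COLUMNS = ["seal_id", "start_time", "end_time", "max_depth_m", "duration_s"]
TRUTH_COLUMNS = DIVE_COLUMNS + ["true_lon", "true_lat", "true_type"]


@dataclass
class SimulationConfig:
    """Knobs for the tag-data simulator.

    Satellite counts default to a uniform draw over 4..10 so the
    downstream >= 5 satellite filter removes a nontrivial fraction of
    fixes. The walk speed is a free parameter kept well below
    ``max_speed_mps`` (the *s* entering the interpolation error bound).
    """

    n_seals: int = 8
    deployment_days: float = 7.0
    fix_interval_s: float = 1800.0
    mean_dive_duration_s: float = 180.0
    mean_surface_duration_s: float = 90.0
    max_speed_mps: float = 2.0
    p_pelagic: dict = field(default_factory=lambda: dict(DEFAULT_P_PELAGIC))
    gps_noise_m: float = 25.0
    p_fix_success: float = 0.9
    satellite_count_distribution: dict = field(
        default_factory=lambda: {n: 1.0 / 7.0 for n in range(4, 11)}
    )
    rng_seed: int = 0
    # movement knobs (not part of the error-bound inputs)
    swim_speed_mps: float = 0.8
    turn_sd_rad: float = 0.25
    substep_s: float = 60.0
    min_start_depth_m: float = 60.0
    start_time: pd.Timestamp = DEFAULT_START_TIME

    def __post_init__(self) -> None:
        if self.n_seals < 1:
            raise ValueError("n_seals must be >= 1")
        for name in (
            "deployment_days",
            "fix_interval_s",
            "mean_dive_duration_s",
            "mean_surface_duration_s",
            "max_speed_mps",
            "swim_speed_mps",
            "substep_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("gps_noise_m", "turn_sd_rad"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.p_fix_success <= 1.0:
            raise ValueError("p_fix_success must be in [0, 1]")
        for sed in ("fine", "coarse", "rock", "unclassified"):
            for diel in ("day", "night"):
                p = self.p_pelagic.get((sed, diel))
                if p is None:
                    raise ValueError(f"p_pelagic missing cell ({sed}, {diel})")
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"p_pelagic[({sed}, {diel})]={p} not in [0, 1]")
        total = sum(self.satellite_count_distribution.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("satellite_count_distribution must sum to 1")


# ---------------------------------------------------------------------
# Habitat generation
# ---------------------------------------------------------------------

def generate_habitat(
    seed: int,
    ncols: int = 128,
    nrows: int = 128,
    cellsize: float = 0.003,
    origin: tuple[float, float] = (-11.0, 51.8),
    max_depth_m: float = 400.0,
    noise_sd_m: float = 8.0,
    n_patches: int | None = None,
) -> tuple[HabitatRaster, HabitatRaster]:
    """Generate co-registered depth and sediment rasters.

    Depth is a smooth onshore-to-offshore gradient (0 m at the eastern
    edge rising to ``max_depth_m`` at the western edge) plus bounded
    smoothed noise, clipped to [0, max_depth_m]. Sediment is a patchy
    mosaic of contiguous blobs over the four integer codes, built by
    nearest-seed (Voronoi) assignment.
    """
    if ncols < 16 or nrows < 16:
        raise ValueError("habitat grids must be at least 16x16")
    rng = np.random.default_rng(seed)
    xll, yll = origin

    # depth gradient: column 0 (west) deepest, last column (east) at 0 m
    ramp = np.linspace(max_depth_m, 0.0, ncols)
    depth_vals = np.tile(ramp, (nrows, 1))
    noise = rng.normal(0.0, 1.0, size=(nrows, ncols))
    noise = ndimage.gaussian_filter(noise, sigma=3.0)
    noise *= noise_sd_m / max(noise.std(), 1e-12)
    depth_vals = np.clip(depth_vals + noise, 0.0, max_depth_m)

    if n_patches is None:
        n_patches = max(8, (ncols * nrows) // 256)
    seed_rows = rng.integers(0, nrows, size=n_patches)
    seed_cols = rng.integers(0, ncols, size=n_patches)
    seed_codes = rng.integers(0, 4, size=n_patches)
    rr, cc = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    d2 = (rr[..., None] - seed_rows) ** 2 + (cc[..., None] - seed_cols) ** 2
    sediment_vals = seed_codes[np.argmin(d2, axis=-1)].astype(int)

    common = dict(ncols=ncols, nrows=nrows, xll=xll, yll=yll, cellsize=cellsize)
    depth = HabitatRaster(nodata=-9999.0, values=depth_vals, **common)
    sediment = HabitatRaster(nodata=-9999.0, values=sediment_vals, **common)
    return depth, sediment


# ---------------------------------------------------------------------
# Seal simulation
# ---------------------------------------------------------------------

def _raster_value(raster: HabitatRaster, lon: float, lat: float) -> float:
    col = int(math.floor((lon - raster.xll) / raster.cellsize))
    rfb = int(math.floor((lat - raster.yll) / raster.cellsize))
    if not (0 <= col < raster.ncols and 0 <= rfb < raster.nrows):
        return math.nan
    v = float(raster.values[raster.nrows - 1 - rfb, col])
    return math.nan if v == raster.nodata else v


def _valid_position(depth: HabitatRaster, lon: float, lat: float) -> bool:
    if not depth.contains(lon, lat):
        return False
    return not math.isnan(_raster_value(depth, lon, lat))


class _Walker:
    """Piecewise-linear correlated random walk inside a raster extent."""

    def __init__(self, depth: HabitatRaster, lon: float, lat: float,
                 speed_mps: float, turn_sd: float, rng: np.random.Generator):
        self.depth = depth
        self.lon = lon
        self.lat = lat
        self.speed = speed_mps
        self.turn_sd = turn_sd
        self.rng = rng
        self.heading = rng.uniform(0.0, 2.0 * math.pi)

    def step(self, dt: float) -> tuple[float, float]:
        """Advance ``dt`` seconds; returns the previous position."""
        prev = (self.lon, self.lat)
        dist = self.speed * dt
        for _ in range(20):
            dx = dist * math.cos(self.heading)
            dy = dist * math.sin(self.heading)
            lon = self.lon + dx / (M_PER_DEG_LAT * math.cos(math.radians(self.lat)))
            lat = self.lat + dy / M_PER_DEG_LAT
            if _valid_position(self.depth, lon, lat):
                self.lon, self.lat = lon, lat
                break
            self.heading = self.rng.uniform(0.0, 2.0 * math.pi)
        if self.turn_sd > 0:
            self.heading += self.rng.normal(0.0, self.turn_sd)
        return prev


def _random_start(depth: HabitatRaster, min_depth: float,
                  rng: np.random.Generator) -> tuple[float, float]:
    vals = depth.values
    ok = (vals != depth.nodata) & (vals >= min_depth)
    if not ok.any():
        ok = vals != depth.nodata
        if not ok.any():
            raise ValueError("depth raster has no usable cells")
    rows, cols = np.nonzero(ok)
    k = rng.integers(0, len(rows))
    return depth.cell_center(int(rows[k]), int(cols[k]))


def simulate_seal(
    config: SimulationConfig,
    depth: HabitatRaster,
    sediment: HabitatRaster,
    seal_id: str,
    rng: np.random.Generator | None = None,
    start_lonlat: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one seal; returns ``(fixes, true_dives)`` DataFrames.

    Dives alternate with surface intervals (exponential durations, dives
    truncated at the 8 s definition floor). GPS fix attempts happen on
    the fixed ``fix_interval_s`` schedule and succeed only when the seal
    is at the surface, with probability ``p_fix_success``. Per-dive true
    type: water shallower than 50 m gives a "shallow" dive capped at the
    local depth; deeper water draws pelagic vs benthic from the
    configured (sediment, diel) probability.
    """
    if not depth.same_geometry(sediment):
        raise ValueError("depth and sediment rasters must share geometry")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)

    if start_lonlat is None:
        lon0, lat0 = _random_start(depth, config.min_start_depth_m, rng)
    else:
        lon0, lat0 = start_lonlat
        if not _valid_position(depth, lon0, lat0):
            raise ValueError(
                f"start position ({lon0}, {lat0}) is outside the raster "
                "or on a nodata cell"
            )

    walker = _Walker(depth, lon0, lat0, config.swim_speed_mps,
                     config.turn_sd_rad, rng)
    start_ts = pd.Timestamp(config.start_time)
    if start_ts.tzinfo is None:
        start_ts = start_ts.tz_localize("UTC")

    sat_counts = np.array(sorted(config.satellite_count_distribution))
    sat_probs = np.array(
        [config.satellite_count_distribution[k] for k in sat_counts], dtype=float
    )
    sat_probs = sat_probs / sat_probs.sum()
    noise_deg_lat = config.gps_noise_m / M_PER_DEG_LAT

    # Sunrise/sunset barely change over the distances a seal covers in a
    # day, so memoise per (day-of-year, coarse position).
    sun_cache: dict[tuple, tuple[float, float]] = {}

    def _diel(abs_seconds: float, lon: float, lat: float) -> str:
        ts = start_ts + pd.Timedelta(seconds=abs_seconds)
        key = (ts.dayofyear, round(lon, 2), round(lat, 2))
        if key not in sun_cache:
            sun_cache[key] = sun_times_utc(ts, lon, lat)
        sr, ss = sun_cache[key]
        if math.isinf(sr):
            return "day" if sr < 0 else "night"
        minutes = ts.hour * 60.0 + ts.minute + ts.second / 60.0
        sr_m, ss_m = sr % 1440.0, ss % 1440.0
        if sr_m <= ss_m:
            return "day" if sr_m <= minutes < ss_m else "night"
        return "day" if (minutes >= sr_m or minutes < ss_m) else "night"

    t = 0.0
    end_t = config.deployment_days * 86400.0
    next_attempt = config.fix_interval_s  # first attempt one interval in
    fixes: list[tuple] = []
    dives: list[tuple] = []

    def advance(duration: float, at_surface: bool, capture_at: float | None):
        """Move for ``duration`` s; optionally capture position at an
        absolute time (dive midpoint). Emits fixes while at surface."""
        nonlocal t, next_attempt
        captured = None
        remaining = duration
        while remaining > 1e-9:
            dt = min(config.substep_s, remaining)
            lon_a, lat_a = walker.lon, walker.lat
            walker.step(dt)
            lon_b, lat_b = walker.lon, walker.lat
            seg_start, seg_end = t, t + dt

            while next_attempt <= seg_end + 1e-9:
                if next_attempt >= seg_start - 1e-9:
                    frac = (next_attempt - seg_start) / dt
                    if at_surface and rng.random() < config.p_fix_success:
                        lon_f = lon_a + frac * (lon_b - lon_a)
                        lat_f = lat_a + frac * (lat_b - lat_a)
                        if config.gps_noise_m > 0:
                            lat_noisy = lat_f + rng.normal(0, noise_deg_lat)
                            lon_noisy = lon_f + rng.normal(
                                0, noise_deg_lat / math.cos(math.radians(lat_f))
                            )
                        else:
                            lon_noisy, lat_noisy = lon_f, lat_f
                        nsat = int(rng.choice(sat_counts, p=sat_probs))
                        fixes.append((next_attempt, lon_noisy, lat_noisy, nsat))
                next_attempt += config.fix_interval_s

            if capture_at is not None and seg_start - 1e-9 <= capture_at <= seg_end + 1e-9:
                frac = (capture_at - seg_start) / dt
                captured = (
                    lon_a + frac * (lon_b - lon_a),
                    lat_a + frac * (lat_b - lat_a),
                )
                capture_at = None
            t = seg_end
            remaining -= dt
        return captured

    while t < end_t:
        surf_dur = max(2.0, rng.exponential(config.mean_surface_duration_s))
        advance(min(surf_dur, end_t - t), at_surface=True, capture_at=None)
        if t >= end_t:
            break

        dive_dur = max(8.5, rng.exponential(config.mean_dive_duration_s))
        dive_dur = min(dive_dur, end_t - t)
        if dive_dur <= 8.0:
            break
        dive_start = t
        local_depth = _raster_value(depth, walker.lon, walker.lat)
        mid = advance(dive_dur, at_surface=False, capture_at=dive_start + dive_dur / 2.0)
        if mid is None:  # numerical edge; fall back to end position
            mid = (walker.lon, walker.lat)

        if math.isnan(local_depth) or local_depth <= 1.6:
            continue  # too shallow to register a dive event
        if local_depth < SHALLOW_TRUTH_CUTOFF_M:
            true_type = "shallow"
            max_depth = rng.uniform(1.51, local_depth)
        else:
            sed_code = _raster_value(sediment, walker.lon, walker.lat)
            sed_class = pool_sediment(sed_code)
            diel = _diel(dive_start, walker.lon, walker.lat)
            p = config.p_pelagic[(sed_class, diel)]
            if rng.random() < p:
                true_type = "pelagic"
                max_depth = rng.uniform(0.1 * local_depth, 0.9 * local_depth)
            else:
                true_type = "benthic"
                max_depth = rng.uniform(0.95 * local_depth, local_depth)
        dives.append((dive_start, dive_dur, max_depth, mid[0], mid[1], true_type))

    fix_df = pd.DataFrame(
        {
            "seal_id": seal_id,
            "timestamp": start_ts + pd.to_timedelta([f[0] for f in fixes], unit="s"),
            "lon": [f[1] for f in fixes],
            "lat": [f[2] for f in fixes],
            "n_satellites": [f[3] for f in fixes],
        }
    )
    dive_starts = pd.to_timedelta([d[0] for d in dives], unit="s")
    dive_durs = np.array([d[1] for d in dives])
    dive_df = pd.DataFrame(
        {
            "seal_id": seal_id,
            "start_time": start_ts + dive_starts,
            "end_time": start_ts + dive_starts + pd.to_timedelta(dive_durs, unit="s"),
            "max_depth_m": [d[2] for d in dives],
            "duration_s": dive_durs,
            "true_lon": [d[3] for d in dives],
            "true_lat": [d[4] for d in dives],
            "true_type": [d[5] for d in dives],
        }
    )
    return fix_df, dive_df


def simulate_dataset(
    config: SimulationConfig,
    depth: HabitatRaster,
    sediment: HabitatRaster,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ``config.n_seals`` seals with per-seal child RNG streams."""
    fix_frames, dive_frames = [], []
    for i in range(config.n_seals):
        rng = np.random.default_rng([config.rng_seed, i])
        seal_id = f"seal_{i + 1:02d}"
        fixes, dives = simulate_seal(config, depth, sediment, seal_id, rng=rng)
        fix_frames.append(fixes)
        dive_frames.append(dives)
    return (
        pd.concat(fix_frames, ignore_index=True),
        pd.concat(dive_frames, ignore_index=True),
    )


# ---------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------

def _timestamps_iso(series: pd.Series) -> pd.Series:
    return series.dt.strftime("%Y-%m-%dT%H:%M:%S.%f%z")


def write_dataset(fixes: pd.DataFrame, dives: pd.DataFrame,
                  directory: str | Path) -> dict[str, Path]:
    """Write ``fixes.csv``, ``dives.csv`` and ``truth.csv`` atomically.

    ``dives.csv`` withholds the true positions/types (the pipeline's
    input); ``truth.csv`` keeps them for recovery tests. Nothing is
    written unless both inputs are non-empty.
    """
    if len(fixes) == 0 or len(dives) == 0:
        raise ValueError("refusing to write an empty dataset")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    fix_out = fixes.copy()
    fix_out["timestamp"] = _timestamps_iso(fix_out["timestamp"])
    truth_out = dives.copy()
    truth_out["start_time"] = _timestamps_iso(truth_out["start_time"])
    truth_out["end_time"] = _timestamps_iso(truth_out["end_time"])
    dive_out = truth_out[DIVE_COLUMNS]

    paths = {}
    frames = {
        "fixes.csv": fix_out[FIX_COLUMNS],
        "dives.csv": dive_out,
        "truth.csv": truth_out[TRUTH_COLUMNS],
    }
    tmp_paths = []
    try:
        for name, frame in frames.items():
            fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
            os.close(fd)
            frame.to_csv(tmp, index=False)
            tmp_paths.append((tmp, directory / name))
        for tmp, final in tmp_paths:
            os.replace(tmp, final)
            paths[final.name] = final
    finally:
        for tmp, _ in tmp_paths:
            if os.path.exists(tmp):
                os.unlink(tmp)
    return paths
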