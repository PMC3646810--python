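"""Annotate located dives with water depth, sediment class and day/night.

Raster lookup uses the containing cell (no interpolation) with cells
treated as half-open intervals, sediment labels are pooled to four broad
classes, and the diel flag comes from local sunrise/sunset computed with
the NOAA solar-geometry equations at zenith 90.833 degrees.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import SEDIMENT_CODES, HabitatRaster

__all__ = [
    "extract_at",
    "extract_values",
    "pool_sediment",
    "sun_times_utc",
    "is_daytime",
    "diel_flags",
    "annotate_dives",
]

SEDIMENT_CLASSES = ("fine", "coarse", "rock", "unclassified")

# EUNIS-derived substrate labels pooled to the three broad classes;
# anything unmatched falls through to "unclassified".
_SEDIMENT_POOL = {
    "mud": "fine",
    "sand": "fine",
    "fine": "fine",
    "mud/sand": "fine",
    "gravel": "coarse",
    "mixed": "coarse",
    "mixed ground": "coarse",
    "gravel/mixed": "coarse",
    "coarse": "coarse",
    "rock": "rock",
    "till": "rock",
    "rocky": "rock",
    "rock/till": "rock",
}


# ---------------------------------------------------------------------
# Raster extraction
# ---------------------------------------------------------------------

def extract_values(raster: HabitatRaster, lons, lats) -> np.ndarray:
    """Cell values at each lon/lat point; NaN outside the extent or on nodata.

    Cells are half-open ``[x, x + cellsize) x [y, y + cellsize)`` so a
    point on a shared edge belongs to exactly one cell (the one whose
    lower bound it is).
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    col = np.floor((lons - raster.xll) / raster.cellsize).astype(int)
    row_from_bottom = np.floor((lats - raster.yll) / raster.cellsize).astype(int)
    inside = (
        (col >= 0)
        & (col < raster.ncols)
        & (row_from_bottom >= 0)
        & (row_from_bottom < raster.nrows)
    )
    out = np.full(lons.shape, np.nan)
    rows = raster.nrows - 1 - row_from_bottom[inside]
    vals = raster.values[rows, col[inside]].astype(float)
    vals[vals == raster.nodata] = np.nan
    out[inside] = vals
    return out


def extract_at(raster: HabitatRaster, lon: float, lat: float) -> float:
    """Scalar form of :func:`extract_values` (NaN marks missing)."""
    return float(extract_values(raster, np.array([lon]), np.array([lat]))[0])


# ---------------------------------------------------------------------
# Sediment pooling
# ---------------------------------------------------------------------

def pool_sediment(code) -> str:
    """Pool a raw sediment label or integer code to one of four classes.

    Integer codes follow the package convention
    (0 unclassified, 1 fine, 2 coarse, 3 rock); strings are matched
    case-insensitively against known substrate names. Everything else,
    including missing values, maps to ``"unclassified"``.
    """
    if code is None:
        return "unclassified"
    if isinstance(code, (int, np.integer)):
        return SEDIMENT_CODES.get(int(code), "unclassified")
    if isinstance(code, (float, np.floating)):
        if np.isnan(code):
            return "unclassified"
        if float(code).is_integer():
            return SEDIMENT_CODES.get(int(code), "unclassified")
        return "unclassified"
    return _SEDIMENT_POOL.get(str(code).strip().lower(), "unclassified")


# ---------------------------------------------------------------------
# Solar day/night
# ---------------------------------------------------------------------

_ZENITH_DEG = 90.833  # standard refraction + solar radius


def solar_position(jd_noon):
    """NOAA equation of time (minutes) and solar declination (radians)
    for a Julian date, via the Julian-century series."""
    jc = (np.asarray(jd_noon, dtype=float) - 2451545.0) / 36525.0
    gmls = np.mod(280.46646 + jc * (36000.76983 + jc * 0.0003032), 360.0)
    gmas = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    gmas_r = np.radians(gmas)
    eqctr = (
        np.sin(gmas_r) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + np.sin(2 * gmas_r) * (0.019993 - 0.000101 * jc)
        + np.sin(3 * gmas_r) * 0.000289
    )
    app_long = gmls + eqctr - 0.00569 - 0.00478 * np.sin(
        np.radians(125.04 - 1934.136 * jc)
    )
    mean_obliq = 23.0 + (
        26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0
    ) / 60.0
    obliq = mean_obliq + 0.00256 * np.cos(np.radians(125.04 - 1934.136 * jc))
    obliq_r = np.radians(obliq)
    decl = np.arcsin(np.sin(obliq_r) * np.sin(np.radians(app_long)))
    vary = np.tan(obliq_r / 2.0) ** 2
    gmls_r = np.radians(gmls)
    eqtime = 4.0 * np.degrees(
        vary * np.sin(2 * gmls_r)
        - 2.0 * ecc * np.sin(gmas_r)
        + 4.0 * ecc * vary * np.sin(gmas_r) * np.cos(2 * gmls_r)
        - 0.5 * vary * vary * np.sin(4 * gmls_r)
        - 1.25 * ecc * ecc * np.sin(2 * gmas_r)
    )
    return eqtime, decl


def _sun_events(jd_noon, lon, lat):
    """Sunrise/sunset in minutes after 00:00 UTC, plus cos(hour angle).

    ``cos_ha`` outside [-1, 1] flags polar day (< -1) or polar night
    (> 1); the returned event times are then meaningless.
    """
    lat_r = np.radians(lat)
    zen = np.radians(_ZENITH_DEG)
    eqtime, decl = solar_position(jd_noon)
    cos_ha = (np.cos(zen) / (np.cos(lat_r) * np.cos(decl))
              - np.tan(lat_r) * np.tan(decl))
    ha = np.degrees(np.arccos(np.clip(cos_ha, -1.0, 1.0)))
    solar_noon = 720.0 - 4.0 * lon - eqtime
    return solar_noon - 4.0 * ha, solar_noon + 4.0 * ha, cos_ha


def sun_times_utc(timestamp, lon: float, lat: float) -> tuple[float, float]:
    """Sunrise and sunset (minutes after 00:00 UTC) for the UTC date of
    ``timestamp`` at the given location.

    Returns ``(-inf, inf)`` under polar day and ``(inf, -inf)`` under
    polar night.
    """
    if not -90.0 <= lat <= 90.0:
        raise ValueError(f"latitude {lat} out of range")
    ts = pd.Timestamp(timestamp)
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    else:
        ts = ts.tz_convert("UTC")
    jd_noon = ts.normalize().to_julian_date() + 0.5
    sr, ss, cos_ha = _sun_events(jd_noon, lon, lat)
    if cos_ha < -1.0:
        return -np.inf, np.inf
    if cos_ha > 1.0:
        return np.inf, -np.inf
    return float(sr), float(ss)


def diel_flags(timestamps, lons, lats) -> np.ndarray:
    """Vectorised day/night labels ("day"/"night") for UTC timestamps."""
    idx = pd.DatetimeIndex(timestamps)
    if idx.tz is None:
        idx = idx.tz_localize("UTC")
    else:
        idx = idx.tz_convert("UTC")
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if np.any(np.abs(lats) > 90.0):
        raise ValueError("latitude out of range")
    jd_noon = idx.normalize().to_julian_date() + 0.5
    minutes = (
        idx.hour.to_numpy() * 60.0
        + idx.minute.to_numpy()
        + idx.second.to_numpy() / 60.0
        + idx.microsecond.to_numpy() / 60e6
    )
    sr, ss, cos_ha = _sun_events(jd_noon, lons, lats)
    sr_m = np.mod(sr, 1440.0)
    ss_m = np.mod(ss, 1440.0)
    no_wrap = sr_m <= ss_m
    day = np.where(
        no_wrap,
        (minutes >= sr_m) & (minutes < ss_m),
        (minutes >= sr_m) | (minutes < ss_m),
    )
    day = np.where(cos_ha < -1.0, True, day)   # polar day
    day = np.where(cos_ha > 1.0, False, day)   # polar night
    return np.where(day, "day", "night")


def is_daytime(timestamp, lon: float, lat: float) -> str:
    """Return ``"day"`` iff local sunrise <= t < sunset, else ``"night"``."""
    return str(diel_flags([timestamp], [lon], [lat])[0])


# ---------------------------------------------------------------------
# Dive annotation
# ---------------------------------------------------------------------

def annotate_dives(
    dives: pd.DataFrame,
    depth_raster: HabitatRaster,
    sediment_raster: HabitatRaster,
) -> tuple[pd.DataFrame, dict]:
    """Attach ``bathy_depth_m``, ``sediment`` and ``diel`` to located dives.

    Depth outside the raster or on nodata cells is left as NaN (counted
    in the returned log dict); missing sediment becomes "unclassified".
    """
    out = dives.copy()
    lons = out["lon"].to_numpy(dtype=float)
    lats = out["lat"].to_numpy(dtype=float)
    bathy = extract_values(depth_raster, lons, lats)
    sed_raw = extract_values(sediment_raster, lons, lats)
    out["bathy_depth_m"] = bathy
    out["sediment"] = [pool_sediment(v) for v in sed_raw]
    out["diel"] = diel_flags(out["start_time"], lons, lats)
    log = {
        "n_in": int(len(out)),
        "n_missing_bathymetry": int(np.isnan(bathy).sum()),
        "n_unclassified_sediment": int((out["sediment"] == "unclassified").sum()),
    }
    return out, log
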