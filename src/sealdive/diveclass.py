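"""Shallow / pelagic / benthic dive classification.

Dives over charted water shallower than the cutoff (default 50 m) are
"shallow" — depth errors there make seabed-proximity judgements
unreliable. Deeper dives are split on the proximity ratio
(max dive depth / charted depth): below the threshold (default 0.95)
pelagic, at or above it benthic. Ratios above 1 are retained, not
clipped; they reflect charted-depth error and feed the binned
diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ClassifierConfig",
    "proximity_ratio",
    "classify_dive",
    "classify_dives",
    "ratio_error_diagnostic",
]

DIVE_TYPES = ("shallow", "pelagic", "benthic")


@dataclass(frozen=True)
class ClassifierConfig:
    shallow_cutoff_m: float = 50.0
    benthic_ratio: float = 0.95

    def __post_init__(self) -> None:
        if self.shallow_cutoff_m <= 0:
            raise ValueError("shallow_cutoff_m must be > 0")
        if not 0.0 < self.benthic_ratio <= 1.0:
            raise ValueError("benthic_ratio must be in (0, 1]")


def proximity_ratio(max_depth_m, bathy_depth_m):
    """Dive depth over charted depth; NaN where charted depth is missing
    or non-positive. Values above 1 are legitimate and retained."""
    max_depth_m = np.asarray(max_depth_m, dtype=float)
    bathy_depth_m = np.asarray(bathy_depth_m, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(bathy_depth_m > 0, max_depth_m / bathy_depth_m, np.nan)
    if ratio.ndim == 0:
        return float(ratio)
    return ratio


def classify_dive(max_depth_m: float, bathy_depth_m: float,
                  cfg: ClassifierConfig = ClassifierConfig()) -> str:
    """Classify one dive. Charted depth below the cutoff wins regardless
    of recorded dive depth (a 100 m dive over charted 40 m is "shallow")."""
    if bathy_depth_m is None or np.isnan(bathy_depth_m):
        raise ValueError("bathy_depth_m is required for classification")
    if bathy_depth_m < cfg.shallow_cutoff_m:
        return "shallow"
    ratio = proximity_ratio(max_depth_m, bathy_depth_m)
    return "pelagic" if ratio < cfg.benthic_ratio else "benthic"


def classify_dives(
    dives: pd.DataFrame, cfg: ClassifierConfig = ClassifierConfig()
) -> tuple[pd.DataFrame, dict]:
    """Vectorised classification of annotated dives.

    Rows without charted depth cannot be classified and are dropped;
    the returned log dict accounts for them.
    """
    bathy = dives["bathy_depth_m"].to_numpy(dtype=float)
    missing = np.isnan(bathy)
    out = dives.loc[~missing].copy()
    b = bathy[~missing]
    ratio = proximity_ratio(out["max_depth_m"].to_numpy(dtype=float), b)
    dive_type = np.where(
        b < cfg.shallow_cutoff_m,
        "shallow",
        np.where(ratio < cfg.benthic_ratio, "pelagic", "benthic"),
    )
    out["dive_type"] = dive_type
    log = {
        "n_in": int(len(dives)),
        "n_classified": int(len(out)),
        "n_missing_bathymetry": int(missing.sum()),
    }
    return out.reset_index(drop=True), log


def ratio_error_diagnostic(
    dives: pd.DataFrame, bin_width_m: float = 5.0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Binned proportion of proximity ratios exceeding 1.

    Charted depth is binned into [0, w), [w, 2w), ...; each row of the
    returned table carries the bin bounds, the dive count and the
    fraction of dives whose ratio exceeds 1. The raw ratio distribution
    is returned alongside for threshold inspection.
    """
    bathy = dives["bathy_depth_m"].to_numpy(dtype=float)
    depth = dives["max_depth_m"].to_numpy(dtype=float)
    ok = ~np.isnan(bathy) & (bathy > 0)
    if not ok.any():
        raise ValueError("no dives with usable charted depth")
    bathy = bathy[ok]
    ratios = depth[ok] / bathy

    bin_idx = np.floor(bathy / bin_width_m).astype(int)
    rows = []
    for b in np.unique(bin_idx):
        mask = bin_idx == b
        rows.append(
            {
                "bin_left_m": b * bin_width_m,
                "bin_right_m": (b + 1) * bin_width_m,
                "n_dives": int(mask.sum()),
                "prop_ratio_gt_1": float((ratios[mask] > 1.0).mean()),
            }
        )
    return pd.DataFrame(rows), ratios
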