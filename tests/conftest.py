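import numpy as np
import pandas as pd
import pytest

from sealdive.grids import HabitatRaster
from sealdive.simdata import SimulationConfig, generate_habitat, simulate_dataset

T0 = pd.Timestamp("2009-03-01T00:00:00", tz="UTC")


def make_flat_habitat(depth_m=100.0, ncols=64, nrows=64, cellsize=0.003,
                      origin=(-10.6, 51.9), stripe_cells=8):
    """Constant-depth raster plus vertical sediment stripes cycling
    fine/coarse/rock. Stripes guarantee every mapped class is visited."""
    xll, yll = origin
    depth = HabitatRaster(
        ncols=ncols, nrows=nrows, xll=xll, yll=yll, cellsize=cellsize,
        values=np.full((nrows, ncols), float(depth_m)),
    )
    cols = np.arange(ncols)
    codes = (cols // stripe_cells) % 3 + 1  # 1 fine, 2 coarse, 3 rock
    sediment = HabitatRaster(
        ncols=ncols, nrows=nrows, xll=xll, yll=yll, cellsize=cellsize,
        values=np.tile(codes, (nrows, 1)).astype(int),
    )
    return depth, sediment


def make_dives(specs, seal_id="seal_01", t0=T0, spacing_s=600.0, duration_s=120.0):
    """Build a dive DataFrame from a list of per-dive dicts; any column
    (lon, lat, bathy_depth_m, sediment, diel, dive_type...) may be set."""
    rows = []
    for i, spec in enumerate(specs):
        start = t0 + pd.Timedelta(seconds=i * spacing_s)
        row = {
            "seal_id": seal_id,
            "start_time": start,
            "end_time": start + pd.Timedelta(seconds=duration_s),
            "max_depth_m": 60.0,
            "duration_s": duration_s,
        }
        row.update(spec)
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def coastal_habitat():
    return generate_habitat(seed=11, ncols=96, nrows=96)


@pytest.fixture(scope="session")
def small_dataset(coastal_habitat):
    """Two simulated seals over the coastal habitat, ~0.5 day each."""
    depth, sediment = coastal_habitat
    config = SimulationConfig(
        n_seals=2, deployment_days=0.5, rng_seed=42,
        mean_dive_duration_s=120.0, mean_surface_duration_s=60.0,
    )
    fixes, dives = simulate_dataset(config, depth, sediment)
    return config, fixes, dives
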