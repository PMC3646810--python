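import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sealdive.trackproc import (
    InterpolationErrorInputs,
    error_from_inputs,
    filter_fixes,
    haversine_m,
    interpolate_dive_locations,
    interpolation_error,
)

from .conftest import T0, make_dives


def make_fixes(times_s, lons, lats, seal_id="seal_01", n_satellites=8):
    return pd.DataFrame({
        "seal_id": seal_id,
        "timestamp": [T0 + pd.Timedelta(seconds=t) for t in times_s],
        "lon": lons,
        "lat": lats,
        "n_satellites": n_satellites,
    })


class TestFilterFixes:
    def test_threshold_is_inclusive_at_five(self):
        fixes = make_fixes([0, 60, 120, 180], [0] * 4, [50] * 4)
        fixes["n_satellites"] = [3, 4, 5, 6]
        assert len(filter_fixes(fixes)) == 2

    def test_identity_when_all_good(self):
        fixes = make_fixes([0, 60], [0, 1], [50, 50], n_satellites=12)
        out = filter_fixes(fixes)
        assert len(out) == 2

    def test_empty_input(self):
        fixes = make_fixes([], [], [])
        assert len(filter_fixes(fixes)) == 0

    def test_duplicate_timestamps_keep_more_satellites(self):
        fixes = make_fixes([0, 0, 60], [1.0, 2.0, 3.0], [50] * 3)
        fixes["n_satellites"] = [6, 9, 7]
        out = filter_fixes(fixes)
        assert len(out) == 2
        assert out["lon"].iloc[0] == 2.0  # the 9-satellite fix wins

    def test_sorted_output(self):
        fixes = pd.concat([
            make_fixes([60, 0], [1, 0], [50, 50], seal_id="b"),
            make_fixes([30], [5], [50], seal_id="a"),
        ])
        out = filter_fixes(fixes)
        assert list(out["seal_id"]) == ["a", "b", "b"]
        assert out.groupby("seal_id")["timestamp"].is_monotonic_increasing.all()


class TestInterpolateDiveLocations:
    def test_midpoint_at_fix_inherits_coordinates_exactly(self):
        fixes = make_fixes([0, 1800, 3600], [-10.0, -10.2, -10.3],
                           [52.0, 52.1, 52.15])
        # dive centred exactly on the middle fix
        dives = make_dives([{"start_time": T0 + pd.Timedelta(seconds=1740),
                             "end_time": T0 + pd.Timedelta(seconds=1860),
                             "duration_s": 120.0}])
        out, drops = interpolate_dive_locations(fixes, dives)
        assert out["lon"].iloc[0] == -10.2
        assert out["lat"].iloc[0] == 52.1
        assert sum(drops.values()) == 0

    def test_halfway_interpolation(self):
        fixes = make_fixes([0, 1800], [-10.0, -10.2], [52.0, 52.1])
        dives = make_dives([{"start_time": T0 + pd.Timedelta(seconds=840),
                             "end_time": T0 + pd.Timedelta(seconds=960),
                             "duration_s": 120.0}])
        out, _ = interpolate_dive_locations(fixes, dives)
        assert out["lon"].iloc[0] == pytest.approx(-10.1, abs=1e-12)
        assert out["lat"].iloc[0] == pytest.approx(52.05, abs=1e-12)

    def test_equally_spaced_dives_equally_spaced_positions(self):
        """Closed-form linear interpolation oracle."""
        fixes = make_fixes([0, 2000], [-10.0, -10.4], [52.0, 52.2])
        mids = [500, 1000, 1500]
        dives = make_dives([
            {"start_time": T0 + pd.Timedelta(seconds=m - 50),
             "end_time": T0 + pd.Timedelta(seconds=m + 50),
             "duration_s": 100.0}
            for m in mids
        ])
        out, _ = interpolate_dive_locations(fixes, dives)
        for lon, lat, m in zip(out["lon"], out["lat"], mids):
            w = m / 2000.0
            assert lon == pytest.approx((1 - w) * -10.0 + w * -10.4, abs=1e-12)
            assert lat == pytest.approx((1 - w) * 52.0 + w * 52.2, abs=1e-12)
        spacings = np.diff(out["lon"])
        assert np.allclose(spacings, spacings[0])

    def test_dives_outside_envelope_dropped_and_counted(self):
        fixes = make_fixes([1000, 2000], [-10.0, -10.1], [52.0, 52.1])
        dives = make_dives([
            {"start_time": T0, "end_time": T0 + pd.Timedelta(seconds=100),
             "duration_s": 100.0},
            {"start_time": T0 + pd.Timedelta(seconds=1400),
             "end_time": T0 + pd.Timedelta(seconds=1500), "duration_s": 100.0},
            {"start_time": T0 + pd.Timedelta(seconds=5000),
             "end_time": T0 + pd.Timedelta(seconds=5100), "duration_s": 100.0},
        ])
        out, drops = interpolate_dive_locations(fixes, dives)
        assert len(out) == 1
        assert drops["before_first_fix"] == 1
        assert drops["after_last_fix"] == 1
        assert len(dives) == len(out) + sum(drops.values())

    def test_seal_with_too_few_fixes_warns(self):
        fixes = make_fixes([0], [-10.0], [52.0])
        dives = make_dives([{}, {}])
        with pytest.warns(UserWarning, match="retained fixes"):
            out, drops = interpolate_dive_locations(fixes, dives)
        assert len(out) == 0
        assert drops["seal_too_few_fixes"] == 2

    @given(
        t_fix=st.lists(st.integers(0, 100_000), min_size=2, max_size=6, unique=True),
        lons=st.lists(st.floats(-11, -9), min_size=6, max_size=6),
        lats=st.lists(st.floats(51, 53), min_size=6, max_size=6),
        mid=st.integers(0, 100_000),
    )
    @settings(max_examples=100, deadline=None)
    def test_convexity(self, t_fix, lons, lats, mid):
        t_fix = sorted(t_fix)
        n = len(t_fix)
        fixes = make_fixes(t_fix, lons[:n], lats[:n])
        dives = make_dives([{"start_time": T0 + pd.Timedelta(seconds=mid - 10),
                             "end_time": T0 + pd.Timedelta(seconds=mid + 10),
                             "duration_s": 20.0}])
        out, _ = interpolate_dive_locations(fixes, dives)
        if len(out) == 0:
            assert mid < t_fix[0] or mid > t_fix[-1]
            return
        i = np.searchsorted(t_fix, mid, side="right") - 1
        i = min(max(i, 0), n - 2)
        eps = 1e-9
        assert min(lons[i], lons[i + 1]) - eps <= out["lon"].iloc[0] <= max(lons[i], lons[i + 1]) + eps
        assert min(lats[i], lats[i + 1]) - eps <= out["lat"].iloc[0] <= max(lats[i], lats[i + 1]) + eps


class TestErrorBound:
    def test_zero_when_moving_at_max_speed(self):
        inputs = InterpolationErrorInputs(
            t_bar=1800.0, d_bar=1800.0, s_max=1.0,
            mean_dive_duration_s=1000.0, mean_surface_duration_s=800.0,
        )
        assert error_from_inputs(inputs) == pytest.approx(0.0)

    def test_direct_evaluation(self):
        # s_max * t_bar = 2000 m, d_bar = 1500 m, n_bar = 5 -> 100 m
        inputs = InterpolationErrorInputs(
            t_bar=1000.0, d_bar=1500.0, s_max=2.0,
            mean_dive_duration_s=150.0, mean_surface_duration_s=50.0,
        )
        assert error_from_inputs(inputs) == pytest.approx(100.0)

    def test_doubling_cycles_halves_error(self):
        a = InterpolationErrorInputs(1000.0, 1500.0, 2.0, 150.0, 50.0)
        b = InterpolationErrorInputs(1000.0, 1500.0, 2.0, 75.0, 25.0)
        assert error_from_inputs(b) == pytest.approx(error_from_inputs(a) / 2.0)

    def test_clamps_n_bar_below_one(self):
        inputs = InterpolationErrorInputs(
            t_bar=100.0, d_bar=50.0, s_max=2.0,
            mean_dive_duration_s=300.0, mean_surface_duration_s=100.0,
        )
        with pytest.warns(UserWarning, match="clamping"):
            err = error_from_inputs(inputs)
        assert err == pytest.approx(2.0 * 100.0 - 50.0)

    def test_inputs_validation(self):
        with pytest.raises(ValueError):
            InterpolationErrorInputs(0.0, 1.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError, match="s_max"):
            InterpolationErrorInputs(100.0, 500.0, 1.0, 10.0, 10.0)

    def test_straight_track_near_zero_error(self):
        """Seal moving in a straight line at constant speed: s_max ~ d/t
        for every gap, so the bound collapses to ~0."""
        times = np.arange(0, 20) * 600.0
        lons = -10.0 + times * 1e-6
        lats = np.full_like(times, 52.0)
        fixes = make_fixes(times, lons, lats)
        dives = make_dives([
            {"start_time": T0 + pd.Timedelta(seconds=300 + i * 600),
             "end_time": T0 + pd.Timedelta(seconds=500 + i * 600),
             "duration_s": 200.0}
            for i in range(18)
        ])
        per_seal, pooled = interpolation_error(fixes, dives)
        assert per_seal["seal_01"] >= 0.0
        assert per_seal["seal_01"] < 1.0
        assert pooled < 1.0

    def test_nonnegative_after_clamping(self, small_dataset):
        _, fixes, dives = small_dataset
        from sealdive.trackproc import filter_fixes
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per_seal, pooled = interpolation_error(filter_fixes(fixes), dives)
        for err in per_seal.values():
            assert err >= 0.0
        assert pooled >= 0.0

    def test_haversine_known_value(self):
        # one degree of latitude is ~111.2 km
        d = haversine_m(0.0, 0.0, 0.0, 1.0)
        assert d == pytest.approx(111_195, rel=1e-3)
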