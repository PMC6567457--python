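import numpy as np
import pandas as pd
import pytest

from batseg import (
    FilterConfig,
    SimConfig,
    Trip,
    compute_steps,
    filter_track,
    generate_trip,
    read_track,
    regularize,
    subsample,
    write_track,
)
from batseg.projection import utm_forward, utm_forward_kruger
from batseg.tracks import TrackDataError, TrackFormatError


def make_trip(n=10, dt=15.0, speed=5.0):
    t = dt * np.arange(n)
    return Trip("t", t, speed * t, np.zeros(n), nominal_dt=dt)


class TestProjection:
    def test_snyder_and_kruger_series_agree_to_mm(self):
        rng = np.random.default_rng(0)
        lon = rng.uniform(-114.9, -109.1, 50)
        lat = rng.uniform(5.0, 60.0, 50)
        e1, n1 = utm_forward(lon, lat, zone=12)
        e2, n2 = utm_forward_kruger(lon, lat, zone=12)
        assert np.max(np.abs(e1 - e2)) < 1e-3
        assert np.max(np.abs(n1 - n2)) < 1e-3

    def test_central_meridian_maps_to_false_easting(self):
        e, n = utm_forward(-111.0, 0.0, zone=12)
        assert e == pytest.approx(500_000.0)
        assert n == pytest.approx(0.0)


class TestReadTrack:
    def test_xy_csv_identity_parse(self, tmp_path):
        p = tmp_path / "t.csv"
        pd.DataFrame(
            {"time_s": [0.0, 15.0, 30.0], "x": [0.0, 10.0, 20.0], "y": [0.0, 0.0, 5.0]}
        ).to_csv(p, index=False)
        trip = read_track(p)
        assert trip.n == 3
        assert np.allclose(trip.x, [0, 10, 20])

    def test_lonlat_csv_is_projected_to_utm(self, tmp_path):
        p = tmp_path / "t.csv"
        lon = np.array([-113.04, -113.03, -113.02])
        lat = np.array([28.88, 28.89, 28.90])
        pd.DataFrame(
            {
                "individual-local-identifier": "bat1",
                "timestamp": pd.date_range("2015-06-01", periods=3, freq="15s"),
                "location-long": lon,
                "location-lat": lat,
            }
        ).to_csv(p, index=False)
        trip = read_track(p, utm_zone=12)
        e, n = utm_forward(lon, lat, zone=12)
        assert np.allclose(trip.x, e)
        assert np.allclose(trip.y, n)
        assert trip.trip_id == "bat1"

    def test_shuffled_rows_sort_to_same_trip(self, tmp_path):
        df = pd.DataFrame(
            {"time_s": np.arange(5) * 15.0, "x": np.arange(5.0), "y": np.zeros(5)}
        )
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        df.to_csv(p1, index=False)
        df.sample(frac=1.0, random_state=3).to_csv(p2, index=False)
        t1, t2 = read_track(p1), read_track(p2)
        assert np.array_equal(t1.times, t2.times)
        assert np.array_equal(t1.x, t2.x)

    def test_missing_columns_is_format_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"foo": [1, 2]}).to_csv(p, index=False)
        with pytest.raises(TrackFormatError):
            read_track(p)

    def test_duplicate_timestamps_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        pd.DataFrame(
            {"time_s": [0.0, 0.0, 15.0], "x": [0, 1, 2], "y": [0, 0, 0]}
        ).to_csv(p, index=False)
        with pytest.raises(TrackDataError):
            read_track(p)

    def test_write_read_roundtrip(self, tmp_path):
        trip = make_trip(20)
        p = tmp_path / "rt.csv"
        write_track(trip, p)
        back = read_track(p)
        assert np.allclose(back.times, trip.times)
        assert np.allclose(back.x, trip.x)
        assert np.allclose(back.y, trip.y)


class TestFilterTrack:
    def test_near_roost_locations_removed(self):
        n = 150
        t = 15.0 * np.arange(n)
        # 30 points within 250 m of origin, 120 beyond
        d = np.concatenate([np.full(30, 100.0), np.full(120, 1000.0)])
        trip = Trip("t", t, d, np.zeros(n))
        out = filter_track(trip, (0.0, 0.0))
        assert out is not None and out.n == 120

    def test_short_track_rejected(self):
        n = 99
        trip = Trip("t", 15.0 * np.arange(n), np.full(n, 1e4), np.zeros(n))
        assert filter_track(trip, (0.0, 0.0)) is None

    def test_all_inside_radius_rejected(self):
        n = 150
        trip = Trip("t", 15.0 * np.arange(n), np.full(n, 10.0), np.zeros(n))
        assert filter_track(trip, (0.0, 0.0)) is None

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        n = 300
        trip = Trip("t", 15.0 * np.arange(n), rng.uniform(0, 2000, n), rng.uniform(0, 2000, n))
        cfg = FilterConfig(min_locations=10)
        once = filter_track(trip, (0.0, 0.0), cfg)
        twice = filter_track(once, (0.0, 0.0), cfg)
        assert np.array_equal(once.x, twice.x) and np.array_equal(once.times, twice.times)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            FilterConfig(exclusion_radius=-1)
        with pytest.raises(ValueError):
            FilterConfig(min_locations=1)


class TestComputeSteps:
    def test_constant_velocity_path(self):
        trip = make_trip(10, speed=5.0)
        s = compute_steps(trip)
        assert np.allclose(s.speed[1:], 5.0)
        assert np.allclose(s.turn_abs[1:-1], 0.0)
        assert np.isnan(s.speed[0]) and np.isnan(s.turn_signed[0]) and np.isnan(s.turn_signed[-1])

    def test_right_angle_geometry(self):
        # 75 m legs at 15 s: speed 5 m/s, 90 degree turn at the vertex
        trip = Trip("t", [0.0, 15.0, 30.0], [0.0, 75.0, 75.0], [0.0, 0.0, 75.0])
        s = compute_steps(trip)
        assert s.speed[1] == pytest.approx(5.0)
        assert s.turn_abs[1] == pytest.approx(90.0)

    def test_two_locations_per_trip_lack_full_metrics(self):
        total = 0
        for k in range(15):
            trip, _ = generate_trip(SimConfig(), seed=100 + k, n_fix=120)
            s = compute_steps(trip)
            total += int((~s.both_defined).sum())
        assert total == 30  # 2 structural omissions per trip

    def test_zero_length_step_leaves_turn_undefined(self):
        trip = Trip("t", [0.0, 15.0, 30.0, 45.0], [0.0, 10.0, 10.0, 20.0],
                    [0.0, 0.0, 0.0, 0.0])
        s = compute_steps(trip)
        assert s.speed[2] == 0.0
        assert np.isnan(s.turn_signed[1]) and np.isnan(s.turn_signed[2])


class TestRegularize:
    def test_already_regular_is_identity(self):
        trip = make_trip(20)
        (out,) = regularize(trip)
        assert np.array_equal(out.times, trip.times)
        assert np.allclose(out.x, trip.x)

    def test_missing_fix_interpolated_on_line(self):
        t = np.array([0.0, 15.0, 45.0, 60.0])
        trip = Trip("t", t, 5.0 * t, np.zeros(4))
        (out,) = regularize(trip, dt=15.0)
        assert out.n == 5
        assert out.x[2] == pytest.approx(5.0 * 30.0)

    def test_deleted_fixes_recovered_within_noise_envelope(self):
        cfg = SimConfig()
        trip, truth = generate_trip(cfg, seed=4, n_fix=300)
        rng = np.random.default_rng(0)
        keep = np.ones(trip.n, bool)
        interior = rng.choice(np.arange(1, trip.n - 1), size=30, replace=False)
        keep[interior] = False
        gappy = Trip("g", trip.times[keep], trip.x[keep], trip.y[keep])
        (out,) = regularize(gappy, dt=15.0)
        assert np.allclose(out.times, trip.times)
        # interpolated positions stay within a few noise+curvature lengths of truth
        err = np.hypot(out.x - truth.true_x, out.y - truth.true_y)
        assert np.quantile(err, 0.95) < 10 * cfg.gps_noise_sd

    def test_long_gap_splits_trip(self):
        t = np.concatenate([15.0 * np.arange(50), 15.0 * np.arange(50) + 50 * 15 + 3600])
        trip = Trip("t", t, np.arange(100.0), np.zeros(100))
        with pytest.warns(UserWarning, match="gap"):
            parts = regularize(trip, dt=15.0)
        assert len(parts) == 2

    def test_regularized_interior_speeds_all_defined(self):
        t = np.array([0.0, 15.0, 60.0, 75.0, 120.0])
        trip = Trip("t", t, np.linspace(0, 500, 5), np.zeros(5))
        (out,) = regularize(trip, dt=15.0)
        s = compute_steps(out)
        assert not np.isnan(s.speed[1:]).any()


class TestSubsample:
    def test_identity_interval(self):
        trip = make_trip(100)
        assert subsample(trip, 15.0) is trip

    def test_every_other_fix(self):
        trip = make_trip(100)
        out = subsample(trip, 30.0)
        assert out.n == 50
        assert out.nominal_dt == 30.0

    def test_non_multiple_interval_rejected(self):
        with pytest.raises(ValueError):
            subsample(make_trip(10), 20.0)

    def test_path_length_shrinks_on_tortuous_track(self):
        trip, _ = generate_trip(SimConfig(), seed=9, n_fix=400)
        s_fine = compute_steps(trip)
        s_coarse = compute_steps(subsample(trip, 60.0))
        # straight-line chords can only shorten the traversed path
        assert np.nansum(s_coarse.step_length) <= np.nansum(s_fine.step_length)
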