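import numpy as np
import pandas as pd
import pytest

from fieldgaze import gps_processing as gp
from fieldgaze.errors import DegenerateInputError, FormatError, OrderingError
from fieldgaze.records import GeoTrack
from fieldgaze.synthetic_data import FaultSpec, WalkScenario, simulate_walk_track

M_PER_DEG_LAT = gp.EARTH_RADIUS_M * np.pi / 180.0


def _track(t, lat, lon, quality=1.0, sats=10.0, precision=np.nan):
    n = len(t)
    return GeoTrack(
        pd.DataFrame(
            {
                "t": np.asarray(t, dtype=float),
                "lat": np.asarray(lat, dtype=float),
                "lon": np.asarray(lon, dtype=float),
                "quality": np.broadcast_to(quality, n).astype(float),
                "n_satellites": np.broadcast_to(sats, n).astype(float),
                "precision": np.broadcast_to(precision, n).astype(float),
            }
        )
    )


def _north_walk(n, speed_ms=1.0, dt=1.0, **kw):
    t = np.arange(n) * dt
    lat = 34.0 + np.degrees(speed_ms * t / gp.EARTH_RADIUS_M)
    return _track(t, lat, np.zeros(n), **kw)


class TestFixSpeed:
    def test_stationary(self):
        a = {"t": 0.0, "lat": 34.0, "lon": 33.0}
        b = {"t": 5.0, "lat": 34.0, "lon": 33.0}
        assert gp.fix_speed(a, b) == pytest.approx(0.0)

    def test_10m_in_12s(self):
        a = {"t": 0.0, "lat": 0.0, "lon": 0.0}
        b = {"t": 12.0, "lat": np.degrees(10.0 / gp.EARTH_RADIUS_M), "lon": 0.0}
        assert gp.fix_speed(a, b) == pytest.approx(3.0, rel=1e-9)

    def test_meridian_degree_closed_form(self):
        a = {"t": 0.0, "lat": 0.0, "lon": 0.0}
        b = {"t": 3600.0, "lat": 1.0, "lon": 0.0}
        expected = gp.EARTH_RADIUS_M * np.pi / 180.0 / 1000.0  # km per meridian degree
        assert gp.fix_speed(a, b) == pytest.approx(expected, rel=1e-9)
        assert gp.fix_speed(a, b) == pytest.approx(111.19, abs=0.01)

    def test_ordering_error(self):
        a = {"t": 1.0, "lat": 0.0, "lon": 0.0}
        with pytest.raises(OrderingError):
            gp.fix_speed(a, a)


class TestStrictRelaxedFlagging:
    def test_clean_walk_no_flags(self):
        report = gp.flag_outliers_rtk(_north_walk(60))  # 3.6 km/h
        assert report.removed == []
        assert report.n_flagged == 0

    def test_single_teleport_flags_only_itself(self):
        track = _north_walk(20)
        track.data.loc[10, "lat"] += 50.0 / M_PER_DEG_LAT  # 50 m jump
        report = gp.flag_outliers_rtk(track)
        assert report.removed == [10]
        assert report.reasons[10] == {"speed"}
        # greedy speed against last retained: neighbours stay
        assert 9 not in report.removed and 11 not in report.removed

    def test_quality_five_and_low_satellites_flagged(self):
        track = _north_walk(10)
        track.data.loc[3, "quality"] = 5
        track.data.loc[6, "n_satellites"] = 4
        report = gp.flag_outliers_rtk(track)
        assert report.reasons[3] == {"quality"}
        assert report.reasons[6] == {"satellites"}
        assert report.removed == [3, 6]

    def test_long_marginal_run_rescued_by_relaxed_tier(self):
        """35 s of 4-satellite fixes: strict flags the run, the >30 s gap
        escalates to the relaxed tier (4 not < 4), the run is retained."""
        track = _north_walk(60)
        track.data.loc[10:44, "n_satellites"] = 4.0  # inclusive slice: 35 fixes
        report = gp.flag_outliers_rtk(track)
        assert report.removed == []
        [run] = report.runs
        assert run["tier"] == "relaxed"
        assert run["span_s"] > 30.0
        assert len(run["rescued"]) == 35

    def test_short_marginal_run_stays_strict(self):
        track = _north_walk(60)
        track.data.loc[10:19, "n_satellites"] = 4.0  # 10 s < 30 s
        report = gp.flag_outliers_rtk(track)
        assert report.removed == list(range(10, 20))
        assert all(run["tier"] == "strict" for run in report.runs)

    def test_relaxed_tier_still_removes_truly_bad_fixes(self):
        track = _north_walk(60)
        track.data.loc[10:44, "n_satellites"] = 4.0
        track.data.loc[20, "n_satellites"] = 3.0  # bad under both tiers
        report = gp.flag_outliers_rtk(track)
        assert report.removed == [20]
        [run] = report.runs
        assert run["tier"] == "relaxed"

    def test_too_short_track(self):
        with pytest.raises(DegenerateInputError):
            gp.flag_outliers_rtk(_north_walk(1))


class TestCameraFlagging:
    def test_constant_precision_never_fires(self):
        report = gp.flag_outliers_camera(_north_walk(30, precision=2.0))
        assert report.removed == []

    def test_single_large_precision_flagged(self):
        prec = np.full(100, 1.0)
        prec[37] = 100.0
        track = _north_walk(100, precision=1.0)
        track.data["precision"] = prec
        report = gp.flag_outliers_camera(track)
        assert report.removed == [37]
        assert report.reasons[37] == {"precision"}

    def test_missing_precision_is_format_error(self):
        with pytest.raises(FormatError):
            gp.flag_outliers_camera(_north_walk(10))


class TestCleanTrack:
    def test_linear_midpoint_interpolation(self):
        track = _track([10.0, 11.0, 12.0], [34.670, 34.6705, 34.672], [33.040, 33.0405, 33.042])
        report = gp.flag_outliers_rtk(track)
        report.removed = [1]
        report.reasons[1] = {"speed"}
        cleaned = gp.clean_track(track, report)
        assert cleaned.lat[1] == pytest.approx(34.671)
        assert cleaned.lon[1] == pytest.approx(33.041)
        assert bool(cleaned.data["interpolated"].iloc[1]) is True
        assert report.interpolated == [1]

    def test_empty_removal_is_identity(self):
        track = _north_walk(20)
        report = gp.flag_outliers_rtk(track)
        cleaned = gp.clean_track(track, report)
        np.testing.assert_allclose(cleaned.lat, track.lat)
        np.testing.assert_allclose(cleaned.t, track.t)

    def test_cleaning_is_idempotent(self):
        track = _north_walk(40)
        track.data.loc[15, "lat"] += 40.0 / M_PER_DEG_LAT
        cleaned = gp.clean_track(track, gp.flag_outliers_rtk(track))
        again = gp.clean_track(cleaned, gp.flag_outliers_rtk(cleaned))
        pd.testing.assert_frame_equal(
            again.data.reset_index(drop=True), cleaned.data.reset_index(drop=True)
        )

    def test_leading_trailing_removed_are_dropped(self):
        track = _north_walk(10)
        track.data.loc[0, "quality"] = 5
        track.data.loc[9, "quality"] = 5
        report = gp.flag_outliers_rtk(track)
        cleaned = gp.clean_track(track, report)
        assert len(cleaned) == 8
        assert report.dropped_edges == [0, 9]

    def test_interpolated_points_lie_on_chord(self):
        track = _north_walk(30)
        track.data.loc[12:14, "quality"] = 5.0
        report = gp.flag_outliers_rtk(track)
        cleaned = gp.clean_track(track, report)
        t, lat = cleaned.t, cleaned.lat
        for i in (12, 13, 14):
            frac = (t[i] - t[11]) / (t[15] - t[11])
            assert lat[i] == pytest.approx(lat[11] + frac * (lat[15] - lat[11]), abs=1e-12)

    def test_recovers_injected_faults_on_synthetic_walk(self):
        faults = [FaultSpec(80.0 + 30 * i, displacement_m=25.0) for i in range(4)]
        scenario = WalkScenario(seed=9, duration_s=200.0, faults=faults)
        track, truth = simulate_walk_track(scenario)
        report = gp.flag_outliers_rtk(track)
        assert set(truth.fault_indices) <= set(report.removed)
        cleaned = gp.clean_track(track, report)
        # cleaned positions near ground truth at the faulted fixes
        for i in truth.fault_indices:
            if i in report.interpolated:
                err_m = float(
                    gp.haversine_m(cleaned.lat[i], cleaned.lon[i], truth.true_lat[i], truth.true_lon[i])
                )
                assert err_m < 5.0  # within ~2 walking steps of the true path


class TestTrackSummary:
    def test_constant_speed_has_zero_sd(self):
        s = gp.track_summary(_north_walk(20))
        assert s["mean_speed_kmh"] == pytest.approx(3.6, rel=1e-6)
        assert s["sd_speed_kmh"] == pytest.approx(0.0, abs=1e-6)

    def test_two_speed_closed_form(self):
        # 1 m/s then 2 m/s over 1 s steps: speeds [3.6, 7.2] km/h
        lat = 34.0 + np.degrees(np.array([0.0, 1.0, 3.0]) / gp.EARTH_RADIUS_M)
        s = gp.track_summary(_track([0.0, 1.0, 2.0], lat, np.zeros(3)))
        assert s["mean_speed_kmh"] == pytest.approx(5.4, rel=1e-6)
        assert s["sd_speed_kmh"] == pytest.approx(np.std([3.6, 7.2], ddof=1), rel=1e-6)

    def test_mean_speed_of_long_synthetic_walk(self):
        scenario = WalkScenario(
            seed=1, duration_s=2000.0, hold_s=0, calibration_s=0, serpentine_s=0, tail_s=0
        )
        track, _ = simulate_walk_track(scenario)
        s = gp.track_summary(track)
        # AR(1) speeds: effective sample size shrinks by (1-phi)/(1+phi)
        n_eff = s["n_fixes"] * (1 - scenario.speed_ar1) / (1 + scenario.speed_ar1)
        se = s["sd_speed_kmh"] / np.sqrt(n_eff)
        assert abs(s["mean_speed_kmh"] - scenario.mean_speed_kmh) < 3.0 * se
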