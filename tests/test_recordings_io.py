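import numpy as np
import pandas as pd
import pytest

from fieldgaze import recordings_io as rio
from fieldgaze.errors import EmptyInputError, FormatError, OrderingError, RangeError
from fieldgaze.records import CompassReading, GeoTrack, SessionManifest


def _gps_csv(tmp_path, rows, name="gps.csv", cols=("timestamp", "lat", "lon", "quality", "n_satellites")):
    path = tmp_path / name
    pd.DataFrame(rows, columns=list(cols)).to_csv(path, index=False)
    return path


class TestGpsTable:
    def test_identity_read(self, tmp_path):
        rows = [[0.0, 34.67, 33.04, 1, 10], [1.0, 34.671, 33.041, 1, 10], [2.0, 34.672, 33.042, 1, 10]]
        track = rio.read_gps_table(_gps_csv(tmp_path, rows), source="rtk")
        assert len(track) == 3
        assert track.n_rejected == 0
        np.testing.assert_allclose(track.t, [0.0, 1.0, 2.0])

    def test_missing_satellite_column_is_format_error(self, tmp_path):
        path = _gps_csv(tmp_path, [[0, 34.67, 33.04, 1]], cols=("timestamp", "lat", "lon", "quality"))
        with pytest.raises(FormatError, match="n_satellites"):
            rio.read_gps_table(path, source="rtk")

    def test_duplicated_timestamp_is_ordering_error(self, tmp_path):
        rows = [[0.0, 34.67, 33.04, 1, 10], [1.0, 34.671, 33.041, 1, 10], [1.0, 34.672, 33.042, 1, 10]]
        with pytest.raises(OrderingError, match="row 2"):
            rio.read_gps_table(_gps_csv(tmp_path, rows), source="rtk")

    def test_unparseable_rows_counted_not_dropped_silently(self, tmp_path):
        rows = [[0.0, 34.67, 33.04, 1, 10], [1.0, "oops", 33.041, 1, 10], [2.0, 34.672, 33.042, 1, 10]]
        track = rio.read_gps_table(_gps_csv(tmp_path, rows), source="rtk")
        assert len(track) + track.n_rejected == 3
        assert track.n_rejected == 1

    def test_camera_source_requires_precision(self, tmp_path):
        path = _gps_csv(tmp_path, [[0, 34.67, 33.04, 1, 10]])
        with pytest.raises(FormatError, match="precision"):
            rio.read_gps_table(path, source="camera")

    def test_csv_round_trip(self, tmp_path, simple_track):
        out = tmp_path / "rt.csv"
        rio.write_gps_table(simple_track, out)
        back = rio.read_gps_table(out, source="rtk")
        pd.testing.assert_frame_equal(back.data, simple_track.data)


class TestGpx:
    def test_gpx_round_trip(self, tmp_path, simple_track):
        out = tmp_path / "track.gpx"
        rio.write_gpx_track(simple_track, out)
        back = rio.read_gpx_track(out)
        np.testing.assert_allclose(back.lat, simple_track.lat, atol=1e-8)
        np.testing.assert_allclose(back.lon, simple_track.lon, atol=1e-8)
        assert back.source == "camera"
        # quality unknown in GPX
        assert np.isnan(back.data["quality"]).all()


class TestImuTable:
    def test_rate_estimate(self, tmp_path):
        t = np.arange(110) / 110.0
        path = tmp_path / "imu.csv"
        pd.DataFrame({"timestamp": t, "yaw": np.zeros(110)}).to_csv(path, index=False)
        trace = rio.read_imu_table(path)
        assert trace.estimated_rate_hz == pytest.approx(110.0, rel=1e-6)

    def test_yaw_out_of_range(self, tmp_path):
        path = tmp_path / "imu.csv"
        pd.DataFrame({"timestamp": [0.0], "yaw": [181.0]}).to_csv(path, index=False)
        with pytest.raises(RangeError):
            rio.read_imu_table(path)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "imu.csv"
        pd.DataFrame({"timestamp": [], "yaw": []}).to_csv(path, index=False)
        with pytest.raises(EmptyInputError):
            rio.read_imu_table(path)


class TestAnnotations:
    @staticmethod
    def _write(tmp_path, rows):
        path = tmp_path / "ann.csv"
        pd.DataFrame(rows, columns=["recording_id", "target", "frame", "x", "y", "w", "h"]).to_csv(
            path, index=False
        )
        return path

    def test_box_center_midpoint(self, tmp_path):
        df = rio.read_validation_annotations(self._write(tmp_path, [["r1", 1, 0, 90, 190, 20, 20]]))
        assert df.loc[0, "cx"] == pytest.approx(100.0)
        assert df.loc[0, "cy"] == pytest.approx(200.0)
        assert df.loc[0, "size_px"] == pytest.approx(20.0)

    def test_target_index_out_of_range(self, tmp_path):
        with pytest.raises(RangeError):
            rio.read_validation_annotations(self._write(tmp_path, [["r1", 11, 0, 0, 0, 5, 5]]))

    def test_negative_box_extent(self, tmp_path):
        with pytest.raises(FormatError):
            rio.read_validation_annotations(self._write(tmp_path, [["r1", 1, 0, 0, 0, -5, 5]]))

    def test_full_study_count_650(self, tmp_path):
        rows = [
            [f"rec{r}", t, f, 10.0 * t, 10.0 * t, 20, 20]
            for r in range(13)
            for t in range(1, 11)
            for f in range(5)
        ]
        df = rio.read_validation_annotations(self._write(tmp_path, rows))
        assert len(df) == 650


class TestManifest:
    def test_yaml_load_and_validation(self, tmp_path):
        gps = tmp_path / "gps.csv"
        gps.write_text("timestamp,lat,lon,quality,n_satellites\n0,34.67,33.04,1,10\n")
        (tmp_path / "m.yaml").write_text(
            "session_id: '2_3'\nplanned_duration_min: 10\ndeclination_deg: 3.9\n"
            "streams:\n  gps: gps.csv\n"
        )
        m = rio.load_manifest(tmp_path / "m.yaml")
        assert m.session_id == "2_3"
        assert m.streams["gps"].exists()

    def test_missing_stream_file_rejected(self, tmp_path):
        (tmp_path / "m.yaml").write_text(
            "session_id: '1_1'\nplanned_duration_min: 10\nstreams:\n  gps: nope.csv\n"
        )
        with pytest.raises(FileNotFoundError):
            rio.load_manifest(tmp_path / "m.yaml")

    def test_invalid_constants_rejected(self):
        with pytest.raises(RangeError):
            SessionManifest(session_id="1_1", planned_duration_min=0)
        with pytest.raises(RangeError):
            SessionManifest(session_id="1_1", planned_duration_min=10, declination_deg=45)


class TestCompassAndPointing:
    def test_compass_round_trip(self, tmp_path):
        readings = [CompassReading("1_1", "start", 39.5), CompassReading("1_1", "end", 215.0)]
        rio.write_compass_readings(readings, tmp_path / "c.csv")
        assert rio.read_compass_readings(tmp_path / "c.csv") == readings

    def test_compass_heading_range(self):
        with pytest.raises(RangeError):
            CompassReading("1_1", "start", 360.0)
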