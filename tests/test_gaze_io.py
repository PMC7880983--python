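"""Gaze/event file round trips, sentinel handling, and degree conversion."""

import numpy as np
import pytest

from fixaqc import gaze_io
from fixaqc.errors import FormatError, IntegrityError, SchemaError
from fixaqc.events import MicrosaccadeEvent
from fixaqc.recording import ScreenGeometry
from fixaqc.synthetic import SyntheticConfig, generate_recording

from conftest import make_recording

GEOM = ScreenGeometry(resolution=(1920, 1080), size_cm=(52.8, 29.7), distance_cm=63.0)

SCHEMA = {
    "columns": {
        "time": "t", "left_x": "lx", "left_y": "ly", "left_pupil": "lp",
        "right_x": "rx", "right_y": "ry", "right_pupil": "rp",
    },
    "missing": -32768,
    "time_unit": "ms",
    "unit": "px",
}


def _write(tmp_path, rows, header="t,lx,ly,lp,rx,ry,rp"):
    p = tmp_path / "gaze.csv"
    p.write_text(header + "\n" + "\n".join(rows) + "\n")
    return p


class TestReadGaze:
    def test_sentinel_marks_exactly_one_sample_invalid(self, tmp_path):
        rows = ["0,100,200,900,100,200,900",
                "1,-32768,201,901,101,201,901",
                "2,102,202,902,102,202,902",
                "3,103,203,903,103,203,903"]
        rec = gaze_io.read_gaze(_write(tmp_path, rows), SCHEMA)
        assert (~rec.left.valid).sum() == 1 and not rec.left.valid[1]
        assert rec.right.valid.all()
        assert np.isnan(rec.left.x[1])  # no silent sentinel leakage

    def test_millisecond_timestamps_converted_to_seconds(self, tmp_path):
        rows = [f"{t},1,1,9,1,1,9" for t in (0, 1, 2, 3)]
        rec = gaze_io.read_gaze(_write(tmp_path, rows), SCHEMA)
        np.testing.assert_allclose(rec.time, [0, 0.001, 0.002, 0.003])
        assert rec.nominal_fs == pytest.approx(1000.0)

    def test_missing_column_is_schema_error(self, tmp_path):
        p = _write(tmp_path, ["0,1,1,9,1,1", "1,1,1,9,1,1"], header="t,lx,ly,lp,rx,ry")
        with pytest.raises(SchemaError):
            gaze_io.read_gaze(p, SCHEMA)

    def test_non_monotone_timestamps_is_format_error(self, tmp_path):
        rows = ["0,1,1,9,1,1,9", "2,1,1,9,1,1,9", "1,1,1,9,1,1,9"]
        with pytest.raises(FormatError):
            gaze_io.read_gaze(_write(tmp_path, rows), SCHEMA)

    def test_round_trip_preserves_synthetic_recording(self, tmp_path):
        rec, _ = generate_recording(SyntheticConfig(duration=1.0, blink_rate_per_min=30.0,
                                                    seed=7))
        path = tmp_path / "rt.csv"
        gaze_io.write_gaze(rec, path)
        back = gaze_io.read_gaze(path, gaze_io.default_schema(fs=rec.nominal_fs))
        np.testing.assert_allclose(back.time, rec.time, atol=1e-8)
        for eye in ("left", "right"):
            a, b = rec.eye(eye), back.eye(eye)
            np.testing.assert_array_equal(a.valid, b.valid)
            np.testing.assert_allclose(a.x[a.valid], b.x[b.valid], rtol=1e-6)
            np.testing.assert_allclose(a.y[a.valid], b.y[b.valid], rtol=1e-6)


class TestPxToDeg:
    @pytest.mark.parametrize(
        "px, expected_deg",
        [
            ((960.0, 540.0), (0.0, 0.0)),                       # screen center
            ((960.0 + 63 / (52.8 / 1920), 540.0), (45.0, 0.0)),  # 63 cm right at 63 cm
            ((960.0 + 1 / (52.8 / 1920), 540.0),
             (np.degrees(np.arctan(1 / 63)), 0.0)),              # 1 cm right: 0.9095 deg
        ],
    )
    def test_known_pixel_positions(self, px, expected_deg):
        rec = make_recording([px[0]] * 4, [px[1]] * 4, unit="px")
        deg = gaze_io.px_to_deg(rec, GEOM)
        assert deg.left.x[0] == pytest.approx(expected_deg[0], abs=1e-9)
        assert deg.left.y[0] == pytest.approx(expected_deg[1], abs=1e-9)

    def test_upward_pixels_map_to_positive_degrees(self):
        rec = make_recording([960.0] * 4, [440.0] * 4, unit="px")  # above center
        assert gaze_io.px_to_deg(rec, GEOM).left.y[0] > 0

    def test_odd_symmetry_and_monotonicity_about_center(self, rng):
        offs = np.sort(rng.uniform(0, 900, 20))
        rec_r = make_recording(960 + offs, [540.0] * 20, unit="px")
        rec_l = make_recording(960 - offs, [540.0] * 20, unit="px")
        xr = gaze_io.px_to_deg(rec_r, GEOM).left.x
        xl = gaze_io.px_to_deg(rec_l, GEOM).left.x
        np.testing.assert_allclose(xr, -xl, atol=1e-12)
        assert np.all(np.diff(xr) >= 0)

    def test_noop_with_warning_when_already_degrees(self):
        rec = make_recording([0.5] * 4, unit="deg")
        with pytest.warns(UserWarning):
            out = gaze_io.px_to_deg(rec, GEOM)
        np.testing.assert_array_equal(out.left.x, rec.left.x)

    def test_validity_mask_preserved(self):
        valid = np.array([True, False, True, True])
        rec = make_recording([960.0] * 4, [540.0] * 4, valid=valid, unit="px")
        out = gaze_io.px_to_deg(rec, GEOM)
        np.testing.assert_array_equal(out.left.valid, valid)


def _evt(onset, offset, eye="binocular", **kw):
    base = dict(duration_ms=(offset - onset) * 1000, amplitude=0.3,
                displacement=0.25, direction=10.0, peak_velocity=25.0)
    base.update(kw)
    return MicrosaccadeEvent(onset=onset, offset=offset, eye=eye, **base)


class TestEventTables:
    def test_empty_list_writes_header_only(self, tmp_path):
        p = tmp_path / "e.csv"
        gaze_io.write_events([], p)
        lines = p.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].split(",") == gaze_io.EVENT_HEADER

    def test_two_events_write_three_lines_and_round_trip(self, tmp_path):
        events = [_evt(0.1, 0.12), _evt(0.5, 0.53, amplitude=0.7)]
        p = tmp_path / "e.csv"
        gaze_io.write_events(events, p)
        assert len(p.read_text().strip().splitlines()) == 3
        back = gaze_io.read_events(p)
        for a, b in zip(events, back):
            for f in ("onset", "offset", "duration_ms", "amplitude",
                      "displacement", "direction", "peak_velocity"):
                assert getattr(a, f) == pytest.approx(getattr(b, f), rel=1e-6)
            assert a.eye == b.eye

    def test_overlapping_same_eye_events_rejected(self, tmp_path):
        events = [_evt(0.1, 0.2, eye="left"), _evt(0.15, 0.3, eye="left")]
        with pytest.raises(IntegrityError):
            gaze_io.write_events(events, tmp_path / "e.csv")

    def test_unsorted_events_rejected(self, tmp_path):
        events = [_evt(0.5, 0.53), _evt(0.1, 0.12)]
        with pytest.raises(IntegrityError):
            gaze_io.write_events(events, tmp_path / "e.csv")


def test_validation_round_trip(tmp_path):
    from fixaqc.recording import ValidationSequence

    seq = ValidationSequence(targets=[(1.0, -2.0, 0.5), (0.0, 3.0, 2.5)])
    p = tmp_path / "val.csv"
    gaze_io.write_validation(seq, p)
    back = gaze_io.read_validation(p)
    assert back.targets == seq.targets
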