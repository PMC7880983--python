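"""Reading/writing tabular gaze data and converting pixels to degrees.

Gaze files are plain delimited text; a schema config (dict or YAML file)
maps column names onto roles and declares the device's missing-data
sentinel (for instance ``nan`` for a Tobii Spectrum, ``-32768`` for an
EyeLink).  Internally missing data are carried as a validity mask — the
numeric arrays downstream never see sentinel values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, IntegrityError, SchemaError
from .events import MicrosaccadeEvent
from .recording import EyeChannel, GazeRecording, ScreenGeometry, ValidationSequence

_ROLE_COLUMNS = ("time", "left_x", "left_y", "left_pupil",
                 "right_x", "right_y", "right_pupil")

_TIME_SCALE = {"s": 1.0, "ms": 1e-3, "us": 1e-6}

EVENT_HEADER = ["onset_s", "offset_s", "duration_ms", "amplitude_deg",
                "displacement_deg", "direction_deg", "peak_velocity_deg_s", "eye"]


def load_schema(schema) -> dict:
    """Accept a schema dict or a path to a YAML schema file."""
    if isinstance(schema, (str, Path)):
        with open(schema) as fh:
            schema = yaml.safe_load(fh)
    if not isinstance(schema, dict) or "columns" not in schema:
        raise SchemaError("schema must be a mapping with a 'columns' entry")
    return schema


def read_gaze(path, schema, sep: str = ",") -> GazeRecording:
    """Read a delimited gaze file into a :class:`GazeRecording`.

    Schema keys: ``columns`` (role -> column name for the roles ``time``,
    ``left_x``, ``left_y``, ``left_pupil``, ``right_x``, ``right_y``,
    ``right_pupil``), ``missing`` (sentinel value, e.g. ``"nan"`` or
    ``-32768``), ``time_unit`` (``s``/``ms``/``us``, default ``s``),
    ``unit`` (``px``/``deg``, default ``px``), optional ``fs`` (Hz, else
    inferred from the median sampling interval) and ``meta``.
    """
    schema = load_schema(schema)
    cols = schema["columns"]
    missing = [role for role in _ROLE_COLUMNS if role not in cols]
    if missing:
        raise SchemaError(f"schema lacks roles: {', '.join(missing)}")
    df = pd.read_csv(path, sep=sep)
    absent = [cols[r] for r in _ROLE_COLUMNS if cols[r] not in df.columns]
    if absent:
        raise SchemaError(f"file {path} lacks columns: {', '.join(absent)}")

    time_unit = schema.get("time_unit", "s")
    if time_unit not in _TIME_SCALE:
        raise SchemaError(f"unknown time unit {time_unit!r}")
    time = pd.to_numeric(df[cols["time"]], errors="coerce").to_numpy(float)
    time = time * _TIME_SCALE[time_unit]
    if np.any(~np.isfinite(time)) or np.any(np.diff(time) <= 0):
        raise FormatError(f"{path}: timestamps must be finite and strictly increasing")

    sentinel = schema.get("missing", "nan")
    channels = {}
    for eye in ("left", "right"):
        arrs = {}
        invalid = np.zeros(len(df), dtype=bool)
        for axis in ("x", "y", "pupil"):
            col = df[cols[f"{eye}_{axis}"]]
            bad = _sentinel_mask(col, sentinel)
            vals = pd.to_numeric(col, errors="coerce").to_numpy(float)
            bad |= ~np.isfinite(vals)
            invalid |= bad
            arrs[axis] = vals
        channels[eye] = EyeChannel(arrs["x"], arrs["y"], arrs["pupil"], ~invalid)

    fs = schema.get("fs")
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(time))) if len(time) > 1 else 0.0
    return GazeRecording(
        time=time, nominal_fs=float(fs), left=channels["left"],
        right=channels["right"], unit=schema.get("unit", "px"),
        meta=dict(schema.get("meta", {})),
    )


def _sentinel_mask(col: pd.Series, sentinel) -> np.ndarray:
    if isinstance(sentinel, str) and sentinel.lower() == "nan":
        return col.astype(str).str.strip().str.lower().eq("nan").to_numpy()
    sval = float(sentinel)
    vals = pd.to_numeric(col, errors="coerce").to_numpy(float)
    with np.errstate(invalid="ignore"):
        return vals == sval


def write_gaze(rec: GazeRecording, path) -> None:
    """Write a recording as CSV; invalid samples are emitted as ``nan``."""
    data = {"time_s": rec.time}
    for eye, ch in rec.eyes():
        data[f"{eye}_x"] = np.where(ch.valid, ch.x, np.nan)
        data[f"{eye}_y"] = np.where(ch.valid, ch.y, np.nan)
        data[f"{eye}_pupil"] = np.where(ch.valid, ch.pupil, np.nan)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


def default_schema(fs: float | None = None, unit: str = "deg") -> dict:
    """Schema matching the column layout produced by :func:`write_gaze`."""
    return {
        "columns": {
            "time": "time_s",
            "left_x": "left_x", "left_y": "left_y", "left_pupil": "left_pupil",
            "right_x": "right_x", "right_y": "right_y", "right_pupil": "right_pupil",
        },
        "missing": "nan",
        "time_unit": "s",
        "unit": unit,
        **({"fs": fs} if fs is not None else {}),
    }


def px_to_deg(rec: GazeRecording, geom: ScreenGeometry) -> GazeRecording:
    """Convert pixel gaze coordinates to degrees of visual angle.

    Degrees are measured from the screen center with a per-axis arctangent,
    rightward positive x and upward positive y (the pixel y axis, which
    grows downward from the top-left origin, is flipped).  Validity masks
    are untouched.  A recording already in degrees is returned unchanged
    with a warning.
    """
    if rec.unit == "deg":
        warnings.warn("recording already in degrees; px_to_deg is a no-op")
        return rec
    out = rec.copy()
    cx = geom.resolution[0] / 2.0
    cy = geom.resolution[1] / 2.0
    cm_per_px_x = geom.size_cm[0] / geom.resolution[0]
    cm_per_px_y = geom.size_cm[1] / geom.resolution[1]
    for _, ch in out.eyes():
        x_cm = (ch.x - cx) * cm_per_px_x
        y_cm = (cy - ch.y) * cm_per_px_y  # flip: screen y grows downward
        ch.x = np.degrees(np.arctan2(x_cm, geom.distance_cm))
        ch.y = np.degrees(np.arctan2(y_cm, geom.distance_cm))
    out.unit = "deg"
    return out


def write_events(events: list[MicrosaccadeEvent], path) -> None:
    """Write an event table as CSV with the documented header.

    Events must be sorted by onset, with no overlap between events of the
    same eye; violations raise :class:`IntegrityError`.
    """
    _check_event_integrity(events)
    rows = []
    for e in events:
        d = asdict(e)
        rows.append([d["onset"], d["offset"], d["duration_ms"], d["amplitude"],
                     d["displacement"], d["direction"], d["peak_velocity"], d["eye"]])
    pd.DataFrame(rows, columns=EVENT_HEADER).to_csv(path, index=False, float_format="%.9g")


def read_events(path) -> list[MicrosaccadeEvent]:
    """Read an event table written by :func:`write_events` (or any CSV with
    the same header)."""
    df = pd.read_csv(path)
    missing = [c for c in EVENT_HEADER if c not in df.columns]
    if missing:
        raise SchemaError(f"event file lacks columns: {', '.join(missing)}")
    return [
        MicrosaccadeEvent(
            onset=float(r.onset_s), offset=float(r.offset_s),
            duration_ms=float(r.duration_ms), amplitude=float(r.amplitude_deg),
            displacement=float(r.displacement_deg), direction=float(r.direction_deg),
            peak_velocity=float(r.peak_velocity_deg_s), eye=str(r.eye),
        )
        for r in df.itertuples()
    ]


def _check_event_integrity(events: list[MicrosaccadeEvent]) -> None:
    onsets = [e.onset for e in events]
    if onsets != sorted(onsets):
        raise IntegrityError("events are not sorted by onset")
    last_offset: dict[str, float] = {}
    for e in events:
        if e.eye in last_offset and e.onset < last_offset[e.eye] - 1e-12:
            raise IntegrityError(f"overlapping {e.eye}-eye events at onset {e.onset}")
        last_offset[e.eye] = max(last_offset.get(e.eye, -math.inf), e.offset)


def read_validation(path) -> ValidationSequence:
    """Read a validation-target CSV (columns target_x_deg, target_y_deg, onset_s)."""
    df = pd.read_csv(path)
    need = ("target_x_deg", "target_y_deg", "onset_s")
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise SchemaError(f"validation file lacks columns: {', '.join(missing)}")
    return ValidationSequence(
        targets=[(float(x), float(y), float(t))
                 for x, y, t in zip(df.target_x_deg, df.target_y_deg, df.onset_s)]
    )


def write_validation(seq: ValidationSequence, path) -> None:
    pd.DataFrame(seq.targets, columns=["target_x_deg", "target_y_deg", "onset_s"]
                 ).to_csv(path, index=False, float_format="%.9g")
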