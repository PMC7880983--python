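"""Preprocessing: single-sample interpolation, blink masking, Bartlett lowpass.

The processing order mirrors common practice for video eye trackers that
intermittently drop single samples: isolated one-sample losses are repaired
by linear interpolation first, then blink segments found in the pupil
signal are removed together with a padding margin (default 200 ms on each
side) to exclude artifacts around blink on- and offsets, and finally the
gaze signal that feeds event detection is lowpass filtered with a 20-ms
triangular (Bartlett) kernel.  Quality metrics are computed on unfiltered
degree-converted data; only detection consumes the filtered signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .recording import GazeRecording, valid_segments


@dataclass(frozen=True)
class BlinkMaskParams:
    """Blink exclusion rule: padding and how a missing pupil is recognized.

    ``pupil_missing_rule='nan'`` fires where the pupil sample is invalid/NaN
    (Tobii-style); ``'threshold'`` fires where the pupil area falls below
    ``pupil_threshold`` device units (EyeLink-style, default 20).
    """

    pad_ms: float = 200.0
    pupil_missing_rule: str = "nan"   # "nan" | "threshold"
    pupil_threshold: float = 20.0

    def __post_init__(self) -> None:
        if self.pad_ms < 0:
            raise ValueError("pad_ms must be >= 0")
        if self.pupil_missing_rule not in ("nan", "threshold"):
            raise ValueError("pupil_missing_rule must be 'nan' or 'threshold'")


@dataclass(frozen=True)
class FilterParams:
    """Bartlett (triangular) lowpass window length in milliseconds."""

    window_ms: float = 20.0

    def __post_init__(self) -> None:
        if self.window_ms <= 0:
            raise ValueError("window_ms must be > 0")


def interpolate_single_samples(rec: GazeRecording) -> GazeRecording:
    """Repair isolated single invalid samples by linear interpolation.

    An invalid sample whose two immediate neighbours are both valid is
    replaced by the midpoint of the neighbours (positions and pupil) and
    marked valid + interpolated.  Runs of two or more invalid samples are
    left untouched.  Idempotent.
    """
    out = rec.copy()
    for _, ch in out.eyes():
        v = ch.valid
        if len(v) < 3:
            continue
        iso = (~v[1:-1]) & v[:-2] & v[2:]
        idx = np.flatnonzero(iso) + 1
        for arr in (ch.x, ch.y, ch.pupil):
            arr[idx] = 0.5 * (arr[idx - 1] + arr[idx + 1])
        ch.valid[idx] = True
        ch.interpolated[idx] = True
    return out


def mask_blinks(
    rec: GazeRecording, params: BlinkMaskParams = BlinkMaskParams()
) -> tuple[GazeRecording, list[tuple[float, float]]]:
    """Mask blink segments found in the pupil signal, padded on both sides.

    Contiguous runs where the pupil rule fires in *either* eye are extended
    by ``pad_ms`` on each side; samples inside the (merged) extended runs
    are marked invalid in both eyes.  Returns the masked recording and the
    extended intervals in seconds.  Never re-validates a sample.
    """
    out = rec.copy()
    n = out.n_samples
    fires = np.zeros(n, dtype=bool)
    for _, ch in out.eyes():
        if params.pupil_missing_rule == "nan":
            fires |= ~np.isfinite(ch.pupil) | ~ch.valid
        else:
            with np.errstate(invalid="ignore"):
                fires |= (ch.pupil < params.pupil_threshold) | ~np.isfinite(ch.pupil) | ~ch.valid
    pad = int(round(params.pad_ms * out.nominal_fs / 1000.0))
    if not fires.any():
        return out, []
    if 2 * pad >= n:
        warnings.warn("blink padding exceeds recording length; whole recording masked")
    mask = np.zeros(n, dtype=bool)
    intervals: list[tuple[int, int]] = []
    for seg in valid_segments(fires):
        a = max(0, seg.start - pad)
        b = min(n, seg.stop + pad)
        if intervals and a <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], b))
        else:
            intervals.append((a, b))
    for a, b in intervals:
        mask[a:b] = True
    for _, ch in out.eyes():
        ch.valid &= ~mask
        ch.mask_invalid_positions()
    dt = out.dt
    return out, [(out.time[a], out.time[b - 1] + dt) for a, b in intervals]


def bartlett_kernel(fs: float, window_ms: float = 20.0) -> np.ndarray:
    """Triangular kernel of length round(window_ms*fs/1000) forced odd,
    normalized to unit sum (21 taps at 1000 Hz, 25 at 1200, 13 at 600)."""
    n = int(round(window_ms * fs / 1000.0))
    if n % 2 == 0:
        n += 1
    n = max(n, 3)
    w = np.bartlett(n + 2)[1:-1]  # strictly positive taps; endpoints of np.bartlett are 0
    return w / w.sum()


def bartlett_lowpass(
    signal: np.ndarray, fs: float, params: FilterParams = FilterParams()
) -> np.ndarray:
    """Zero-phase triangular smoothing of one contiguous (fully valid) series.

    The symmetric kernel is centered on each sample; near the edges the
    truncated kernel is renormalized over the available samples, so no data
    are fabricated beyond the segment.  Segments shorter than the kernel
    are returned unfiltered with a warning.
    """
    x = np.asarray(signal, dtype=float)
    w = bartlett_kernel(fs, params.window_ms)
    if len(x) < len(w):
        warnings.warn(f"segment of {len(x)} samples shorter than {len(w)}-tap kernel; left unfiltered")
        return x.copy()
    num = np.convolve(x, w, mode="same")
    den = np.convolve(np.ones_like(x), w, mode="same")
    return num / den


def filter_recording(
    rec: GazeRecording, params: FilterParams = FilterParams()
) -> GazeRecording:
    """Apply the Bartlett lowpass to each valid segment of each eye/axis."""
    out = rec.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _, ch in out.eyes():
            for arr in (ch.x, ch.y):
                for seg in valid_segments(ch.valid):
                    arr[seg] = bartlett_lowpass(arr[seg], out.nominal_fs, params)
    out.meta = {**out.meta, "filtered": True}
    return out
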