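"""Microsaccade event properties, the main sequence, and average waveforms.

An event's *amplitude* is its maximum excursion during the event interval
(the diagonal of the bounding box of the trajectory), while *displacement*
is the straight-line distance between onset and offset; amplitude exceeds
displacement whenever the movement overshoots.  Direction follows the
convention 0 deg = rightward, 90 deg = upward.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import FixaqcError, UndefinedMetricError
from .recording import GazeRecording


@dataclass
class MicrosaccadeEvent:
    """A detected (or injected) microsaccade.

    Times in seconds, duration in ms, amplitude/displacement in degrees,
    direction in degrees within [0, 360), peak velocity in deg/s.  The event
    interval is half-open: ``onset`` is the time of the first sample and
    ``offset`` the end of the last sample, so ``duration = offset - onset``.
    """

    onset: float
    offset: float
    duration_ms: float
    amplitude: float
    displacement: float
    direction: float
    peak_velocity: float
    eye: str  # "left" | "right" | "binocular"

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise FixaqcError(f"event offset {self.offset} <= onset {self.onset}")

    def overlaps(self, other: "MicrosaccadeEvent") -> bool:
        """True when the half-open intervals share at least part of a sample."""
        return self.onset < other.offset and other.onset < self.offset


@dataclass
class MainSequenceFit:
    """Linear amplitude/peak-velocity relation fitted by ordinary least squares."""

    slope: float          # (deg/s) per deg
    intercept: float      # deg/s
    n: int
    residual_sd: float    # deg/s
    r_value: float


@dataclass
class WaveformBundle:
    """Normalized horizontal event waveforms on a shared time base.

    ``time_ms`` runs from 0 (event onset); ``traces`` is (n_events, n_time)
    with each row scaled to peak at +1; ``average`` is the pointwise mean.
    """

    time_ms: np.ndarray
    traces: np.ndarray
    average: np.ndarray


def annotate_interval(
    rec: GazeRecording,
    a: int,
    b: int,
    eye: str,
    vx: np.ndarray | None = None,
    vy: np.ndarray | None = None,
    amplitude_rule: str = "bbox",
) -> MicrosaccadeEvent:
    """Compute event properties over sample interval [a, b] (inclusive) of one eye.

    Amplitude is by default the bounding-box diagonal of the trajectory
    ("maximum excursion"); ``amplitude_rule='from_onset'`` instead uses the
    maximum distance from the onset sample.  Peak velocity is the largest
    2-D speed among interval samples where the velocity is defined; if no
    velocity signal is supplied it is estimated from first differences.
    """
    ch = rec.eye(eye)
    if not ch.valid[a:b + 1].all():
        raise FixaqcError("event interval touches invalid samples")
    x = ch.x[a:b + 1]
    y = ch.y[a:b + 1]
    if amplitude_rule == "bbox":
        amp = math.hypot(x.max() - x.min(), y.max() - y.min())
    elif amplitude_rule == "from_onset":
        amp = float(np.max(np.hypot(x - x[0], y - y[0])))
    else:
        raise ValueError(f"unknown amplitude_rule {amplitude_rule!r}")
    dx = x[-1] - x[0]
    dy = y[-1] - y[0]
    disp = math.hypot(dx, dy)
    theta = math.degrees(math.atan2(dy, dx)) % 360.0
    if vx is not None and vy is not None:
        speed = np.hypot(vx[a:b + 1], vy[a:b + 1])
        speed = speed[np.isfinite(speed)]
    else:
        speed = np.array([])
    if speed.size:
        vpeak = float(speed.max())
    else:
        vpeak = float(np.max(np.hypot(np.diff(x), np.diff(y))) / rec.dt) if b > a else disp / rec.dt
    onset = float(rec.time[a])
    offset = float(rec.time[b]) + rec.dt
    return MicrosaccadeEvent(
        onset=onset,
        offset=offset,
        duration_ms=(offset - onset) * 1000.0,
        amplitude=amp,
        displacement=disp,
        direction=theta,
        peak_velocity=vpeak,
        eye=eye,
    )


def merge_binocular_annotations(
    left: MicrosaccadeEvent, right: MicrosaccadeEvent
) -> MicrosaccadeEvent:
    """Average the per-eye properties of a binocularly matched pair.

    Scalar properties are arithmetic means; direction is a circular mean.
    The merged interval is the union of the two eyes' intervals.
    """
    onset = min(left.onset, right.onset)
    offset = max(left.offset, right.offset)
    ang = np.deg2rad([left.direction, right.direction])
    theta = math.degrees(math.atan2(np.sin(ang).mean(), np.cos(ang).mean())) % 360.0
    return MicrosaccadeEvent(
        onset=onset,
        offset=offset,
        duration_ms=(offset - onset) * 1000.0,
        amplitude=0.5 * (left.amplitude + right.amplitude),
        displacement=0.5 * (left.displacement + right.displacement),
        direction=theta,
        peak_velocity=0.5 * (left.peak_velocity + right.peak_velocity),
        eye="binocular",
    )


def main_sequence_fit(events: list[MicrosaccadeEvent]) -> MainSequenceFit:
    """Ordinary least squares of peak velocity on amplitude.

    Requires at least two events with distinct amplitudes; raises
    :class:`UndefinedMetricError` otherwise.
    """
    if len(events) < 2:
        raise UndefinedMetricError("main-sequence fit needs >= 2 events")
    amp = np.array([e.amplitude for e in events])
    vel = np.array([e.peak_velocity for e in events])
    if np.ptp(amp) == 0:
        raise UndefinedMetricError("main-sequence fit needs distinct amplitudes")
    res = stats.linregress(amp, vel)
    resid = vel - (res.slope * amp + res.intercept)
    return MainSequenceFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=len(events),
        residual_sd=float(np.std(resid, ddof=2)) if len(events) > 2 else 0.0,
        r_value=float(res.rvalue),
    )


def average_waveform(
    events: list[MicrosaccadeEvent],
    rec: GazeRecording,
    amp_band: tuple[float, float] = (0.14, 0.26),
    n_points: int = 101,
) -> WaveformBundle:
    """Scaled average of horizontal gaze traces for events in an amplitude band.

    Each event's horizontal signal is extracted from onset over the duration
    of the longest selected event (traces shorter than that are continued
    along the recorded signal, holding the last valid value where needed),
    baseline-subtracted at onset, sign-flipped so the peak excursion is
    positive, normalized by its maximum absolute value, and linearly
    resampled onto a common time base before pointwise averaging.
    """
    sel = [e for e in events if amp_band[0] <= e.amplitude <= amp_band[1]]
    if not sel:
        warnings.warn("no events in the amplitude band; empty waveform bundle")
        empty = np.empty((0, n_points))
        return WaveformBundle(np.linspace(0, 0, n_points), empty, np.full(n_points, np.nan))
    dur_max = max(e.offset - e.onset for e in sel)
    time_ms = np.linspace(0.0, dur_max * 1000.0, n_points)
    traces = np.empty((len(sel), n_points))
    for i, e in enumerate(sel):
        a = int(np.searchsorted(rec.time, e.onset - 0.5 * rec.dt))
        n_need = int(round(dur_max / rec.dt)) + 1
        ch = rec.eye(e.eye) if e.eye in ("left", "right") else None
        if ch is not None:
            raw = _extract_hold(ch.x, ch.valid, a, n_need)
        else:  # binocular events: mean of the two eyes' horizontal signals
            raw_l = _extract_hold(rec.left.x, rec.left.valid, a, n_need)
            raw_r = _extract_hold(rec.right.x, rec.right.valid, a, n_need)
            raw = 0.5 * (raw_l + raw_r)
        raw = raw - raw[0]
        peak = raw[np.argmax(np.abs(raw))]
        if peak < 0:
            raw = -raw
        t_raw = np.arange(n_need) * rec.dt * 1000.0
        tr = np.interp(time_ms, t_raw, raw)
        m = np.max(np.abs(tr))  # normalize on the common base: max exactly 1
        traces[i] = tr / m if m > 0 else tr
    return WaveformBundle(time_ms, traces, traces.mean(axis=0))


def _extract_hold(x: np.ndarray, valid: np.ndarray, a: int, n: int) -> np.ndarray:
    """Take n samples from index a, holding the last valid value past gaps/ends."""
    out = np.empty(n)
    last = x[a] if valid[a] else 0.0
    for k in range(n):
        i = a + k
        if i < len(x) and valid[i]:
            last = x[i]
        out[k] = last
    return out


def rotate_events(events: list[MicrosaccadeEvent], angle_deg: float) -> list[MicrosaccadeEvent]:
    """Rotate event directions (convenience for symmetry checks)."""
    return [replace(e, direction=(e.direction + angle_deg) % 360.0) for e in events]
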