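"""Velocity-threshold microsaccade detection with median-based noise scaling.

The detector follows the Engbert–Kliegl family: gaze velocity is computed
with a smoothing 5-point stencil, a robust per-axis noise scale sigma is
estimated from medians (insensitive to the saccades themselves), and a
sample counts as saccadic when its velocity lies outside the ellipse with
semi-axes eta = lambda * sigma.  Maximal supra-threshold runs lasting at
least a minimum duration become events; events closer together than a
minimum separation are treated as overshoots of their predecessor and
discarded.  Optionally only binocularly coincident events are kept.

Threshold selection can also be data-driven: amplitude-adjusted Fourier
surrogates (which keep each axis' value distribution and power spectrum
but destroy the phase structure that makes saccades saccadic) provide a
null detection rate per lambda, and the smallest lambda whose surrogate
rate falls below a small fraction of the real-data rate is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateThresholdError, InsufficientDataError, UndefinedMetricError
from .events import MicrosaccadeEvent, annotate_interval, merge_binocular_annotations
from .recording import GazeRecording, valid_segments


@dataclass(frozen=True)
class DetectionParams:
    """Detector settings.

    lam : threshold multiplier (eta = lam * sigma), default 6
    min_duration_ms : minimum event duration, default 5 ms
    min_separation_ms : minimum gap between consecutive events, default 10 ms
        (a later event closer than this is discarded as an overshoot)
    binocular_required : keep only events present in both eyes
    amplitude_rule : 'bbox' (maximum excursion) or 'from_onset'
    """

    lam: float = 6.0
    min_duration_ms: float = 5.0
    min_separation_ms: float = 10.0
    binocular_required: bool = True
    amplitude_rule: str = "bbox"

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.min_duration_ms <= 0 or self.min_separation_ms < 0:
            raise ValueError("lam and min_duration_ms must be > 0, min_separation_ms >= 0")


@dataclass
class EyeVelocity:
    """Velocity signal of one eye with its noise scales and thresholds.

    vx, vy are NaN where the stencil touches invalid samples.  sigma is the
    median-based noise scale per axis; eta = lam * sigma once estimated.
    """

    vx: np.ndarray
    vy: np.ndarray
    sigma_x: float = np.nan
    sigma_y: float = np.nan
    eta_x: float = np.nan
    eta_y: float = np.nan

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.vx) & np.isfinite(self.vy)


@dataclass
class VelocitySignal:
    """Binocular velocity container (per-eye :class:`EyeVelocity`)."""

    left: EyeVelocity
    right: EyeVelocity
    fs: float

    def eye(self, name: str) -> EyeVelocity:
        return self.left if name == "left" else self.right


@dataclass(frozen=True)
class SurrogateConfig:
    """Settings for surrogate-based lambda selection.

    lam_grid : candidate thresholds, increasing (default 3..12 step 0.5)
    n_surrogates : surrogates per recording (>= 1)
    method : surrogate dialect — 'aaft_increments' (default: amplitude-
        adjusted Fourier surrogate of the per-axis increment series,
        integrated back to positions), 'shuffle_increments' (random
        permutation of increments) or 'aaft' (AAFT of the position series)
    epsilon : acceptance rate — lambda* is the smallest grid value whose
        mean surrogate detection rate is <= epsilon * real-data rate
    seed : surrogate-generation seed
    """

    lam_grid: tuple = tuple(np.arange(3.0, 12.01, 0.5))
    n_surrogates: int = 10
    method: str = "aaft_increments"
    epsilon: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        grid = np.asarray(self.lam_grid, float)
        if grid.size == 0 or np.any(np.diff(grid) <= 0):
            raise ValueError("lam_grid must be non-empty and strictly increasing")
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")
        if self.method not in ("aaft_increments", "shuffle_increments", "aaft"):
            raise ValueError(f"unknown surrogate method {self.method!r}")


def _stencil_velocity(x: np.ndarray, dt: float) -> np.ndarray:
    """5-point smoothing differentiator: v_n = (x_{n+2}+x_{n+1}-x_{n-1}-x_{n-2})/(6 dt)."""
    v = np.full_like(x, np.nan, dtype=float)
    if len(x) >= 5:
        v[2:-2] = (x[4:] + x[3:-1] - x[1:-3] - x[:-4]) / (6.0 * dt)
    return v


def compute_velocity(rec: GazeRecording) -> VelocitySignal:
    """Per-eye gaze velocity on each valid segment (NaN elsewhere).

    The first and last two samples of every valid segment have no defined
    velocity; segments shorter than 5 samples yield none at all.
    """
    dt = rec.dt
    out = {}
    for eye, ch in rec.eyes():
        vx = np.full(rec.n_samples, np.nan)
        vy = np.full(rec.n_samples, np.nan)
        for seg in valid_segments(ch.valid, min_len=5):
            vx[seg] = _stencil_velocity(ch.x[seg], dt)
            vy[seg] = _stencil_velocity(ch.y[seg], dt)
        out[eye] = EyeVelocity(vx, vy)
    return VelocitySignal(out["left"], out["right"], rec.nominal_fs)


def median_sigma(v: np.ndarray) -> float:
    """Median-based noise scale sqrt(median(v^2) - median(v)^2).

    Robust to the heavy velocity tail contributed by saccades.  Raises
    :class:`DegenerateThresholdError` when the scale is zero or undefined.
    """
    v = np.asarray(v, float)
    v = v[np.isfinite(v)]
    if v.size < 3:
        raise InsufficientDataError("need >= 3 defined velocity samples")
    var = float(np.median(v ** 2) - np.median(v) ** 2)
    if not np.isfinite(var) or var <= 0:
        raise DegenerateThresholdError(f"median-based velocity variance {var} is not positive")
    return float(np.sqrt(var))


def estimate_threshold(vel: EyeVelocity, lam: float) -> EyeVelocity:
    """Fill in sigma and eta = lam * sigma for one eye (returns the same object)."""
    vel.sigma_x = median_sigma(vel.vx)
    vel.sigma_y = median_sigma(vel.vy)
    vel.eta_x = lam * vel.sigma_x
    vel.eta_y = lam * vel.sigma_y
    return vel


def _candidate_runs(vel: EyeVelocity, fs: float, params: DetectionParams) -> list[tuple[int, int]]:
    """Supra-threshold runs (inclusive sample intervals) after the
    minimum-duration rule."""
    with np.errstate(invalid="ignore"):
        crit = (vel.vx / vel.eta_x) ** 2 + (vel.vy / vel.eta_y) ** 2 > 1.0
    crit &= vel.defined
    min_samples = int(np.ceil(params.min_duration_ms * fs / 1000.0))
    return [(s.start, s.stop - 1) for s in valid_segments(crit, min_len=max(min_samples, 1))]


def _apply_separation(
    runs: list[tuple], fs: float, min_separation_ms: float
) -> list[tuple]:
    """Discard any event closer than the minimum gap to its predecessor.

    Overshoots re-cross the velocity threshold just after a saccade; the
    later of two events separated by less than the minimum is treated as
    such an overshoot and dropped.  Applied to the final event list (after
    any binocular combination), so sub-threshold monocular blips cannot
    suppress real events.
    """
    min_gap = min_separation_ms / 1000.0
    dt = 1.0 / fs
    kept: list[tuple] = []
    for run in runs:
        if kept and (run[0] - kept[-1][1] - 1) * dt < min_gap:
            continue
        kept.append(run)
    return kept


def detect_monocular(
    vel: VelocitySignal, params: DetectionParams, eye: str
) -> list[tuple[int, int]]:
    """Detect one eye's events as inclusive sample intervals, applying the
    duration and separation rules to this eye alone.

    Thresholds must have been estimated (see :func:`estimate_threshold`);
    a degenerate threshold propagates as an error.
    """
    ev = vel.eye(eye)
    if not (np.isfinite(ev.eta_x) and np.isfinite(ev.eta_y)):
        raise DegenerateThresholdError("thresholds not estimated or non-finite")
    runs = _candidate_runs(ev, vel.fs, params)
    return _apply_separation(runs, vel.fs, params.min_separation_ms)


def binocular_combine(
    left: list[tuple[int, int]], right: list[tuple[int, int]]
) -> list[tuple[int, int, int, int]]:
    """Pair temporally overlapping left/right intervals (greedy, in order).

    Returns tuples (union_start, union_stop, left_index, right_index);
    events present in one eye only are dropped.
    """
    pairs = []
    j = 0
    for i, (la, lb) in enumerate(left):
        while j < len(right) and right[j][1] < la:
            j += 1
        if j < len(right):
            ra, rb = right[j]
            if ra <= lb and la <= rb:
                pairs.append((min(la, ra), max(lb, rb), i, j))
                j += 1
    return pairs


def detect_microsaccades(
    rec: GazeRecording, params: DetectionParams = DetectionParams()
) -> list[MicrosaccadeEvent]:
    """Full detection pipeline on a degree-unit (ideally lowpass-filtered)
    recording: velocity -> thresholds -> monocular runs -> binocular
    combination -> annotated events sorted by onset.

    With ``binocular_required`` the output holds merged binocular events
    whose properties are per-eye averages; otherwise both eyes' monocular
    events are returned interleaved, labelled by eye.  An all-invalid
    recording yields an empty list.
    """
    vel = compute_velocity(rec)
    runs: dict[str, list[tuple[int, int]]] = {}
    for eye in ("left", "right"):
        ev = vel.eye(eye)
        if not ev.defined.any():
            runs[eye] = []
            continue
        estimate_threshold(ev, params.lam)
        if params.binocular_required:
            runs[eye] = _candidate_runs(ev, vel.fs, params)  # separation applied later
        else:
            runs[eye] = detect_monocular(vel, params, eye)

    events: list[MicrosaccadeEvent] = []
    if params.binocular_required:
        pairs = binocular_combine(runs["left"], runs["right"])
        for a, b, i, j in _apply_separation(pairs, vel.fs, params.min_separation_ms):
            el = annotate_interval(rec, *runs["left"][i], "left", vel.left.vx,
                                   vel.left.vy, params.amplitude_rule)
            er = annotate_interval(rec, *runs["right"][j], "right", vel.right.vx,
                                   vel.right.vy, params.amplitude_rule)
            events.append(merge_binocular_annotations(el, er))
    else:
        for eye in ("left", "right"):
            ev = vel.eye(eye)
            for a, b in runs[eye]:
                events.append(annotate_interval(rec, a, b, eye, ev.vx, ev.vy,
                                                params.amplitude_rule))
    events.sort(key=lambda e: (e.onset, e.eye))
    return events


def microsaccade_rate(events: list[MicrosaccadeEvent], rec: GazeRecording) -> float:
    """Events per second of *valid* recording time (both-eye validity).

    Dividing by valid rather than total duration prevents trials with heavy
    data loss from masquerading as low-rate trials.
    """
    n_valid = int(rec.joint_valid().sum())
    if n_valid == 0:
        raise UndefinedMetricError("no valid samples; rate undefined")
    return len(events) / (n_valid * rec.dt)


def aaft_surrogate(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Amplitude-adjusted Fourier surrogate of a 1-D series.

    Preserves the empirical value distribution exactly and the power
    spectrum approximately while randomizing Fourier phases.
    """
    x = np.asarray(x, float)
    n = len(x)
    ranks = np.argsort(np.argsort(x))
    gauss = np.sort(rng.standard_normal(n))[ranks]  # Gaussianized copy of x
    # phase-randomize the Gaussianized series
    spec = np.fft.rfft(gauss)
    phases = rng.uniform(0, 2 * np.pi, len(spec))
    phases[0] = 0.0
    if n % 2 == 0:
        phases[-1] = 0.0
    shuffled = np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n)
    # map the original values onto the randomized rank order
    return np.sort(x)[np.argsort(np.argsort(shuffled))]


@dataclass
class LambdaSelection:
    """Result of surrogate-based lambda selection."""

    lam_star: float | None
    table: pd.DataFrame = field(repr=False)  # columns: lam, real_rate, surrogate_rate


def surrogate_recording(
    rec: GazeRecording, method: str, rng: np.random.Generator
) -> GazeRecording:
    """One surrogate of a fully valid recording (per axis, per eye)."""
    s = rec.copy()
    for _, ch in s.eyes():
        for attr in ("x", "y"):
            v = getattr(ch, attr)
            if method == "aaft":
                setattr(ch, attr, aaft_surrogate(v, rng))
                continue
            inc = np.diff(v)
            if method == "aaft_increments":
                si = aaft_surrogate(inc, rng)
            else:  # shuffle_increments
                si = rng.permutation(inc)
            setattr(ch, attr, np.concatenate([[v[0]], v[0] + np.cumsum(si)]))
    return s


def optimal_lambda_surrogate(
    rec: GazeRecording,
    cfg: SurrogateConfig = SurrogateConfig(),
    params: DetectionParams = DetectionParams(),
    filter_params=None,
) -> LambdaSelection:
    """Select the detection threshold multiplier from surrogate data.

    ``rec`` should be the degree-converted, *unfiltered* recording: the
    surrogates are built from the raw signal and then real data and
    surrogates alike pass through the standard Bartlett lowpass before
    detection, exactly as in the detection pipeline.  (Surrogate jumps must
    be smeared by the same filter the real saccades are.)

    Works on the longest contiguous both-eye-valid stretch of the recording
    (surrogate generation needs an unbroken series).  For every lambda on
    the grid the detection rate is measured on the real data and on
    ``n_surrogates`` surrogates; lambda* is the smallest grid value whose
    mean surrogate rate is <= epsilon * real rate (with a nonzero real
    rate).  If no grid value qualifies, ``lam_star`` is None and the
    per-lambda diagnostic table is still returned — no silent default.
    """
    from .preprocess import FilterParams, filter_recording

    if filter_params is None:
        filter_params = FilterParams()
    segs = valid_segments(rec.joint_valid())
    if not segs:
        raise InsufficientDataError("no valid samples for surrogate analysis")
    seg = max(segs, key=lambda s: s.stop - s.start)
    if seg.stop - seg.start < 16:
        raise InsufficientDataError("longest valid segment too short for surrogates")
    sub = _crop(rec, seg)

    rng = np.random.default_rng(cfg.seed)
    grid = np.asarray(cfg.lam_grid, float)
    real = _rates_over_grid(filter_recording(sub, filter_params), grid, params)

    surr = np.zeros((cfg.n_surrogates, len(grid)))
    for k in range(cfg.n_surrogates):
        s = surrogate_recording(sub, cfg.method, rng)
        surr[k] = _rates_over_grid(filter_recording(s, filter_params), grid, params)
    surr_mean = surr.mean(axis=0)

    table = pd.DataFrame({"lam": grid, "real_rate": real, "surrogate_rate": surr_mean})
    ok = (surr_mean <= cfg.epsilon * real) & (real > 0)
    lam_star = float(grid[np.argmax(ok)]) if ok.any() else None
    return LambdaSelection(lam_star, table)


def _crop(rec: GazeRecording, seg: slice) -> GazeRecording:
    from dataclasses import replace

    return replace(
        rec.copy(),
        time=rec.time[seg].copy(),
        left=_crop_eye(rec.left, seg),
        right=_crop_eye(rec.right, seg),
    )


def _crop_eye(ch, seg: slice):
    from .recording import EyeChannel

    return EyeChannel(ch.x[seg].copy(), ch.y[seg].copy(), ch.pupil[seg].copy(),
                      ch.valid[seg].copy(), ch.interpolated[seg].copy())


def _rates_over_grid(rec: GazeRecording, grid: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Detection rate at each lambda; velocity and sigma are computed once."""
    from dataclasses import replace

    vel = compute_velocity(rec)
    for eye in ("left", "right"):
        estimate_threshold(vel.eye(eye), 1.0)  # eta = sigma; rescaled per lam below
    n_valid = int(rec.joint_valid().sum())
    rates = np.zeros(len(grid))
    for g, lam in enumerate(grid):
        runs = {}
        for eye in ("left", "right"):
            ev = vel.eye(eye)
            scaled = EyeVelocity(ev.vx, ev.vy, ev.sigma_x, ev.sigma_y,
                                 lam * ev.sigma_x, lam * ev.sigma_y)
            runs[eye] = _candidate_runs(scaled, vel.fs, replace(params, lam=lam))
        if params.binocular_required:
            pairs = binocular_combine(runs["left"], runs["right"])
            count = len(_apply_separation(pairs, vel.fs, params.min_separation_ms))
        else:
            count = sum(
                len(_apply_separation(runs[eye], vel.fs, params.min_separation_ms))
                for eye in ("left", "right"))
        rates[g] = count / (n_valid * rec.dt)
    return rates
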