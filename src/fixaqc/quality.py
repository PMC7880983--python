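"""Data-quality metrics: RMS-S2S and SD precision, accuracy, data loss, PSD.

RMS of sample-to-sample distances captures high-frequency noise (each
difference cancels slow components), while the standard deviation of the
position signal is dominated by slow drift; the two together separate
sensor noise from oculomotor drift.  Accuracy is the mean distance between
validation targets and the median gaze position in a window 500–1000 ms
after each target onset.  The PSD uses 256-sample Hann-tapered
non-overlapping segments with one-sided density normalization.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import InsufficientDataError, UndefinedMetricError
from .recording import GazeRecording, ValidationSequence, valid_segments

PSD_SEGMENT_SAMPLES = 256


def rms_s2s(
    x: np.ndarray, y: np.ndarray, valid: np.ndarray | None = None
) -> tuple[float, float, float]:
    """Root-mean-square of sample-to-sample differences (x, y, 2-D).

    Differences are only taken between adjacent valid samples (adjacency
    never straddles an invalid gap).  Returns (rms_x, rms_y, rms_2d) with
    rms_2d^2 = rms_x^2 + rms_y^2.  Requires at least one valid adjacent
    pair.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if valid is None:
        valid = np.isfinite(x) & np.isfinite(y)
    pair = valid[:-1] & valid[1:]
    if not pair.any():
        raise UndefinedMetricError("no adjacent valid sample pairs; RMS-S2S undefined")
    dx = np.diff(x)[pair]
    dy = np.diff(y)[pair]
    mx = float(np.mean(dx ** 2))
    my = float(np.mean(dy ** 2))
    return float(np.sqrt(mx)), float(np.sqrt(my)), float(np.sqrt(mx + my))


def sd_precision(
    x: np.ndarray, y: np.ndarray, valid: np.ndarray | None = None
) -> tuple[float, float]:
    """Per-axis standard deviation about the mean, over valid samples only."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if valid is None:
        valid = np.isfinite(x) & np.isfinite(y)
    if valid.sum() < 2:
        raise UndefinedMetricError("need >= 2 valid samples for SD precision")
    return float(np.std(x[valid])), float(np.std(y[valid]))


def accuracy(
    rec: GazeRecording,
    seq: ValidationSequence,
    eye: str = "left",
    window: tuple[float, float] = (0.5, 1.0),
) -> float:
    """Mean Euclidean offset between targets and median gaze per target.

    For each validation point, gaze samples in the half-open window
    [onset + window[0], onset + window[1]) are reduced to their
    componentwise median; the distances to the targets are averaged.
    Points with an empty window are skipped with a warning; if all are
    empty an error is raised.  Recording must be in degrees.
    """
    if rec.unit != "deg":
        raise UndefinedMetricError("accuracy requires a degree-unit recording")
    ch = rec.eye(eye)
    dists = []
    for tx, ty, onset in seq.targets:
        sel = (rec.time >= onset + window[0]) & (rec.time < onset + window[1]) & ch.valid
        if not sel.any():
            warnings.warn(f"validation point at t={onset}s has no valid gaze; skipped")
            continue
        mx = float(np.median(ch.x[sel]))
        my = float(np.median(ch.y[sel]))
        dists.append(np.hypot(mx - tx, my - ty))
    if not dists:
        raise UndefinedMetricError("no validation point had valid gaze data")
    return float(np.mean(dists))


def data_loss(rec: GazeRecording) -> dict[str, float]:
    """Proportion of invalid samples per eye (device-reported loss;
    compute before blink padding)."""
    return {eye: float((~ch.valid).sum()) / rec.n_samples for eye, ch in rec.eyes()}


def psd(
    x: np.ndarray,
    fs: float,
    valid: np.ndarray | None = None,
    nperseg: int = PSD_SEGMENT_SAMPLES,
) -> tuple[np.ndarray, np.ndarray]:
    """Averaged periodogram over non-overlapping Hann-tapered segments.

    Every full ``nperseg``-sample block inside a contiguous valid stretch
    contributes one periodogram; blocks never straddle invalid gaps.  The
    one-sided density (unit^2/Hz) is returned with its frequency grid,
    which ends at fs/2.  Raises when no contiguous stretch holds a full
    block.
    """
    x = np.asarray(x, float)
    if valid is None:
        valid = np.isfinite(x)
    blocks = []
    for seg in valid_segments(valid, min_len=nperseg):
        xs = x[seg]
        for k in range(len(xs) // nperseg):
            blocks.append(xs[k * nperseg:(k + 1) * nperseg])
    if not blocks:
        raise InsufficientDataError(
            f"PSD needs at least one contiguous run of {nperseg} valid samples")
    f, pxx = sps.welch(
        np.asarray(blocks), fs=fs, window="hann", nperseg=nperseg,
        noverlap=0, detrend=False, scaling="density", axis=-1,
    )
    return f, pxx.mean(axis=0)


def quality_report(
    rec: GazeRecording, validation: ValidationSequence | None = None
) -> pd.DataFrame:
    """One row per eye with RMS-S2S, SD, data loss and (optionally) accuracy.

    Precision metrics are meaningful on unfiltered degree-converted data;
    data loss reflects the device-reported validity mask.
    """
    loss = data_loss(rec)
    rows = []
    for eye, ch in rec.eyes():
        row = {"eye": eye, **{k: np.nan for k in
                              ("rms_s2s_x", "rms_s2s_y", "rms_s2s_2d", "sd_x", "sd_y")}}
        try:
            row["rms_s2s_x"], row["rms_s2s_y"], row["rms_s2s_2d"] = rms_s2s(
                ch.x, ch.y, ch.valid)
            row["sd_x"], row["sd_y"] = sd_precision(ch.x, ch.y, ch.valid)
        except UndefinedMetricError:
            pass
        row["data_loss"] = loss[eye]
        if validation is not None:
            try:
                row["accuracy"] = accuracy(rec, validation, eye)
            except UndefinedMetricError:
                row["accuracy"] = np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    for key in ("participant", "setup", "trial", "repetition"):
        if key in rec.meta:
            df[key] = rec.meta[key]
    return df
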