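"""Core containers for binocular gaze data.

A :class:`GazeRecording` is the universal currency of the pipeline: a
timestamped pair of eye channels with explicit per-sample validity masks.
Missing data are never represented by sentinel values inside the pipeline —
a sample is either valid or its positions are unusable (NaN) and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .errors import FormatError

EYES = ("left", "right")


@dataclass
class EyeChannel:
    """Per-eye gaze signal: positions, pupil size and a validity mask.

    Positions are in the recording's unit (pixels or degrees).  ``valid``
    marks samples usable for analysis; invalid samples hold NaN positions.
    ``interpolated`` marks samples reconstructed from their neighbours.
    """

    x: np.ndarray
    y: np.ndarray
    pupil: np.ndarray
    valid: np.ndarray
    interpolated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.interpolated is None:
            self.interpolated = np.zeros_like(self.valid)
        else:
            self.interpolated = np.asarray(self.interpolated, dtype=bool)
        n = len(self.x)
        if not all(len(a) == n for a in (self.y, self.pupil, self.valid, self.interpolated)):
            raise FormatError("eye channel arrays have unequal lengths")

    def __len__(self) -> int:
        return len(self.x)

    def copy(self) -> "EyeChannel":
        return EyeChannel(
            self.x.copy(), self.y.copy(), self.pupil.copy(),
            self.valid.copy(), self.interpolated.copy(),
        )

    def mask_invalid_positions(self) -> None:
        """Overwrite positions of invalid samples with NaN (no silent zeros)."""
        bad = ~self.valid
        self.x[bad] = np.nan
        self.y[bad] = np.nan


@dataclass
class GazeRecording:
    """Timestamped binocular gaze samples with validity flags and metadata.

    Parameters
    ----------
    time : array of float
        Sample timestamps in seconds, strictly increasing.
    nominal_fs : float
        Nominal sampling rate in Hz; the median inter-sample interval must be
        within 10% of ``1/nominal_fs``.
    left, right : EyeChannel
        Per-eye signals of equal length.
    unit : {"px", "deg"}
        Unit of the position arrays.
    meta : dict
        Free-form acquisition metadata (participant, setup, trial, repetition).
    """

    time: np.ndarray
    nominal_fs: float
    left: EyeChannel
    right: EyeChannel
    unit: str = "px"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.unit not in ("px", "deg"):
            raise FormatError(f"unknown position unit {self.unit!r}")
        if len(self.left) != len(self.right) or len(self.time) != len(self.left):
            raise FormatError("time/left/right arrays have unequal lengths")
        if len(self.time) > 1:
            dts = np.diff(self.time)
            if np.any(dts <= 0):
                raise FormatError("timestamps are not strictly increasing")
            med = float(np.median(dts))
            if abs(med - 1.0 / self.nominal_fs) > 0.1 / self.nominal_fs:
                raise FormatError(
                    f"median inter-sample interval {med:.6g} s deviates >10% "
                    f"from 1/nominal_fs = {1.0 / self.nominal_fs:.6g} s"
                )
        for eye in (self.left, self.right):
            eye.mask_invalid_positions()

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def dt(self) -> float:
        return 1.0 / self.nominal_fs

    @property
    def duration(self) -> float:
        return self.n_samples * self.dt

    def eyes(self) -> Iterator[tuple[str, EyeChannel]]:
        yield "left", self.left
        yield "right", self.right

    def eye(self, name: str) -> EyeChannel:
        if name not in EYES:
            raise KeyError(name)
        return self.left if name == "left" else self.right

    def joint_valid(self) -> np.ndarray:
        """Samples valid in both eyes."""
        return self.left.valid & self.right.valid

    def copy(self) -> "GazeRecording":
        return replace(
            self, time=self.time.copy(), left=self.left.copy(),
            right=self.right.copy(), meta=dict(self.meta),
        )


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display geometry used for pixel-to-degree conversion.

    All quantities strictly positive: resolution in pixels, physical size in
    cm, viewing distance in cm.
    """

    resolution: tuple[int, int]
    size_cm: tuple[float, float]
    distance_cm: float

    def __post_init__(self) -> None:
        if (self.resolution[0] <= 0 or self.resolution[1] <= 0
                or self.size_cm[0] <= 0 or self.size_cm[1] <= 0
                or self.distance_cm <= 0):
            raise ValueError("screen geometry values must be strictly positive")


@dataclass
class ValidationSequence:
    """Fixation-target sequence used to measure accuracy.

    ``targets`` is a list of ``(x_deg, y_deg, onset_s)`` triples; onsets must
    lie inside the time span of the recording they are evaluated against.
    """

    targets: list[tuple[float, float, float]]


def valid_segments(valid: np.ndarray, min_len: int = 1) -> list[slice]:
    """Maximal runs of True in a boolean mask, as slices, length >= min_len."""
    valid = np.asarray(valid, dtype=bool)
    if valid.size == 0:
        return []
    padded = np.concatenate(([False], valid, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return [slice(a, b) for a, b in zip(starts, stops) if b - a >= min_len]
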