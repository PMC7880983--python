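import numpy as np
import pytest

from fixaqc.recording import EyeChannel, GazeRecording


def make_recording(
    x,
    y=None,
    fs=1000.0,
    valid=None,
    pupil=None,
    unit="deg",
    x_right=None,
    y_right=None,
    valid_right=None,
):
    """Small binocular recording for tests; the right eye mirrors the left
    unless given explicitly."""
    x = np.asarray(x, float)
    y = np.zeros_like(x) if y is None else np.asarray(y, float)
    n = len(x)
    valid = np.ones(n, bool) if valid is None else np.asarray(valid, bool)
    pupil = np.full(n, 1000.0) if pupil is None else np.asarray(pupil, float)
    left = EyeChannel(x.copy(), y.copy(), pupil.copy(), valid.copy())
    right = EyeChannel(
        (x if x_right is None else np.asarray(x_right, float)).copy(),
        (y if y_right is None else np.asarray(y_right, float)).copy(),
        pupil.copy(),
        (valid if valid_right is None else np.asarray(valid_right, bool)).copy(),
    )
    return GazeRecording(
        time=np.arange(n) / fs, nominal_fs=fs, left=left, right=right, unit=unit
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
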