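"""Synthetic binocular fixation recordings with ground truth.

The generator produces what a video eye tracker sees during steady
fixation: a microsaccade train riding on slow 1/f^alpha oculomotor drift,
observed through independent white sensor noise per eye, with optional
blink dropouts.  Microsaccades are raised-cosine velocity pulses whose
peak velocity follows a configurable linear main sequence
(V = slope * A + intercept) with Gaussian jitter, optionally followed by a
small opposite-direction overshoot pulse.  Event parameters are drawn in
continuous time from a seed substream that does not depend on the sampling
rate, so the same seed yields the *same* ground-truth events at 600 and
1200 Hz.

Four presets emulate the sampling rates and relative noise magnitudes of
common recording setups (Tobii Spectrum at 1200/600 Hz; EyeLink at
1000 Hz with heuristic filtering off/on).  The preset noise levels are
illustrative magnitudes, not measurements of any device.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError
from .events import MicrosaccadeEvent
from .preprocess import FilterParams, bartlett_lowpass
from .recording import EyeChannel, GazeRecording

SETUP_NAMES = ("spectrum1200", "spectrum600", "eyelink_u", "eyelink_f")


@dataclass(frozen=True)
class SyntheticConfig:
    """Simulator settings; defaults give a plausible 1000-Hz fixation trial.

    Rates in Hz, durations in seconds unless suffixed, amplitudes and noise
    in degrees, velocities in deg/s.
    """

    fs: float = 1000.0
    duration: float = 20.0
    rate: float = 1.5                       # target microsaccade rate
    amp_log_mean: float = math.log(0.3)     # lognormal amplitude, log-scale mean
    amp_log_sd: float = 0.45
    amp_min: float = 0.05                   # truncation band, deg
    amp_max: float = 1.0
    main_seq_slope: float = 45.0            # (deg/s)/deg
    main_seq_intercept: float = 10.0        # deg/s
    peak_velocity_jitter_sd: float = 3.0    # deg/s scatter about the main sequence
    overshoot_prob: float = 0.3
    overshoot_frac: float = 0.15            # overshoot amplitude relative to A
    direction_kappa: float = 1.5            # von Mises concentration (horizontal bias)
    drift_sd: float = 0.01                  # deg, std of 1/f^alpha drift per axis
    drift_alpha: float = 1.0
    drift_cutoff_hz: float = 100.0          # drift carries no power above this
    noise_sd: float = 0.015                 # deg per axis white sensor noise
    noise_independent: bool = True          # independent noise per eye
    blink_rate_per_min: float = 0.0
    blink_duration_log_mean: float = math.log(0.15)  # s
    blink_duration_log_sd: float = 0.3
    refractory_ms: float = 100.0            # minimum offset-to-onset gap
    device_filter_ms: float = 0.0           # >0: extra in-device lowpass (EyeLink F)
    setup: str = "custom"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0 or self.rate < 0:
            raise ConfigError("fs and duration must be positive, rate non-negative")
        if not (0.5 <= self.drift_alpha <= 2.0):
            raise ConfigError("drift_alpha must lie in [0.5, 2]")
        if not (0 < self.amp_min < self.amp_max):
            raise ConfigError("need 0 < amp_min < amp_max")
        if self.rate > 0 and 1.0 / self.rate <= self.refractory_ms / 1000.0 + 0.05:
            raise ConfigError(
                f"rate {self.rate} Hz infeasible with refractory {self.refractory_ms} ms")


@dataclass
class GroundTruth:
    """Injected events, blink intervals and the noiseless shared trajectory."""

    events: list[MicrosaccadeEvent]
    blink_intervals: list[tuple[float, float]]
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)


def _truncated_lognormal(rng: np.random.Generator, mu: float, sd: float,
                         lo: float, hi: float) -> float:
    for _ in range(1000):
        a = rng.lognormal(mu, sd)
        if lo <= a <= hi:
            return a
    raise ConfigError("amplitude truncation band rejects virtually all draws")


def _raised_cosine_profile(u: np.ndarray) -> np.ndarray:
    """Normalized displacement of a raised-cosine velocity pulse, u in [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    return u - np.sin(2 * np.pi * u) / (2 * np.pi)


def _draw_events(cfg: SyntheticConfig, rng: np.random.Generator) -> list[dict]:
    """Continuous-time event train (independent of fs)."""
    if cfg.rate == 0:
        return []
    # mean onset-to-onset interval 1/rate = refractory + duration + gamma part;
    # pre-estimate the mean event duration from the amplitude distribution
    probe = [_truncated_lognormal(rng, cfg.amp_log_mean, cfg.amp_log_sd,
                                  cfg.amp_min, cfg.amp_max) for _ in range(500)]
    probe_dur = np.mean([2 * a / (cfg.main_seq_slope * a + cfg.main_seq_intercept)
                         for a in probe])
    mean_gap = 1.0 / cfg.rate - cfg.refractory_ms / 1000.0 - probe_dur
    if mean_gap <= 0:
        raise ConfigError("rate too high for the refractory interval and event durations")
    gamma_scale = mean_gap / 2.0  # shape-2 gamma: mean = 2 * scale

    events = []
    t = rng.gamma(2.0, gamma_scale)  # first onset
    while True:
        amp = _truncated_lognormal(rng, cfg.amp_log_mean, cfg.amp_log_sd,
                                   cfg.amp_min, cfg.amp_max)
        vp_nom = cfg.main_seq_slope * amp + cfg.main_seq_intercept
        vp = vp_nom + rng.normal(0.0, cfg.peak_velocity_jitter_sd)
        vp = max(vp, 0.3 * vp_nom)
        dur = 2.0 * amp / vp
        mu = 0.0 if rng.random() < 0.5 else np.pi
        theta = rng.vonmises(mu, cfg.direction_kappa)
        over = cfg.overshoot_frac * amp if rng.random() < cfg.overshoot_prob else 0.0
        if over > 0:
            vp_o = cfg.main_seq_slope * over + cfg.main_seq_intercept
            dur_o = 2.0 * over / vp_o
        else:
            dur_o = 0.0
        offset = t + dur + dur_o
        if offset >= cfg.duration - 0.05:
            break
        events.append(dict(onset=t, dur=dur, dur_over=dur_o, amp=amp, over=over,
                           theta=theta, vp=vp))
        t = offset + cfg.refractory_ms / 1000.0 + rng.gamma(2.0, gamma_scale)
    return events


def _pink_noise(n: int, dt: float, alpha: float, sd: float,
                rng: np.random.Generator, cutoff_hz: float = np.inf) -> np.ndarray:
    """1/f^alpha series by spectral shaping of white noise, std scaled to sd.

    Power above ``cutoff_hz`` is removed: oculomotor drift contributes no
    power at high frequencies, where gaze spectra are floored by white
    sensor noise instead.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, dt)
    scale = np.zeros_like(freqs)
    band = (freqs > 0) & (freqs <= cutoff_hz)
    scale[band] = freqs[band] ** (-alpha / 2.0)
    x = np.fft.irfft(spec * scale, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def generate_recording(cfg: SyntheticConfig) -> tuple[GazeRecording, GroundTruth]:
    """Simulate one binocular fixation trial.

    Returns a degree-unit :class:`GazeRecording` and the
    :class:`GroundTruth` with the injected event list, blink intervals and
    the noiseless shared trajectory.  Deterministic under ``cfg.seed``;
    the event train additionally does not depend on ``cfg.fs``.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_ev, rng_drift, rng_nl, rng_nr, rng_blink = (
        np.random.default_rng(s) for s in ss.spawn(5))

    n = int(round(cfg.duration * cfg.fs))
    dt = 1.0 / cfg.fs
    t = np.arange(n) * dt

    raw_events = _draw_events(cfg, rng_ev)
    x = np.zeros(n)
    y = np.zeros(n)
    gt_events: list[MicrosaccadeEvent] = []
    for ev in raw_events:
        ux, uy = math.cos(ev["theta"]), math.sin(ev["theta"])
        i0 = int(np.searchsorted(t, ev["onset"]))
        i1 = min(n, int(np.searchsorted(t, ev["onset"] + ev["dur"] + ev["dur_over"])) + 1)
        tt = t[i0:i1]
        disp = ev["amp"] * _raised_cosine_profile((tt - ev["onset"]) / ev["dur"])
        if ev["over"] > 0:
            disp = disp - ev["over"] * _raised_cosine_profile(
                (tt - ev["onset"] - ev["dur"]) / ev["dur_over"])
        net = ev["amp"] - ev["over"]
        x[i0:i1] += ux * disp
        y[i0:i1] += uy * disp
        x[i1:] += ux * net
        y[i1:] += uy * net
        gt_events.append(MicrosaccadeEvent(
            onset=ev["onset"], offset=ev["onset"] + ev["dur"] + ev["dur_over"],
            duration_ms=(ev["dur"] + ev["dur_over"]) * 1000.0,
            amplitude=ev["amp"], displacement=net,
            direction=math.degrees(ev["theta"]) % 360.0,
            peak_velocity=ev["vp"], eye="binocular",
        ))

    if cfg.drift_sd > 0:
        x = x + _pink_noise(n, dt, cfg.drift_alpha, cfg.drift_sd, rng_drift,
                            cfg.drift_cutoff_hz)
        y = y + _pink_noise(n, dt, cfg.drift_alpha, cfg.drift_sd, rng_drift,
                            cfg.drift_cutoff_hz)
    truth = GroundTruth(gt_events, [], x.copy(), y.copy())

    channels = {}
    shared_noise = None
    for eye, rng_n in (("left", rng_nl), ("right", rng_nr)):
        if cfg.noise_sd > 0:
            if cfg.noise_independent or shared_noise is None:
                noise = rng_n.standard_normal((2, n)) * cfg.noise_sd
                shared_noise = noise
            else:
                noise = shared_noise
        else:
            noise = np.zeros((2, n))
        pupil = np.full(n, 1000.0)
        channels[eye] = EyeChannel(x + noise[0], y + noise[1], pupil,
                                   np.ones(n, dtype=bool))

    blink_intervals: list[tuple[float, float]] = []
    if cfg.blink_rate_per_min > 0:
        n_blinks = rng_blink.poisson(cfg.blink_rate_per_min * cfg.duration / 60.0)
        onsets = np.sort(rng_blink.uniform(0, cfg.duration, n_blinks))
        for onset in onsets:
            d = rng_blink.lognormal(cfg.blink_duration_log_mean, cfg.blink_duration_log_sd)
            a = int(np.searchsorted(t, onset))
            b = min(n, int(np.searchsorted(t, onset + d)))
            if b <= a:
                continue
            if blink_intervals and onset <= blink_intervals[-1][1]:
                blink_intervals[-1] = (blink_intervals[-1][0], t[b - 1] + dt)
            else:
                blink_intervals.append((t[a], t[b - 1] + dt))
            for ch in channels.values():
                ch.valid[a:b] = False
                ch.pupil[a:b] = np.nan
    truth.blink_intervals = blink_intervals

    if cfg.device_filter_ms > 0:
        fp = FilterParams(window_ms=cfg.device_filter_ms)
        for ch in channels.values():
            ch.x = bartlett_lowpass(ch.x, cfg.fs, fp)
            ch.y = bartlett_lowpass(ch.y, cfg.fs, fp)

    rec = GazeRecording(
        time=t, nominal_fs=cfg.fs, left=channels["left"], right=channels["right"],
        unit="deg",
        meta={"setup": cfg.setup, "seed": cfg.seed, "synthetic": True},
    )
    return rec, truth


_PRESETS: dict[str, dict] = {
    # illustrative noise magnitudes ordered as the qualitative RMS ranking
    # eyelink_f < eyelink_u < spectrum; fs per setup
    "spectrum1200": dict(fs=1200.0, noise_sd=0.017),
    "spectrum600": dict(fs=600.0, noise_sd=0.015),
    "eyelink_u": dict(fs=1000.0, noise_sd=0.008),
    "eyelink_f": dict(fs=1000.0, noise_sd=0.008, device_filter_ms=15.0),
}


def setup_presets(name: str, **overrides) -> SyntheticConfig:
    """Config preset for one of the four emulated recording setups.

    ``spectrum1200`` (1200 Hz), ``spectrum600`` (600 Hz), ``eyelink_u``
    (1000 Hz, unfiltered), ``eyelink_f`` (1000 Hz with an extra in-device
    lowpass emulating heuristic filtering).  Keyword overrides are applied
    on top of the preset.
    """
    if name not in _PRESETS:
        raise ConfigError(f"unknown setup {name!r}; choose from {SETUP_NAMES}")
    return SyntheticConfig(setup=name, **{**_PRESETS[name], **overrides})
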