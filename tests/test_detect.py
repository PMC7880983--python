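"""Velocity stencil, median thresholds, event detection and lambda selection."""

import numpy as np
import pytest

import fixaqc
from fixaqc.detect import (
    DetectionParams,
    EyeVelocity,
    SurrogateConfig,
    _apply_separation,
    _candidate_runs,
    binocular_combine,
    compute_velocity,
    detect_microsaccades,
    estimate_threshold,
    median_sigma,
    microsaccade_rate,
    optimal_lambda_surrogate,
)
from fixaqc.errors import DegenerateThresholdError
from fixaqc.preprocess import filter_recording
from fixaqc.synthetic import SyntheticConfig, generate_recording

from conftest import make_recording


class TestVelocityStencil:
    def test_linear_ramp_gives_exact_slope(self):
        fs = 1000.0
        t = np.arange(100) / fs
        rec = make_recording(3.5 * t, -1.25 * t, fs=fs)
        vel = compute_velocity(rec)
        np.testing.assert_allclose(vel.left.vx[2:-2], 3.5, atol=1e-9)
        np.testing.assert_allclose(vel.left.vy[2:-2], -1.25, atol=1e-9)
        assert np.isnan(vel.left.vx[:2]).all() and np.isnan(vel.left.vx[-2:]).all()

    def test_constant_position_gives_zero(self):
        rec = make_recording(np.full(50, 2.0))
        assert np.nanmax(np.abs(compute_velocity(rec).left.vx)) == 0.0

    def test_quadratic_matches_direct_stencil_evaluation(self):
        fs = 1000.0
        t = np.arange(20) / fs
        x = t ** 2
        rec = make_recording(x, fs=fs)
        v = compute_velocity(rec).left.vx
        dt = 1.0 / fs
        for n in range(2, 18):  # brute-force stencil oracle
            expect = (x[n + 2] + x[n + 1] - x[n - 1] - x[n - 2]) / (6 * dt)
            assert v[n] == pytest.approx(expect, abs=1e-12)

    def test_segment_shorter_than_five_samples_has_no_velocity(self):
        valid = np.ones(20, bool)
        valid[4] = False  # leaves a 4-sample leading segment
        rec = make_recording(np.arange(20.0), valid=valid)
        v = compute_velocity(rec).left.vx
        assert np.isnan(v[:5]).all()


class TestMedianThreshold:
    def test_constant_velocity_is_degenerate(self):
        with pytest.raises(DegenerateThresholdError):
            median_sigma(np.full(10, 2.0))

    def test_matches_brute_force_median_formula(self, rng):
        for _ in range(50):
            v = rng.standard_normal(rng.integers(5, 40)) * rng.uniform(0.1, 10)
            expect = np.sqrt(np.median(v ** 2) - np.median(v) ** 2)
            if not expect > 0:
                continue
            assert median_sigma(v) == pytest.approx(expect, rel=1e-12)

    def test_three_level_velocities(self):
        v = np.array([-1.0, 0.0, 1.0] * 5)  # median(v)=0, median(v^2)=1
        assert median_sigma(v) == pytest.approx(1.0)
        ev = EyeVelocity(v, v.copy())
        estimate_threshold(ev, 6.0)
        assert ev.eta_x == pytest.approx(6.0)

    def test_scaling_velocities_scales_sigma_and_eta(self, rng):
        v = rng.standard_normal(101)
        s1 = median_sigma(v)
        assert median_sigma(4.0 * v) == pytest.approx(4.0 * s1, rel=1e-12)


def _saccade_signal(fs=1000.0, dur_s=5.0, onsets=(2.0,), amp=0.3, sacc_ms=15.0,
                    noise=0.0, seed=0):
    """Drift-free trajectory with raised-cosine saccades at given onsets."""
    rng = np.random.default_rng(seed)
    n = int(dur_s * fs)
    t = np.arange(n) / fs
    x = np.zeros(n)
    T = sacc_ms / 1000.0
    for t0 in onsets:
        u = np.clip((t - t0) / T, 0, 1)
        x += amp * (u - np.sin(2 * np.pi * u) / (2 * np.pi))
    x += rng.standard_normal(n) * noise
    y = rng.standard_normal(n) * noise
    return make_recording(x, y, fs=fs)


class TestDetection:
    def test_single_injected_saccade_found_with_accurate_timing(self):
        fs = 1000.0
        rec = _saccade_signal(fs=fs, onsets=(2.0,), noise=0.002, seed=1)
        events = detect_microsaccades(filter_recording(rec), DetectionParams())
        assert len(events) == 1
        # localization at the resolution of the 21-tap zero-phase filter,
        # whose half-width (10 ms) smears the velocity pulse symmetrically
        assert events[0].onset == pytest.approx(2.0, abs=0.011)
        assert events[0].offset == pytest.approx(2.015, abs=0.011)
        assert events[0].onset <= 2.001 and events[0].offset >= 2.014

    def test_pure_noise_rate_is_small(self):
        rates = []
        for seed in range(5):
            rec = _saccade_signal(dur_s=10.0, onsets=(), noise=0.02, seed=seed)
            ev = detect_microsaccades(filter_recording(rec), DetectionParams())
            rates.append(microsaccade_rate(ev, rec))
        assert np.mean(rates) <= 0.1

    def test_overshoot_8ms_apart_counts_once(self):
        # two supra-threshold runs separated by < 10 ms: later one discarded
        vx = np.zeros(200)
        vx[50:60] = 30.0   # 10-ms event
        vx[68:75] = 30.0   # 8 ms later
        ev = EyeVelocity(vx, np.zeros(200), 1.0, 1.0, 5.0, 5.0)
        runs = _apply_separation(_candidate_runs(ev, 1000.0, DetectionParams()),
                                 1000.0, 10.0)
        assert runs == [(50, 59)]

    def test_minimum_duration_rule(self):
        vx = np.zeros(200)
        vx[50:53] = 30.0  # 3 ms: below the 5-ms minimum
        ev = EyeVelocity(vx, np.zeros(200), 1.0, 1.0, 5.0, 5.0)
        assert _candidate_runs(ev, 1000.0, DetectionParams()) == []

    def test_all_invalid_recording_yields_no_events(self):
        rec = make_recording(np.zeros(100), valid=np.zeros(100, bool))
        assert detect_microsaccades(rec, DetectionParams()) == []

    def test_raising_lambda_never_increases_event_count(self):
        cfg = SyntheticConfig(seed=11, amp_min=0.1)
        rec, _ = generate_recording(cfg)
        recf = filter_recording(rec)
        counts = [len(detect_microsaccades(recf, DetectionParams(lam=lam)))
                  for lam in np.arange(3.0, 12.1, 0.5)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_detection_invariant_to_rigid_translation(self):
        rec = _saccade_signal(onsets=(1.0, 3.0), noise=0.005, seed=3)
        shifted = rec.copy()
        shifted.left.x += 4.0
        shifted.right.x += 4.0
        shifted.left.y -= 2.0
        shifted.right.y -= 2.0
        e1 = detect_microsaccades(filter_recording(rec))
        e2 = detect_microsaccades(filter_recording(shifted))
        assert [(e.onset, e.offset) for e in e1] == [(e.onset, e.offset) for e in e2]

    def test_detection_equivariant_to_axis_exchange(self):
        rec = _saccade_signal(onsets=(1.0, 3.0), noise=0.005, seed=4)
        swapped = rec.copy()
        for ch in (swapped.left, swapped.right):
            ch.x, ch.y = ch.y.copy(), ch.x.copy()
        e1 = detect_microsaccades(filter_recording(rec))
        e2 = detect_microsaccades(filter_recording(swapped))
        assert [(e.onset, e.offset) for e in e1] == [(e.onset, e.offset) for e in e2]


class TestBinocularCombine:
    def test_identical_lists_map_to_same_intervals(self):
        runs = [(10, 20), (50, 60)]
        out = binocular_combine(runs, list(runs))
        assert [(a, b) for a, b, _, _ in out] == runs

    def test_monocular_event_excluded(self):
        out = binocular_combine([(10, 20), (100, 110)], [(12, 22)])
        assert len(out) == 1 and out[0][:2] == (10, 22)

    def test_union_of_overlapping_pair(self):
        # left 100-120 ms, right 110-130 ms at 1000 Hz -> union 100-130 ms
        out = binocular_combine([(100, 120)], [(110, 130)])
        assert out[0][:2] == (100, 130)


class TestRate:
    def test_fully_valid_trial(self):
        rec = make_recording(np.zeros(20_000))
        events = [None] * 10
        assert microsaccade_rate(events, rec) == pytest.approx(0.5)

    def test_blink_masked_time_excluded_from_denominator(self):
        valid = np.ones(20_000, bool)
        valid[:5000] = False  # 5 s masked out of 20
        rec = make_recording(np.zeros(20_000), valid=valid)
        assert microsaccade_rate([None] * 30, rec) == pytest.approx(2.0)


class TestLambdaSelection:
    def test_identical_seed_gives_identical_lambda_star(self):
        cfg = SyntheticConfig(amp_min=0.3, noise_sd=0.005, seed=21)
        rec, _ = generate_recording(cfg)
        sc = SurrogateConfig(n_surrogates=3, seed=5)
        a = optimal_lambda_surrogate(rec, sc)
        b = optimal_lambda_surrogate(rec, sc)
        assert a.lam_star == b.lam_star
        np.testing.assert_allclose(a.table.surrogate_rate, b.table.surrogate_rate)

    def test_acceptance_rule_holds_at_lambda_star(self):
        cfg = SyntheticConfig(amp_min=0.3, noise_sd=0.005, seed=22)
        rec, _ = generate_recording(cfg)
        sc = SurrogateConfig(n_surrogates=5, seed=0)
        sel = optimal_lambda_surrogate(rec, sc)
        assert sel.lam_star is not None
        row = sel.table[sel.table.lam == sel.lam_star].iloc[0]
        assert row.surrogate_rate <= sc.epsilon * row.real_rate
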