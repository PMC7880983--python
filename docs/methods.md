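# Methods

This note documents the models and numerical choices behind `fixaqc`:
what each stage computes, which parameters matter, what the simulator
does and does not emulate, and where the design was genuinely open.

## Coordinate and unit conventions

Gaze positions are converted from pixels to degrees of visual angle with
a per-axis arctangent about the screen center:
`x_deg = atan((x_px − c_x)·cm_per_px / d)`, with the pixel y axis
(top-left origin, growing downward) flipped so that positive y is upward
and event direction 90° means an upward microsaccade. A great-circle
(slant-corrected) conversion would differ only in the fourth decimal at
fixation eccentricities of a degree or two, so the separable form is
used. Timestamps are seconds internally; durations are reported in ms.
Missing data are carried as a per-sample validity mask — sentinel values
(`nan`, `-32768`, ...) are translated at the I/O boundary and never reach
any computation.

## Preprocessing

Order: interpolate → blink-mask → filter. Isolated single invalid
samples flanked by valid neighbours are replaced by the neighbour
midpoint first, so that a one-sample dropout does not trigger removal of
a ±200 ms blink margin. Blink segments are found in the pupil signal
(invalid/NaN pupil, or area below 20 device units under the threshold
rule), extended by `pad_ms` (default 200 ms) on each side, merged when
the padded intervals overlap, and masked in **both** eyes — binocular
analyses need joint validity, and a blink is a binocular occlusion.
Masking never re-validates a sample.

The detection lowpass is a triangular (Bartlett) kernel of
`round(0.020·fs)` taps forced odd (21 at 1000 Hz, 25 at 1200 Hz, 13 at
600 Hz), built with strictly positive taps and normalized to unit sum.
It is applied zero-phase (symmetric, centered); at segment edges the
truncated kernel is renormalized over the available samples rather than
extending the signal, so no data are fabricated at blink boundaries.
Segments shorter than the kernel are passed through unfiltered with a
warning. Quality metrics are computed on *unfiltered* degree-converted
data; only detection consumes the filtered signal. On white noise the
filter scales the variance by Σw² (≈0.0609 for the 21-tap kernel), which
the acceptance script verifies against measurement.

## Data-quality metrics

- **RMS-S2S** `= sqrt(mean(Δx²))` per axis over differences of adjacent
  valid samples only (a difference never straddles an invalid gap or a
  trial boundary); the 2-D value satisfies `rms_2d² = rms_x² + rms_y²`.
  For iid noise with per-axis σ, `rms_2d = 2σ`.
- **SD** is the per-axis standard deviation about the trial mean over
  valid samples. RMS-S2S responds to high-frequency noise and is blind
  to slow drift; SD is the converse — together they separate sensor
  noise from oculomotor drift, which is why a setup can have the best
  RMS and the worst SD at the same time.
- **Accuracy**: for each validation target, the componentwise median of
  gaze in the half-open window `[onset+0.5 s, onset+1.0 s)` (median for
  robustness to transients), then the mean of the Euclidean
  target-to-median distances over targets. Empty windows are skipped
  with a warning.
- **Data loss** is the per-eye proportion of device-invalid samples,
  taken before blink padding so it reflects what the device reported.
- **PSD**: averaged periodogram over non-overlapping 256-sample
  Hann-tapered blocks, no detrending, one-sided density normalization,
  frequency grid up to fs/2. Blocks never straddle invalid gaps. The
  256/Hann/no-overlap dialect is fixed so results are exactly
  reproducible; `nperseg` is exposed for uses (like drift-slope fits)
  that need finer frequency resolution than the 256-sample default's
  ~4 Hz.

## Microsaccade detection

Velocity comes from the smoothing 5-point stencil
`v_n = (x_{n+2}+x_{n+1}−x_{n−1}−x_{n−2})/(6Δt)` per valid segment (the
first/last two samples of a segment have no velocity; segments under 5
samples none at all). The stencil is exact for polynomials up to second
degree. The noise scale is the median-based estimator
`σ = sqrt(median(v²) − median(v)²)` per axis, per eye and per trial —
robust to the saccadic velocity tail, and estimated per trial because
noise differs across trials and eyes. A non-positive or non-finite
median variance raises a degenerate-threshold error rather than
producing thresholds silently.

A sample is saccadic when `(v_x/η_x)² + (v_y/η_y)² > 1` with `η = λσ`
(λ default 6). Maximal saccadic runs lasting at least 5 ms
(`ceil(min_duration_ms·fs/1000)` samples) are candidate events. With the
binocular requirement (default on, since the recordings are binocular),
temporally overlapping left/right candidates are paired greedily in time
order; the merged interval is the union and event properties are the
per-eye averages (directions averaged circularly). Finally, any event
starting less than 10 ms after its predecessor ends is discarded as an
overshoot. The separation rule deliberately runs on the **final**
(post-binocular) list: applied per eye it lets a sub-threshold monocular
noise blip suppress a genuine binocular event, which also breaks the
monotonicity of event count in λ. Discarding (rather than merging)
keeps overshoots from inflating durations; a merge variant was
considered and rejected for that reason.

Event intervals are half-open (`offset` = end of the last saccadic
sample), so `duration = offset − onset` exactly and two adjacent events
never "overlap". Detected onsets/offsets are accurate to about the
half-width of the Bartlett kernel (±10 ms at 1000 Hz): a zero-phase
filter smears the velocity pulse symmetrically, so the detected interval
brackets the true one rather than matching it to the sample.

The rate estimator divides the event count by the duration of *valid*
samples (joint validity of both eyes), so blink-masked spans do not
masquerade as low-rate fixation.

## Surrogate-based λ selection

For a data-driven threshold, surrogates of the recording are detected on
alongside the real data over a λ grid (default 3–12 in steps of 0.5):
λ* is the smallest grid value at which the mean surrogate rate is at
most ε (default 0.05) of the real rate. If no grid value qualifies the
result is `None` together with the per-λ diagnostic table — never a
silent default.

The default surrogate is an amplitude-adjusted Fourier transform (AAFT)
of the per-axis **increment** series, integrated back to positions: it
preserves the increment distribution exactly and the power spectrum
approximately, while destroying the temporal clustering of large
increments that makes a saccade a saccade. AAFT applied to the raw
position series (also available, tag `aaft`) fails as a null here: the
value distribution of a fixation trace is multimodal (plateaus between
saccades), and rank-remapping makes surrogates hop between modes,
*out-detecting* the real data. Surrogates are generated from the
unfiltered signal and then passed through the same Bartlett filter as
the real data, so a scattered large increment is smeared into a slow
low-velocity bump exactly as it would be in the pipeline; generating
surrogates from already-filtered data leaves them sharp and
over-detectable. A plain increment permutation (`shuffle_increments`)
is provided as a distribution-only null. Surrogate analysis operates on
the longest contiguous both-eye-valid stretch, since Fourier surrogates
need an unbroken series.

## Event properties, main sequence, waveforms

Amplitude is the bounding-box diagonal over the event interval (the
standard reading of "maximum excursion" in this algorithm family; a
max-distance-from-onset variant is available behind
`amplitude_rule='from_onset'`). Displacement is the onset→offset
distance, so amplitude ≥ displacement with equality for monotone
trajectories. Peak velocity is the largest 2-D speed among interval
samples with defined velocity. The main sequence is an ordinary
least-squares fit of peak velocity on amplitude (plain OLS matches the
linear-fit convention; outlier handling is left to callers).

Average waveforms take events with amplitude in a band (default
0.14–0.26°), extract the horizontal trace from onset over the duration
of the longest selected event (continuing along the recorded signal and
holding the last valid value at gaps), subtract the onset baseline,
flip the sign so the peak excursion is positive (left- and rightward
saccades superimpose), resample linearly onto a common time base, and
normalize each resampled trace by its maximum absolute value — the
normalization comes after resampling so every stored trace peaks at
exactly 1, and the pointwise average is bounded by 1.

## Agreement and reliability

Event matching is greedy one-to-one in time order under an any-overlap
rule (a configurable minimum overlap in seconds is available; the
default accepts a single shared sample). Because events within a list
are disjoint, greedy earliest-match attains the maximum matching
cardinality; the test suite verifies this against an exhaustive matcher
on all random lists of up to 8 events. F1 is the harmonic mean of
precision and recall, 0 when both are 0.

Test-retest reliability takes a tidy table of per-recording statistics
(participant × setup × repetition) and returns a symmetric setups ×
setups matrix of Pearson r over participants: diagonal cells correlate
repetition 1 with repetition 2 of one setup; off-diagonal cells average
r(setup A rep 1, setup B rep 2) with r(setup A rep 2, setup B rep 1).
Cells with fewer than three paired participants are NaN.

## The simulator

`generate_recording` composes, per trial:

1. **Event train.** Onset-to-onset structure: after each event a
   refractory gap (default 100 ms) plus a shape-2 gamma interval whose
   scale is set so the mean interval equals `1/rate` (the mean event
   duration is pre-estimated from the amplitude distribution). The
   shape-2 gamma gives the sub-Poisson regularity of fixational
   inter-saccade intervals; only the mean rate is treated as a
   calibrated quantity, and the realized rate tracks the target within
   a few percent across the 0.5–2.5 Hz range.
2. **Events.** Amplitudes are lognormal (log-mean ln 0.3, log-SD 0.45)
   truncated to [0.05, 1.0]°; directions are von Mises (κ = 1.5) around
   0° or 180° with equal probability, giving the horizontal bias of
   fixational saccades. Peak velocity is `slope·A + intercept` (defaults
   45 (°/s)/° and 10 °/s) plus Gaussian jitter (SD 3 °/s) so the main
   sequence has genuine residual scatter; the saccade is a raised-cosine
   velocity pulse, whose duration `T = 2A/V_peak` then follows from the
   amplitude and the jittered peak velocity. With probability 0.3 a
   scaled opposite-direction pulse (15% of A) follows immediately,
   modelling overshoot, so amplitude (max excursion) exceeds net
   displacement for those events.
3. **Drift.** Per-axis 1/f^α noise (α default 1) by spectral shaping of
   white noise, shared between the eyes, with **no power above 100 Hz**
   and the position SD scaled to 0.01°. The band limit encodes that
   oculomotor power lives below 100 Hz while the high-frequency floor of
   a gaze spectrum is sensor noise; the amplitude is set so the drift
   *velocity* is physiological (≈1.5 °/s sample-to-sample at 1200 Hz) —
   an unbounded 1/f band at larger amplitude implies drift speeds orders
   of magnitude above anything an eye produces, and would swamp the
   velocity noise estimate.
4. **Sensor noise and blinks.** Independent white noise per eye and axis
   (per-axis σ by preset), optional Poisson blinks with lognormal
   durations (median 150 ms) masking both eyes with NaN pupils.

Event parameters are drawn in continuous time from a seed substream that
never touches the sampling rate, so one seed yields the *same*
ground-truth events at 600 and 1200 Hz — the basis of the cross-rate
comparison. All randomness flows from a single `SeedSequence` with fixed
substream order (events, drift, left noise, right noise, blinks), making
outputs bitwise reproducible under a seed.

Presets (`spectrum1200`, `spectrum600`, `eyelink_u`, `eyelink_f`) fix
the sampling rate (1200/600/1000/1000 Hz) and illustrative per-axis
noise magnitudes (0.017/0.015/0.008/0.008°) ordered as the qualitative
RMS ranking of such setups; `eyelink_f` additionally applies a 15-ms
in-device Bartlett to emulate heuristic filtering. These magnitudes are
plausible defaults, not measurements of any device, and no quantitative
result in the test suite depends on their absolute values.

**What the simulator does not emulate:** tremor, pupil-size artifacts in
the gaze signal, saccadic curvature and dynamic overshoot asymmetries,
head-movement residuals, device-specific noise colour, or calibration
drift. Recovery results on synthetic data therefore show that the
pipeline is correct and well-calibrated under its stated model, not
that any particular hardware attains a given F1 on human data.

## Problem sizes and tolerances

Closed-form precision checks use 10⁵ samples (Monte-Carlo error well
under the 2% assertion tolerance). Simulation-based checks use 20-s
trials: 10–20 seeds per claim, 10 surrogates per recording for λ
selection. Confidence intervals in recovery tests are t-based across
seeds with a small absolute floor (e.g. 3–5% of the target) to keep
them meaningful when the across-seed variance collapses. The waveform
agreement bound between 600 and 1200 Hz is the resampling error bound
`dt_coarse · max|slope|` plus a small constant, which covers the
half-sample onset-alignment jitter inherent to snapping a continuous
onset to two different sample grids.

## Known limitations

- Degenerate-threshold errors make constant-velocity (e.g. perfectly
  still synthetic) segments unanalyzable by design; add noise or use the
  simulator's sensor-noise floor.
- The greedy matcher's optimality guarantee assumes non-overlapping
  events within each list (enforced); with a nonzero minimum-overlap
  requirement the greedy pairing can in principle be suboptimal.
- The λ* criterion compares surrogate to real rates per λ; on recordings
  with almost no saccades the real rate is itself near zero and no λ may
  qualify — the diagnostic table is the intended output in that case.
- Accuracy uses a fixed 500–1000 ms post-onset window; fixations slower
  than 500 ms to settle bias it upward.
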