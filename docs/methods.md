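# Methods

This note documents the models, parameter choices and numerical
conventions behind `gyrobeat`, and what the synthetic-data tests do and
do not establish about behaviour on real recordings.

## Signal model and working conventions

All event times are milliseconds from recording start; sample index `i`
maps to `i/fs·1000`. Recordings are upsampled to a 1 kHz working rate by
linear interpolation onto the uniform grid `t_k = k/target_fs`,
`k = 0..floor(duration·target_fs)`, with no extrapolation beyond the
original support. The grid covers the original last sample only when
`duration·target_fs` is an integer; in general the duration shrinks by
less than one target-rate sample period, which is the invariant the
resampler guarantees.

## Filtering

"Fourth-order zero-phase Butterworth" is implemented as a 4th-order
design applied forward–backward (`sosfiltfilt`, odd-symmetric padding):
an effective 8th-order magnitude response with exactly zero phase, which
is what preserves fiducial timing at the millisecond scale the interval
analysis needs. The alternative reading (2nd-order design, doubled by
the two passes) is available by passing `order=2`.

The powerline comb notch is a cascade of second-order IIR notches at
every harmonic of the 50 Hz base below Nyquist, with constant absolute
−3 dB bandwidth `base_hz/q` (i.e. `Q_k = k·q` at harmonic `k`). A
cascade is used rather than a single comb section because a comb
requires the fundamental to divide the sampling rate exactly, which
fails at the 256 Hz acquisition rate. The default `q = 60` was chosen
from the forward–backward magnitude response: the two-pass response at a
detuning δ from a harmonic is approximately `δ²/(δ²+(bw/2)²)`, and
`q = 60` (bw ≈ 0.83 Hz) keeps content ≥ 2 Hz away from any harmonic
within 5 % of its amplitude while still nulling the harmonics
themselves; a wider notch (e.g. `q = 35`) violates that selectivity
bound once the response is squared by the second pass.

## Reference R-peak detection

Classic Pan–Tompkins constants: 5–15 Hz band-pass (zero-phase), 5-point
derivative, squaring, 150 ms moving-window integration, 200 ms
refractory period, dual signal/noise thresholds
(`THR = NPKI + 0.25(SPKI − NPKI)`, 0.125/0.875 running updates,
0.25/0.75 on search-back), search-back when a gap exceeds 1.66× the
running RR average, and a 360 ms slope-ratio T-wave check. Two
departures from textbook phrasing, both in service of timing accuracy:
the derivative and integration kernels are applied centred (symmetric)
so integrated-signal fiducials are not systematically delayed, and each
accepted fiducial is refined to the local maximum of the band-passed ECG
within ±40 ms (duplicates collapse; the refractory gap is re-imposed
after refinement). Accuracy is assessed by ground-truth recovery on
synthetic ECG, not bit-level agreement with any particular historic
implementation.

## Template matching

The NCC is the zero-normalized form: the local window mean is removed
per alignment, making the score invariant to positive affine transforms
of the signal and bounded in [−1, 1]. Only full-overlap alignments are
computed. Numerics: the numerator reduces to a correlation with the
mean-removed template (the window-mean term vanishes because the
template deviations sum to zero); window variances come from sliding
sums, clamped at zero, and windows whose variance is ≤ 1e−12 of the
maximum window variance are defined to score 0 (flat-lined segments
would otherwise produce 0/0). Values are clipped to [−1, 1] to absorb
last-ulp excursions. Equivalence with a direct per-alignment evaluation
of the formula is enforced to 1e−10 in the tests.

Peak picking follows the named-parameter semantics of standard
`findpeaks`-style tools: local maxima are filtered by topographic
prominence (≥ 0.5 by default), then retained greedily in descending
height order — earlier index wins ties — subject to pairwise spacing
≥ 500 ms. A detected peak at alignment `i` is reported at
`(i + anchor)/fs`, where the anchor is the template's maximum-absolute
sample (its systolic peak); this makes reported times comparable across
templates and against ground-truth AO times. Note the prominence rule
measures peak-to-base relief of the NCC curve, not absolute match
quality: on beat-free band-limited noise the NCC fluctuates with
σ ≈ (2·bandwidth·template_duration)^(−1/2) ≈ 0.2, so its global maximum
can clear a 0.5 prominence bar even though its value is far below a true
match (≈ 0.95). False positives in quiet segments are therefore possible
by design, exactly as in practice; the cycle-based evaluation attributes
them correctly.

`suggest_template` automates the manual guideline (start two–three waves
before the systolic peak, end after the last diastolic wave): it takes
the highest-prominence positive peak as the systolic candidate, requires
it to exceed 15× the median absolute signal level (pure band-limited
noise peaks at 4–12×, synthetic beat trains at ≥ 40× even at 5 dB SNR —
below the bar it raises and advises manual selection), walks back to the
last pre-peak extremum under 30 % of the systolic magnitude and then up
to two zero crossings further, bounded by one carrier period (estimated
from zero-crossing spacing at the peak); the end is one zero crossing
after the last excursion above 20 % of the systolic magnitude, capped at
0.9× the local cycle length (so a short following cycle can never leak
the next beat into the template) and at 700 ms past the peak. The 30 %,
20 % and 15× thresholds are heuristics validated only on synthetic data.

## Cycle annotation

Reference R peaks define half-open cycles `[R_j, R_{j+1})` (a boundary
peak belongs to the later cycle; the window offset δ defaults to 0). Per
cycle: no detection → FN; otherwise the detection nearest to
`R_j + expected_delay` is the TP candidate and all other in-cycle
detections are FPs; if the nearest detection is further than the
tolerance (±150 ms default) the cycle is a DE. The expected delay, when
not supplied, is the median signed offset between each cycle's R peak
and its nearest in-cycle detection — a robust, reproducible stand-in for
the manual plausibility judgement the protocol otherwise requires. The
FP tally counts only extra in-cycle peaks, so `TP + FP + DE` equals the
number of detections attributed to cycles and `TP + FN + DE` equals the
number of cycles; the DE term enters both the sensitivity and PPV
denominators. Interval pairs are formed only between consecutive TP
cycles (FN/DE-corrupted intervals are dropped; FP peaks never enter
interval construction).

## Agreement statistics

Regression is OLS of test (GCG) intervals on reference (ECG) intervals;
R² is the squared correlation. Bland–Altman uses the classic 1986
formulation: bias = mean difference, LoA = bias ± 1.96·SD (the 1.96 is
fixed, not t-based), 95% CI of the bias = bias ± t₀.₉₇₅,ₙ₋₁·SD/√n, and
the CI of each limit uses SE = SD·√(3/n) with the same t quantile. The
p-value attached to the bias is a one-sample t-test of zero mean
difference. No per-subject clustering correction is applied: cohort
evaluation pools all interval pairs, matching the protocol being
reproduced. Sensitivity/PPV are reported to the nearest integer percent.

## Synthetic data generator

The generator emulates what the detector assumes and nothing more:

* **Rhythm** — RR intervals i.i.d. Normal(mean, SDNN), truncated at
  ±4 SDNN. Defaults 800 ± 50 ms (a resting adult; SDNN of healthy
  resting subjects is typically 30–70 ms). No autocorrelation or
  respiratory sinus arrhythmia — the detector makes no rhythm assumption
  beyond the 500 ms spacing floor, so white HRV suffices.
* **ECG** — per beat a dominant Gaussian R spike (σ 12 ms, amplitude 1)
  with Q/S dips and smaller P/T humps at fixed phase offsets; R times
  are snapped to the sample grid so the apex is exact.
* **GCG** — per beat, at `R + delay` with delay ~ Normal(100, 3) ms (a
  pre-ejection-period scale and its beat-to-beat variability), a
  systolic Hann-windowed cosine burst (18 Hz, 120 ms, amplitude 1,
  anchored so its extremum is the AO fiducial) and a diastolic burst at
  60 % amplitude (14 Hz, 100 ms) starting 320 ms after systolic onset.
  Both carriers sit inside the 7–30 Hz analysis band. Per-beat amplitude
  and frequency jitter (5 %), multiplicative respiratory modulation
  (0.25 Hz, depth 0.2) and additive white Gaussian noise at a prescribed
  SNR (10 dB default, defined against the clean-signal RMS before
  filtering) complete the model.

What this does **not** emulate: pathological morphology variability
(e.g. valvular disease produces atypical, less stereotyped complexes),
posture/sensor-placement drift, motion artefacts, non-stationary noise,
or template drift over long recordings. Passing the synthetic cohort
therefore demonstrates correctness of the pipeline's mechanics and its
behaviour under the stated noise/jitter model — not field performance on
clinical data, where sensitivity and PPV are substantially lower.

## Problem sizes

The pooled synthetic-cohort evaluation uses 20 records × 200 beats
(≈ 53 min of paired signal at 1 kHz), chosen to give ≈ 4 000 evaluated
cycles and ≈ 3 960 interval pairs — enough that the regression slope and
R² estimates are stable to the third decimal while the whole evaluation
completes in well under a minute. Under this model R² is bounded near
`Var(RR)/(Var(RR) + 2σ_delay²) ≈ 0.993`: the delay jitter is
irreducible, so R² ≥ 0.99 is a meaningful but attainable bar.

## Known limitations

* Single fixed template per record; no adaptive or multi-template
  tracking, no automatic polarity inversion (negate the channel if the
  sensor orientation flips the waveform).
* The DE rule is a fixed ±150 ms plausibility window around a
  data-estimated delay; protocols that annotate DEs manually may count
  differently on borderline cycles.
* The CSV reader is the only ingestion path; acquisition-specific binary
  formats are out of scope.
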