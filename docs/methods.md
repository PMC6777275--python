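# Methods

This note documents the models and numerical choices behind
`shiftpulse`: what each stage computes, why the defaults are what they
are, and what the synthetic-data experiments do and do not demonstrate.

## Data model

A *session* is one wrist-PPG recording over (nominally) one 9-hour
clinical shift, 14:00–23:00 local time. It consists of a 64 Hz
blood-volume-pulse waveform (`BvpRecording`) and an interbeat-interval
log (`IbiLog`) of `(offset_s, ibi_s)` pairs relative to the session
start, where the offset stamps the beat at the **end** of the interval.
Timestamps are UTC epoch seconds; shift windows are local wall-clock and
converted through a configurable UTC offset, which keeps tests free of
timezone-database ambiguity. IBI logs are validated on construction:
strictly increasing offsets, positive intervals, every interval inside
the session.

## Synthetic sessions (IPFM generator)

The generator exists because per-shift wrist recordings of this kind are
not publicly deposited; it emulates their second-order structure with
exact ground truth.

**Beat process.** Integral pulse frequency modulation: the instantaneous
rate

    r(t) = 1/mean_rr + a_LF sin(2π f_LF t) + a_HF sin(2π f_HF t) + ε(t)

is integrated with step 1/256 s (beat-time quantization ≪ the 1/64 s
sample period) and a beat fires at each integer crossing, located by
linear interpolation; with zero modulation and noise the beats land at
exact multiples of `mean_rr`. ε is white rate jitter (per-step i.i.d.
normal, default SD 0.02 beats/s), giving a broadband tachogram floor.

**Beat-averaging transfer.** The interval series does not see the rate
modulation directly: each interval averages the rate over one beat, a
boxcar of length ≈ `mean_rr`, so a modulation at frequency *f* reaches
the RR series with gain `sinc(f·mean_rr)` and stamped at the interval's
end (half-a-beat lag). `rate_amplitude_for_rr_amplitude` inverts this
exactly, so requesting a 10 ms RR amplitude at 0.25 Hz really produces a
10 ms tachogram sinusoid (band power 10²/2 = 50 ms²); the
`GroundTruth.expected_*_power_ms2` oracles include the same factor.

**Defaults as study conditions.** The defaults describe a mid-shift
emergency-physician cohort: `mean_rr = 0.80 s`; LF modulation at
0.10 Hz and HF at 0.25 Hz (the centers of the conventional bands) with
RR amplitudes 82.4 and 128.8 ms, i.e. sinusoidal band powers of
3.4×10³ and 8.3×10³ ms², LHR 0.41 and an implied interval SD of
~0.108 s — a mutually consistent set matching the magnitudes such
cohorts report. The default `dropout_fraction` of 0.915 renders all but
~8.5% of the session undetectable, the interpretable-data level
observed with wrist PPG during active clinical work.

**Waveform renderer.** Each beat places a difference-of-Gaussians pulse
(upstroke σ = 0.08 s, undershoot 0.20 at σ = 0.15 s, unit amplitude) at
its beat time on the 64 Hz grid, over baseline noise (SD 0.04). The
template is symmetric so zero-phase filtering preserves peak positions;
its width keeps neighbour-pulse overlap small enough that peak shifts
stay well under one sample at physiological rates (a broader undershoot
measurably violates that).

**Dropout.** Artifact is modelled as contiguous blocks (default 300 s)
totalling exactly `dropout_fraction × duration`, placed with
Dirichlet-distributed clean gaps and filled with white noise of
pulse-scale amplitude (SD 1.0) — "detection-defeating": no beat
structure survives. Long blocks mirror the reality that unusable
stretches of wrist data come in extended runs (motion, lost skin
contact), and at 91.5% dropout they are what allows any clean run long
enough for spectral analysis to exist at all.

**Cohort simulator.** `make_cohort` draws per-participant physiology:
mean RR ~ N(0.80, 0.05) s (clipped to 0.55–1.4), and modulation
amplitudes scaled by a *shared* lognormal power factor (log-SD 0.2)
times a small independent "balance" jitter per band (log-SD 0.05), each
location-shifted so the squared scale has unit mean (cohort-expected
band powers equal the base configuration). The shared factor encodes an
empirical feature of such cohorts: large between-person spread in LF
and HF power but a nearly constant LF:HF ratio, so per-person LF and HF
are almost proportional. Q4 sessions reuse the participant's Q1
parameters plus the requested effect shifts; with zero effect the
generating parameters are identical across quarters and only the
realization differs, which is exactly what makes zero-effect cohorts a
valid type-I benchmark. About 10/21 of participants are labelled
residents, the rest attendings.

**What the generator does not emulate:** pulse-morphology changes,
respiration as a signal (HF modulation is a pure sinusoid, not a
respiratory chain), baroreflex feedback, non-stationarity across the
shift, or graded (partial-quality) artifact — dropout is binary. Tests
passing on this generator show the *pipeline* is correct and calibrated;
they do not show that real wrist PPG meets the generator's assumptions.

## Beat detection

A stand-in for the wearable's proprietary onboard detector, with the
same contract (beats only from clean signal):

1. zero-phase Butterworth band-pass, 0.5–8 Hz, order 3;
2. sliding signal-quality gate: 10 s windows, hop 2.5 s; a window
   passes when the cardiac-band (0.7–3.5 Hz) share of its pass-band
   power exceeds 0.60. Spectra are whitened by the clamped filter
   response so broadband noise scores the flat bandwidth ratio (~0.37)
   regardless of the filter's shaping; clean pulse trains score >0.9.
   A *sample* is accepted only if **every** window covering it passes —
   this AND rule means acceptance cannot leak into an artifact block
   longer than one window, at the cost of discarding up to one window
   of clean signal on each side of a block;
3. peak picking with refractory distance 0.25 s, height and prominence
   floors at 0.4× the 95th-percentile accepted amplitude, and parabolic
   sub-sample refinement (three-point quadratic around each peak),
   which removes the ±0.5-sample grid quantization;
4. intervals are logged only when both peaks and the entire span lie in
   accepted samples and the length is physiological (0.25–3.0 s), so no
   interval bridges a quality-gate boundary.

On clean synthetic sessions this achieves ≥0.98 sensitivity and
precision at a 1-sample (1/64 s) match tolerance; pure-noise recordings
yield zero beats; no beats are emitted inside ground-truth dropout
blocks. Equivalence with any particular commercial detector is not
claimed and is untestable without its raw data.

## Screening

Three checks, mirroring a repeated-measures inclusion protocol: shift
overlap (any positive overlap by default; a stricter minimum is
configurable — the protocol states the check's purpose but no cutoff),
a minimum of 300 registered beats (inclusive at exactly 300), and a
manual-review flag carried in the metadata (the human judgment is an
input, not automated; the overlay-plot data for that review are
exported). Cohort selection keeps participants with an included session
in both Q1 and Q4; several included sessions in one quarter resolve
deterministically to the earliest shift date.

## Time-domain metrics

MPR, MRRI and SDNN use **all** logged intervals; RMSSD alone is
restricted to the single longest contiguous run, because successive
differences across detection gaps are meaningless. Contiguity tolerance
defaults to one sample period (1/64 s), the device's beat-offset
quantization: a one-tick mismatch between offset step and logged
interval is contiguous, two ticks split the run. Ties between
equal-length runs resolve to the earliest. SDNN uses the sample (n−1)
denominator; the median of an even-count series is the mean of the two
middle values. These conventions are what the exactness tests pin down.

## Frequency-domain metrics

Spectral analysis runs on the RR interval series, not the raw waveform:
band powers in ms² are only meaningful for a tachogram. The longest
contiguous run (default; a whole-log mode that splines across gaps is
available as `SpectralConfig(use_longest_run=False)`) is cubic-spline
interpolated onto a uniform 4 Hz grid in milliseconds, and the PSD is a
Welch periodogram: 300 s Hann segments, 50% overlap, linear detrend;
runs shorter than one segment shrink the segment to the run (logged).
Band powers integrate the PSD by trapezoid over LF [0.05, 0.15) and
HF [0.15, 0.40) Hz — half-open so the shared 0.15 Hz edge counts once.
Runs shorter than `2/hf_low` ≈ 13.3 s are rejected as unresolvable.
Validation is by closed form: a sinusoidal RR modulation of amplitude
A ms recovers A²/2 ms² in its band within 10% on an hour-long run, and
a dual-band modulation recovers LHR = (A_LF/A_HF)² within 15%. Note
that single-segment estimates (runs ≲ 600 s) are heavy-tailed; see the
calibration remark below.

## Interpretable-data yield

The IBI log is rasterized on the recording's own 64 Hz grid: sample *k*
(time k/64) is covered when it lies inside some interval
`[offset − ibi, offset]` (closed; marking is idempotent, and a fully
contiguous log covers the whole recording including sample 0). The
yield quotient is 100 × covered/total samples. A literal 1-second-bin
variant (`coverage_vector_1s_bins`, bins anchored at t = 0, a bin
covered if any covered sample falls in it) is provided for sensitivity
analysis; the per-sample reading is primary because it is the only one
with a unique answer. Aggregation pools seconds — Σcovered/Σtotal — not
per-session percentages, matching a "fraction of grand total recording
time" definition. On synthetic sessions the quotient tracks
100·(1 − dropout_fraction) to within beat-length edge effects at each
block boundary.

## Paired cohort comparison

For each metric the per-participant differences d = Q4 − Q1 enter a
paired Student *t* test, t = mean(d)/(sd(d)/√n), df = n − 1, two-sided
p. Zero-variance differences with nonzero mean produce an infinite t
and p = 0 with a warning. Post-hoc power is the standard noncentral-*t*
power at the observed standardized effect mean(d)/sd(d):
P(|T| > t_crit) with ncp = effect·√n — exactly α at zero observed
effect — validated against a 10⁵-replicate Monte-Carlo oracle to ±0.01
(scipy's `nct` overflows at extreme noncentrality; an asymptotic normal
fallback covers that corner). Seven tests are run uncorrected, and
every generated report carries a note saying so. Subgroup filters
(residents/attendings) reproduce the secondary-analysis layout.

**Calibration.** On zero-effect simulated cohorts (n = 21 pairs) the
per-metric type-I rate at α = 0.05 falls in the nominal range and null
p-values are uniform (KS). The calibration experiments use 900 s clean
sessions: long enough that the Welch band powers average several
segments. With 300 s sessions the LF/HF estimates are single-segment
and heavy-tailed, and the t test on LHR turns *conservative*
(rate ≈ 0.015) — a warning that ratio metrics from short runs violate
the test's normality assumption, not a defect of the test at
study-scale recording lengths. An injected Q4 mean-RR shift equal to
the between-participant SD (0.05 s) is detected (p < 0.05) in >90% of
replicate cohorts at n = 21.

## Pipeline and reproducibility

`run_pipeline` persists every intermediate as plain CSV/JSON
(screening table, attrition log, per-session metrics, per-session and
pooled yield, the comparison table) plus a manifest with the config
SHA-256, seed, and package version; all stages are pure functions of
(inputs, config, seed), and identical runs are byte-identical in their
metric outputs. All randomness flows from `numpy.random.default_rng`
seeded from the run seed; the waveform renderer uses a seed stream
separate from the beat process so waveform noise never perturbs beat
times.

**Problem sizes.** The test-suite and acceptance experiments use scaled
sessions — 120 s for detection fidelity, 900 s–1 h for spectral
recovery and calibration, 10-min sessions for cohort means, hundreds of
replicate cohorts via the ideal-detector (ground-truth IBI) path — sizes
chosen so the statistical assertions have the precision their
tolerances need. Full 9-hour sessions run through the same code paths
(the default `SyntheticConfig` is a 9-hour shift) and are exercised in
miniature by the pipeline tests.

## Known limitations

- The detector is tuned for the synthetic pulse template family; real
  wrist PPG morphology (dicrotic notches, amplitude drift, graded
  artifact) would need threshold re-validation.
- The quality gate's AND rule sacrifices up to one window (10 s) of
  clean data at each artifact boundary; at very high dropout this
  dominates the difference between detected yield and the ground-truth
  coverage fraction.
- Spectral estimates from runs shorter than a few Welch segments are
  heavy-tailed; LHR inherits this worst. Statistics on such runs should
  be treated with caution (see Calibration).
- Post-hoc power at the observed effect is reported because the
  reproduced design reports it; it is a deterministic transform of the
  p-value and should not be read as independent evidence.
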