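# shiftpulse

Pulse-rate-variability (PRV) analysis of wearable photoplethysmography
(PPG) recordings made during clinical shifts.

Wrist-worn PPG biosensors record a blood-volume-pulse (BVP) waveform and
an interbeat-interval (IBI) log while a physician works a shift. Such
recordings promise a low-burden, objective window on workplace stress,
but wrist PPG during active clinical work is heavily corrupted by motion
artifact and poor skin contact, so both the analysis and the *data-yield
accounting* need to be explicit and reproducible. `shiftpulse` is a
tested implementation of that pipeline for researchers working with
per-shift biosensor exports (or evaluating whether the modality is worth
deploying at all):

- **Session I/O** — vendor-style CSV exports: a 64 Hz BVP waveform, an
  IBI log of `(offset, interval)` pairs, and a JSON metadata sidecar
  (participant, role, academic-year quarter, shift window).
- **Beat detection** (`detect_beats`) — band-pass filtering, a sliding
  signal-quality gate that rejects artifact windows, refractory-limited
  peak picking; corrupted segments contribute no beats.
- **Screening** — the three inclusion checks (shift overlap, ≥300
  registered beats, manual waveform review) and paired-cohort selection:
  a participant enters the analysis only with one included session in
  both the first (Q1, Jul–Sep) and fourth (Q4, Apr–Jun) quarter.
- **Time domain** — median pulse rate MPR = median(60/RR); mean interval
  MRRI; SDNN (sample SD of intervals); RMSSD
  `sqrt(mean((RR_{i+1}-RR_i)^2))`, computed on the single longest
  contiguous beat run.
- **Frequency domain** — cubic-spline RR tachogram at 4 Hz, Welch PSD
  (300 s Hann segments, 50% overlap, linear detrend), band powers in
  LF 0.05–0.15 Hz and HF 0.15–0.40 Hz (ms²), and their ratio LHR.
- **Yield** — the interpretable-time quotient: the fraction of total
  recording time covered by detected beat-to-beat intervals, rasterized
  on the 64 Hz sample grid; sessions pool by time, not by averaging
  percentages.
- **Cohort statistics** — paired Student *t* tests on Q4 − Q1
  per-participant differences for each of the seven metrics, with
  post-hoc power from the noncentral-*t* at the observed effect size.
  Seven uncorrected tests; every report says so.
- **Synthetic sessions** — an integral-pulse-frequency-modulation (IPFM)
  beat generator with LF/HF sinusoidal rate modulation, a pulse-template
  waveform renderer, and contiguous artifact-dropout blocks, all with
  exact ground truth, so every stage is testable without any raw data.

## Worked example

Simulate a half-hour session in which 40% of the recording is destroyed
by artifact bursts, detect beats, and compute the session metrics:

```python
from shiftpulse import (SyntheticConfig, generate_session, detect_beats,
                        session_metric_dict, session_yield)

cfg = SyntheticConfig(duration_s=1800.0, dropout_fraction=0.4,
                      dropout_block_s=300.0, seed=42)
truth, bvp = generate_session(cfg)
ibi = detect_beats(bvp)
print(session_metric_dict(ibi))
rep = session_yield(ibi, bvp.duration_s)
print(f"yield: {rep.covered_s:.1f} s of {rep.total_s:.0f} s -> {rep.quotient_pct:.2f}%")
```

prints (rounded):

```
{'MPR': 74.7142, 'MRRI': 0.7999, 'SDNN': 0.1092, 'RMSSD': 0.1161,
 'LF': 3624.5479, 'HF': 8586.0261, 'LHR': 0.4221}
yield: 1046.3 s of 1800 s -> 58.13%
```

The detector recovered the generator's physiology — mean interval
0.80 s (≈75 bpm), interval SD 0.11 s, LF/HF band powers of ~3.6×10³ and
~8.6×10³ ms² (LHR 0.42) — and the yield quotient reports 58% of the
session as interpretable: the artifact blocks (40% of the time) plus
detector edge losses around them carry no beats.

A full simulated study (cohort simulation → detection → screening →
metrics → yield → paired comparison, with all intermediates persisted
as CSV/JSON) runs from the shell:

```bash
shiftpulse run --out study/ --n-participants 6 --seed 1
```

and writes `screening.csv`, `cohort.json`, per-session metric JSONs,
`yield.csv` (with a pooled footer row), `tables.csv` (the seven-metric
paired-comparison table) and a run manifest with the config hash and
seed. `shiftpulse simulate/detect/screen/metrics/yield/compare` expose
the individual stages.

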