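"""Synthetic wrist-PPG sessions with known ground truth.

The study this package analyzes recorded 9-hour emergency-department
shifts with a wrist photoplethysmograph; the raw recordings are not
public.  This module generates sessions with the same second-order
structure so that every downstream stage (beat detection, screening,
time/frequency metrics, yield, cohort statistics) can be validated
against exact ground truth.

The beat process is an integral pulse frequency modulation (IPFM) model:
an instantaneous rate

    r(t) = 1/mean_rr + a_LF * sin(2*pi*f_LF*t) + a_HF * sin(2*pi*f_HF*t) + eps(t)

is integrated on a fine grid and a beat fires each time the integral
crosses a successive integer.  Low-frequency (~0.1 Hz) and
high-frequency (~0.25 Hz) sinusoidal rate modulation reproduce the two
spectral bands of pulse-rate variability; ``eps`` is white rate jitter.

The waveform renderer places a fixed difference-of-Gaussians pulse
template at every beat time on a 64 Hz sample grid and corrupts a
configurable fraction of the session with contiguous "dropout" blocks of
detection-defeating broadband noise, mimicking the motion-artifact
bursts that made most of the study's wrist data unusable.

Default modulation amplitudes are chosen so that an uncorrupted session
reproduces the magnitudes a mid-shift physician cohort shows: mean
interbeat interval ~0.80 s, LF power ~3.4e3 ms^2, HF power ~8.3e3 ms^2
(hence LF/HF ~0.41 and interval SD ~0.11 s), and the default dropout
fraction leaves less than a tenth of the session usable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .session_io import DEVICE_FS_HZ, BvpRecording, IbiLog

__all__ = [
    "PulseShape",
    "SyntheticConfig",
    "GroundTruth",
    "SessionPair",
    "modulation_transfer",
    "rate_amplitude_for_rr_amplitude",
    "generate_rr_series",
    "render_bvp",
    "generate_session",
    "make_cohort",
]

#: Integrator step for the IPFM beat process.  Beat-time quantization
#: error is O(dt) = 1/256 s, well below the 1/64 s waveform sample period.
IPFM_DT_S = 1.0 / 256.0


def modulation_transfer(mod_freq_hz: float, mean_rr_s: float) -> float:
    """RR-series gain of a rate modulation at ``mod_freq_hz``.

    Each interval averages the instantaneous rate over one beat, so the
    interval series sees a sinusoidal rate modulation through a
    beat-length boxcar: gain ``sinc(f * mean_rr)`` (numpy convention).
    """
    return float(np.sinc(mod_freq_hz * mean_rr_s))


def rate_amplitude_for_rr_amplitude(
    rr_amp_s: float, mean_rr_s: float, mod_freq_hz: float = 0.0
) -> float:
    """Rate-modulation amplitude (beats/s) producing a given RR amplitude.

    For small modulation the interval series tracks the reciprocal rate
    (an RR swing of ``A`` seconds needs a rate swing of ``A/mean_rr**2``)
    attenuated by the beat-averaging gain of :func:`modulation_transfer`.
    """
    return rr_amp_s / (mean_rr_s**2 * modulation_transfer(mod_freq_hz, mean_rr_s))


@dataclass(frozen=True)
class PulseShape:
    """Difference-of-Gaussians per-beat waveform template.

    A positive Gaussian of width ``sigma_s`` (systolic upstroke, peak at
    the beat time) minus a broader Gaussian scaled by ``undershoot``
    gives a plausible pulsatile shape with a post-beat dip.
    """

    amplitude: float = 1.0
    sigma_s: float = 0.08
    undershoot: float = 0.20
    undershoot_sigma_s: float = 0.15

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        main = np.exp(-0.5 * (t / self.sigma_s) ** 2)
        dip = self.undershoot * np.exp(-0.5 * (t / self.undershoot_sigma_s) ** 2)
        return self.amplitude * (main - dip)

    @property
    def half_width_s(self) -> float:
        """Support used when rendering (±4 undershoot widths)."""
        return 4.0 * self.undershoot_sigma_s


# Default modulation amplitudes (rate units, beats/s).  With mean RR
# 0.80 s these correspond to RR swings of ~82 ms (LF) and ~129 ms (HF),
# i.e. sinusoidal band powers of ~3.4e3 and ~8.3e3 ms^2 and a combined
# interval SD of ~0.108 s — the magnitudes observed in the target cohort.
_DEFAULT_MEAN_RR_S = 0.80
_DEFAULT_LF_AMP = rate_amplitude_for_rr_amplitude(0.0824, _DEFAULT_MEAN_RR_S, 0.10)
_DEFAULT_HF_AMP = rate_amplitude_for_rr_amplitude(0.1288, _DEFAULT_MEAN_RR_S, 0.25)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic session.

    ``lf_mod``/``hf_mod`` are (frequency Hz, amplitude beats/s) pairs;
    frequencies must sit inside the conventional LF (0.05-0.15 Hz) and
    HF (0.15-0.40 Hz) bands.  ``dropout_fraction`` of the session is
    replaced by contiguous noise blocks of nominal length
    ``dropout_block_s``.  The default duration is a full 9-hour shift.
    """

    duration_s: float = 32400.0
    mean_rr_s: float = _DEFAULT_MEAN_RR_S
    lf_mod: tuple[float, float] = (0.10, _DEFAULT_LF_AMP)
    hf_mod: tuple[float, float] = (0.25, _DEFAULT_HF_AMP)
    white_noise_sd: float = 0.02
    dropout_fraction: float = 0.915
    dropout_block_s: float = 300.0
    pulse_shape: PulseShape = field(default_factory=PulseShape)
    baseline_noise_sd: float = 0.04
    dropout_noise_sd: float = 1.0
    start_time: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.duration_s > 0):
            raise ValueError("duration_s must be positive")
        if not (0.25 <= self.mean_rr_s <= 3.0):
            raise ValueError("mean_rr_s must lie in [0.25, 3.0] s")
        if not (0.05 < self.lf_mod[0] < 0.15):
            raise ValueError("LF modulation frequency must lie in (0.05, 0.15) Hz")
        if not (0.15 < self.hf_mod[0] < 0.40):
            raise ValueError("HF modulation frequency must lie in (0.15, 0.40) Hz")
        if self.lf_mod[1] < 0 or self.hf_mod[1] < 0:
            raise ValueError("modulation amplitudes must be non-negative")
        if not (0.0 <= self.dropout_fraction < 1.0):
            raise ValueError("dropout_fraction must lie in [0, 1)")
        if self.dropout_block_s <= 0:
            raise ValueError("dropout_block_s must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Exact generator state for one session (the test oracle).

    ``beat_times`` excludes the implicit beat at t=0 that anchors the
    integrator; ``rr`` has the same length, with ``rr[0] = beat_times[0]``.
    ``dropout_intervals`` are the (start_s, end_s) corrupted blocks and
    ``coverage_mask`` the per-sample (64 Hz) renderability flag.
    """

    config: SyntheticConfig
    beat_times: np.ndarray
    rr: np.ndarray
    dropout_intervals: tuple[tuple[float, float], ...]
    coverage_mask: np.ndarray

    @property
    def expected_lf_power_ms2(self) -> float:
        """Closed-form band power of the LF sinusoidal modulation
        (including the beat-averaging gain of the interval series)."""
        f, a = self.config.lf_mod
        mean = self.config.mean_rr_s
        amp_ms = a * mean**2 * modulation_transfer(f, mean) * 1000.0
        return amp_ms**2 / 2.0

    @property
    def expected_hf_power_ms2(self) -> float:
        f, a = self.config.hf_mod
        mean = self.config.mean_rr_s
        amp_ms = a * mean**2 * modulation_transfer(f, mean) * 1000.0
        return amp_ms**2 / 2.0

    def in_dropout(self, times: np.ndarray) -> np.ndarray:
        """Boolean mask: which of ``times`` fall inside a dropout block."""
        times = np.asarray(times, dtype=float)
        mask = np.zeros(times.shape, dtype=bool)
        for start, end in self.dropout_intervals:
            mask |= (times >= start) & (times < end)
        return mask

    def clean_ibi_log(self) -> IbiLog:
        """The IBI log an ideal detector would produce.

        Contains every interval whose span lies entirely outside the
        dropout blocks (both endpoint beats renderable, no block
        crossed), matching the premise that only contiguous clean
        signal yields logged intervals.
        """
        t = self.beat_times
        prev = np.concatenate([[0.0], t[:-1]])
        keep = ~self.in_dropout(t) & ~self.in_dropout(prev)
        for start, end in self.dropout_intervals:
            keep &= ~((prev < start) & (t >= end))  # interval straddles a block
        return IbiLog(self.config.start_time, t[keep], self.rr[keep])


def _dropout_intervals(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[tuple[float, float], ...]:
    """Contiguous non-overlapping dropout blocks totalling exactly
    ``dropout_fraction * duration_s`` seconds."""
    total = config.dropout_fraction * config.duration_s
    if total <= 0:
        return ()
    n_blocks = max(1, math.ceil(total / config.dropout_block_s))
    lengths = np.full(n_blocks, total / n_blocks)
    free = config.duration_s - total
    gaps = rng.dirichlet(np.ones(n_blocks + 1)) * free
    starts = np.cumsum(gaps[:-1]) + np.concatenate([[0.0], np.cumsum(lengths[:-1])])
    return tuple((float(s), float(s + l)) for s, l in zip(starts, lengths))


def generate_rr_series(config: SyntheticConfig) -> GroundTruth:
    """Run the IPFM model and return exact beat times, RR series and
    the dropout/coverage layout for one session."""
    rng = np.random.default_rng(config.seed)

    dt = IPFM_DT_S
    n_steps = int(round(config.duration_s / dt))
    t = np.arange(n_steps) * dt
    rate = np.full(n_steps, 1.0 / config.mean_rr_s)
    f_lf, a_lf = config.lf_mod
    f_hf, a_hf = config.hf_mod
    if a_lf:
        rate += a_lf * np.sin(2.0 * np.pi * f_lf * t)
    if a_hf:
        rate += a_hf * np.sin(2.0 * np.pi * f_hf * t)
    if config.white_noise_sd:
        rate += rng.normal(0.0, config.white_noise_sd, size=n_steps)
    np.clip(rate, 0.05, None, out=rate)

    # integral of the rate at the step edges; beats fire at integer crossings
    integral = np.concatenate([[0.0], np.cumsum(rate) * dt])
    n_beats = int(math.floor(integral[-1] + 1e-9))
    ks = np.arange(1, n_beats + 1, dtype=float)
    idx = np.minimum(np.searchsorted(integral, ks, side="left"), n_steps)
    # crossing of k lies between edges idx-1 and idx; linear interpolation
    beat_times = (idx - 1) * dt + (ks - integral[idx - 1]) / rate[idx - 1]
    beat_times = np.minimum(beat_times, config.duration_s)
    rr = np.diff(np.concatenate([[0.0], beat_times]))

    dropout = _dropout_intervals(config, rng)
    n_samples = int(round(config.duration_s * DEVICE_FS_HZ))
    sample_t = np.arange(n_samples) / DEVICE_FS_HZ
    coverage = np.ones(n_samples, dtype=bool)
    for start, end in dropout:
        coverage[(sample_t >= start) & (sample_t < end)] = False

    return GroundTruth(
        config=config,
        beat_times=beat_times,
        rr=rr,
        dropout_intervals=dropout,
        coverage_mask=coverage,
    )


def render_bvp(truth: GroundTruth, config: SyntheticConfig | None = None) -> BvpRecording:
    """Render the 64 Hz BVP waveform for a generated session.

    A pulse template is placed at every beat time whose center falls
    outside the dropout blocks; dropout blocks are filled with broadband
    noise of comparable amplitude so that no beat structure survives.
    """
    if config is None:
        config = truth.config
    # independent stream so waveform noise never perturbs beat times
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5E55]))
    fs = DEVICE_FS_HZ
    n = int(round(config.duration_s * fs))
    samples = rng.normal(0.0, config.baseline_noise_sd, size=n)

    shape = config.pulse_shape
    half = int(math.ceil(shape.half_width_s * fs))
    renderable = ~truth.in_dropout(truth.beat_times)
    for bt in truth.beat_times[renderable]:
        center = int(round(bt * fs))
        lo = max(0, center - half)
        hi = min(n, center + half + 1)
        if lo >= hi:
            continue
        window_t = np.arange(lo, hi) / fs - bt
        samples[lo:hi] += shape.evaluate(window_t)

    for start, end in truth.dropout_intervals:
        lo = int(round(start * fs))
        hi = min(n, int(round(end * fs)))
        samples[lo:hi] = rng.normal(0.0, config.dropout_noise_sd, size=hi - lo)

    return BvpRecording(config.start_time, fs, samples)


def generate_session(config: SyntheticConfig) -> tuple[GroundTruth, BvpRecording]:
    """Convenience: ground truth plus rendered waveform for one config."""
    truth = generate_rr_series(config)
    return truth, render_bvp(truth, config)


@dataclass(frozen=True)
class SessionPair:
    """Matched Q1/Q4 generating configurations for one participant."""

    participant_id: str
    role: str                   # "resident" | "attending"
    pgy_level: int | None
    q1: SyntheticConfig
    q4: SyntheticConfig


def make_cohort(
    n_participants: int,
    effect: dict[str, float] | None = None,
    seed: int = 0,
    base: SyntheticConfig | None = None,
    between_sd: dict[str, float] | None = None,
) -> list[SessionPair]:
    """Simulate a paired Q1/Q4 cohort of session configurations.

    Each participant draws individual physiology (mean RR, modulation
    amplitudes) around ``base``; the Q4 configuration adds the per-field
    shifts in ``effect`` (e.g. ``{"mean_rr_s": 0.05}``) to that
    participant's Q1 parameters, so a zero effect gives identical
    generating parameters across quarters.  Between-participant spread
    uses a *shared* modulation-power scale plus a small independent
    sympathovagal-balance jitter: cohorts of this kind show large
    between-person LF/HF power spread but an almost constant LF:HF
    ratio, so per-person LF and HF amplitudes are nearly proportional.
    Roughly half the cohort is labelled resident (with a PGY level),
    the rest attending, matching the source cohort's 10/21 resident
    share.
    """
    if n_participants < 2:
        raise ValueError("a paired cohort needs at least 2 participants")
    effect = dict(effect or {})
    base = base or SyntheticConfig()
    between = {"mean_rr_s": 0.05, "power_scale_sd": 0.2, "balance_sd": 0.05}
    between.update(between_sd or {})

    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    session_seeds = root.generate_state(2 * n_participants + 1)[1:] % (2**31 - 1)

    n_residents = int(round(n_participants * 10.0 / 21.0))
    pairs: list[SessionPair] = []
    for i in range(n_participants):
        mean_rr = float(np.clip(rng.normal(base.mean_rr_s, between["mean_rr_s"]), 0.55, 1.4))
        # location -sigma^2 makes the *squared* scale unit-mean, so the
        # cohort-expected band powers equal the base configuration's
        sp, sb = between["power_scale_sd"], between["balance_sd"]
        power = float(np.exp(rng.normal(-sp**2, sp)))
        lf_scale = power * float(np.exp(rng.normal(-sb**2, sb)))
        hf_scale = power * float(np.exp(rng.normal(-sb**2, sb)))
        q1_fields = {
            "mean_rr_s": mean_rr,
            "lf_mod": (base.lf_mod[0], base.lf_mod[1] * lf_scale),
            "hf_mod": (base.hf_mod[0], base.hf_mod[1] * hf_scale),
        }
        q4_fields = dict(q1_fields)
        for key, shift in effect.items():
            if key == "mean_rr_s":
                q4_fields["mean_rr_s"] = q1_fields["mean_rr_s"] + shift
            elif key == "lf_amp":
                f, a = q4_fields["lf_mod"]
                q4_fields["lf_mod"] = (f, max(0.0, a + shift))
            elif key == "hf_amp":
                f, a = q4_fields["hf_mod"]
                q4_fields["hf_mod"] = (f, max(0.0, a + shift))
            else:
                raise ValueError(f"unknown effect field {key!r}")
        q1 = replace(base, seed=int(session_seeds[2 * i]), **q1_fields)
        q4 = replace(base, seed=int(session_seeds[2 * i + 1]), **q4_fields)
        resident = i < n_residents
        pairs.append(
            SessionPair(
                participant_id=f"P{i:02d}",
                role="resident" if resident else "attending",
                pgy_level=(i % 3) + 1 if resident else None,
                q1=q1,
                q4=q4,
            )
        )
    return pairs
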