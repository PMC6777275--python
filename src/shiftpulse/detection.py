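"""Pulse-beat detection from the raw BVP waveform.

The wrist device's onboard beat detector is proprietary; this module is
an open stand-in with the same contract: it emits an IBI log only for
stretches of signal that look like pulse, and rejects windows dominated
by artifact or noise so that corrupted segments contribute no beats.

Pipeline:

1. zero-phase Butterworth band-pass (0.5-8 Hz) of the 64 Hz waveform;
2. a sliding signal-quality gate: in each window the fraction of
   (filter-response-whitened) band-passed power falling in the cardiac
   range (0.7-3.5 Hz, fundamental pulse rates 42-210 bpm) must exceed
   ``snr_threshold``.  A pulse train concentrates its power there;
   broadband artifact spreads it across the whole pass-band, scoring
   near the bandwidth ratio (~0.37).  Windows overlap (hop
   ``snr_hop_s``) and a sample is accepted only when *every* window
   covering it passes, so acceptance cannot leak more than one hop into
   an artifact block longer than the window;
3. local-maximum picking with a refractory period, an amplitude floor
   from the accepted-signal envelope, and parabolic sub-sample
   refinement;
4. interval assembly: an interval is logged only when its whole span
   lies in accepted samples and its length is physiological
   ([``min_ibi_s``, ``max_ibi_s``]).  No interval may span a gate
   boundary, so beats bordering a rejected stretch are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .session_io import BvpRecording, IbiLog

__all__ = ["DetectorConfig", "detect_beats"]


@dataclass(frozen=True)
class DetectorConfig:
    bandpass_low_hz: float = 0.5
    bandpass_high_hz: float = 8.0
    refractory_s: float = 0.25
    snr_window_s: float = 10.0
    snr_hop_s: float = 2.5
    #: minimum cardiac-band fraction of whitened pass-band power;
    #: broadband noise scores ~0.37, clean pulse >0.8
    snr_threshold: float = 0.60
    cardiac_band_hz: tuple[float, float] = (0.7, 3.5)
    min_ibi_s: float = 0.25
    max_ibi_s: float = 3.0

    def __post_init__(self) -> None:
        if not (0 < self.bandpass_low_hz < self.bandpass_high_hz):
            raise ValueError("need 0 < bandpass_low < bandpass_high")
        if not (0 < self.min_ibi_s < self.max_ibi_s):
            raise ValueError("need 0 < min_ibi_s < max_ibi_s")
        if not (0.0 < self.snr_threshold < 1.0):
            raise ValueError("snr_threshold must lie in (0, 1)")
        if not (0 < self.snr_hop_s <= self.snr_window_s):
            raise ValueError("need 0 < snr_hop_s <= snr_window_s")


def _accepted_samples(
    filtered: np.ndarray, fs: float, sos: np.ndarray, cfg: DetectorConfig
) -> np.ndarray:
    """Boolean per-sample acceptance from the sliding quality gate."""
    n = filtered.size
    w = int(round(cfg.snr_window_s * fs))
    hop = max(1, int(round(cfg.snr_hop_s * fs)))
    if w > n:
        return np.zeros(n, dtype=bool)
    starts = np.arange(0, n - w + 1, hop)

    windows = np.lib.stride_tricks.sliding_window_view(filtered, w)[starts]
    windows = windows - windows.mean(axis=1, keepdims=True)
    spec = np.abs(np.fft.rfft(windows, axis=1)) ** 2

    freqs = np.fft.rfftfreq(w, d=1.0 / fs)
    # undo the band-pass shaping so broadband noise scores the flat
    # bandwidth ratio; clamp the response to keep edge bins bounded
    _, resp = signal.sosfreqz(sos, worN=freqs, fs=fs)
    gain = np.maximum(np.abs(resp) ** 2, 0.25)
    spec = spec / gain

    passband = (freqs >= cfg.bandpass_low_hz) & (freqs <= cfg.bandpass_high_hz)
    cardiac = (freqs >= cfg.cardiac_band_hz[0]) & (freqs <= cfg.cardiac_band_hz[1])
    total = spec[:, passband].sum(axis=1)
    inband = spec[:, cardiac].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        quality = np.where(total > 0, inband / np.maximum(total, 1e-300), 0.0)

    accepted = np.zeros(n, dtype=bool)
    last_end = int(starts[-1]) + w
    accepted[:last_end] = True
    accepted[last_end:] = False        # tail not covered by any full window
    for i in np.flatnonzero(quality < cfg.snr_threshold):
        s = int(starts[i])
        accepted[s : s + w] = False
    return accepted


def detect_beats(bvp: BvpRecording, cfg: DetectorConfig = DetectorConfig()) -> IbiLog:
    """Detect pulse beats and assemble an IBI log.

    Raises ``ValueError`` when the recording is shorter than twice the
    maximum physiological interval (nothing could be logged anyway).
    """
    fs = bvp.sampling_rate_hz
    if bvp.duration_s <= 2.0 * cfg.max_ibi_s:
        raise ValueError(
            f"recording of {bvp.duration_s:.2f} s is too short to detect intervals "
            f"(need more than {2 * cfg.max_ibi_s:.2f} s)"
        )

    nyq = fs / 2.0
    high = min(cfg.bandpass_high_hz, 0.95 * nyq)
    sos = signal.butter(3, [cfg.bandpass_low_hz, high], btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, bvp.samples)

    accepted = _accepted_samples(filtered, fs, sos, cfg)
    if not accepted.any():
        return IbiLog(bvp.start_time, np.empty(0), np.empty(0))

    # amplitude floor from the accepted signal's upper envelope
    scale = float(np.percentile(np.abs(filtered[accepted]), 95))
    if scale <= 0:
        return IbiLog(bvp.start_time, np.empty(0), np.empty(0))
    peaks, _ = signal.find_peaks(
        filtered,
        distance=max(1, int(round(cfg.refractory_s * fs))),
        height=0.4 * scale,
        prominence=0.4 * scale,
    )
    peaks = peaks[accepted[peaks]]
    if peaks.size < 2:
        return IbiLog(bvp.start_time, np.empty(0), np.empty(0))

    # parabolic sub-sample refinement removes the grid-quantization error
    times = peaks.astype(float)
    interior = (peaks > 0) & (peaks < filtered.size - 1)
    ym = filtered[peaks[interior] - 1]
    y0 = filtered[peaks[interior]]
    yp = filtered[peaks[interior] + 1]
    denom = ym - 2.0 * y0 + yp
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (ym - yp) / denom, 0.0)
    times[interior] += np.clip(shift, -0.5, 0.5)
    times /= fs

    # an interval is valid only if no rejected sample lies inside it
    n_rejected_before = np.cumsum(~accepted)
    offsets, ibis = [], []
    for j in range(1, peaks.size):
        a, b = peaks[j - 1], peaks[j]
        if n_rejected_before[b] - n_rejected_before[a] > 0:
            continue
        interval = times[j] - times[j - 1]
        if cfg.min_ibi_s <= interval <= cfg.max_ibi_s:
            offsets.append(times[j])
            ibis.append(interval)

    return IbiLog(bvp.start_time, np.asarray(offsets), np.asarray(ibis))
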