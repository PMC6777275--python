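"""Time-domain pulse-rate-variability metrics from an IBI log.

Four headline variables:

* **MPR** — median pulse rate, the median of the instantaneous rates
  ``60/ibi`` in beats per minute;
* **MRRI** — mean interbeat (R-R) interval in seconds;
* **SDNN** — sample standard deviation of the interval series;
* **RMSSD** — root mean square of successive interval differences,
  computed on the **single longest contiguous run** of beats only,
  because successive differences are meaningless across detection gaps.

MPR, MRRI and SDNN use every logged interval; only RMSSD is restricted
to the longest run.  Two consecutive entries are contiguous when the
offset step matches the logged interval to within ``contiguity_tol``
(default one sample period at 64 Hz, the device's beat-time
quantization).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session_io import DEVICE_FS_HZ, IbiLog

__all__ = [
    "BeatRun",
    "TimeDomainMetrics",
    "DEFAULT_CONTIGUITY_TOL_S",
    "median_pulse_rate",
    "mean_rr",
    "sdnn",
    "longest_contiguous_run",
    "rmssd",
    "time_domain_metrics",
]

#: One sample period of the 64 Hz device: beat offsets are quantized at
#: this resolution, so steps within one tick of the logged interval are
#: treated as contiguous.
DEFAULT_CONTIGUITY_TOL_S = 1.0 / DEVICE_FS_HZ


@dataclass(frozen=True)
class BeatRun:
    """A maximal stretch of mutually contiguous beats in an IBI log."""

    start_index: int
    end_index: int              # inclusive
    offsets: np.ndarray         # beat times within the run (s)
    rr: np.ndarray              # intervals within the run (s)

    @property
    def n_beats(self) -> int:
        return int(self.rr.size)

    @property
    def duration_s(self) -> float:
        return float(self.offsets[-1] - (self.offsets[0] - self.rr[0]))


@dataclass(frozen=True)
class TimeDomainMetrics:
    mpr_bpm: float
    mrri_s: float
    sdnn_s: float
    rmssd_s: float
    n_beats_used: int
    longest_run_beats: int


def median_pulse_rate(ibi: IbiLog) -> float:
    """Median of instantaneous pulse rates 60/ibi, in beats per minute.

    An even-count series returns the mean of the two middle rates.
    """
    if ibi.beat_count < 1:
        raise ValueError("median_pulse_rate requires at least one beat")
    return float(np.median(60.0 / ibi.ibis))


def mean_rr(ibi: IbiLog) -> float:
    """Arithmetic mean of all interbeat intervals, in seconds."""
    if ibi.beat_count < 1:
        raise ValueError("mean_rr requires at least one beat")
    return float(np.mean(ibi.ibis))


def sdnn(ibi: IbiLog) -> float:
    """Sample standard deviation (n-1 denominator) of the intervals."""
    if ibi.beat_count < 2:
        raise ValueError("sdnn requires at least two beats")
    return float(np.std(ibi.ibis, ddof=1))


def _run_boundaries(ibi: IbiLog, contiguity_tol: float) -> np.ndarray:
    """Indices i where entry i is NOT contiguous with entry i-1."""
    gaps = np.abs(np.diff(ibi.offsets) - ibi.ibis[1:])
    # tiny relative slack so that an offset sum computed in floating point
    # does not break an exactly-one-tick tolerance
    return np.flatnonzero(gaps > contiguity_tol * (1.0 + 1e-9)) + 1


def longest_contiguous_run(
    ibi: IbiLog, contiguity_tol: float = DEFAULT_CONTIGUITY_TOL_S
) -> BeatRun:
    """The longest stretch of consecutive beats (ties -> earliest).

    Entries i-1, i belong to the same run when
    ``|offset_i - offset_{i-1} - ibi_i| <= contiguity_tol``.
    """
    if ibi.beat_count < 2:
        raise ValueError("longest_contiguous_run requires at least two beats")
    breaks = _run_boundaries(ibi, contiguity_tol)
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [ibi.beat_count]])  # exclusive
    lengths = ends - starts
    best = int(np.argmax(lengths))  # argmax takes the first maximum: earliest run
    if lengths[best] < 2:
        raise ValueError("no contiguous run of at least 2 beats")
    s, e = int(starts[best]), int(ends[best]) - 1
    return BeatRun(
        start_index=s,
        end_index=e,
        offsets=ibi.offsets[s : e + 1].copy(),
        rr=ibi.ibis[s : e + 1].copy(),
    )


def rmssd(run: BeatRun) -> float:
    """Root mean square of successive RR differences over one run."""
    if run.n_beats < 2:
        raise ValueError("rmssd requires a run of at least 2 intervals")
    diffs = np.diff(run.rr)
    return float(np.sqrt(np.mean(diffs**2)))


def time_domain_metrics(
    ibi: IbiLog, contiguity_tol: float = DEFAULT_CONTIGUITY_TOL_S
) -> TimeDomainMetrics:
    """All four time-domain variables for one session."""
    run = longest_contiguous_run(ibi, contiguity_tol)
    return TimeDomainMetrics(
        mpr_bpm=median_pulse_rate(ibi),
        mrri_s=mean_rr(ibi),
        sdnn_s=sdnn(ibi),
        rmssd_s=rmssd(run),
        n_beats_used=ibi.beat_count,
        longest_run_beats=run.n_beats,
    )
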