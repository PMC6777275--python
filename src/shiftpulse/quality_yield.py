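"""Interpretable-data yield: how much recording time carried beats.

The study's data-quality statistic is a time quotient: the IBI log is
rasterized onto the recording's own 64 Hz sample grid, a sample counts
as *covered* when it falls inside a detected beat-to-beat interval
(including the interval between consecutive beats), and the yield is

    quotient_pct = 100 * covered samples / total samples.

Aggregation across sessions pools seconds (sum of covered over sum of
total), not per-session percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .session_io import DEVICE_FS_HZ, IbiLog

__all__ = [
    "YieldReport",
    "coverage_vector",
    "coverage_vector_1s_bins",
    "yield_quotient",
    "session_yield",
    "aggregate_yield",
]


@dataclass(frozen=True)
class YieldReport:
    covered_s: float
    total_s: float
    quotient_pct: float
    n_sessions: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.covered_s <= self.total_s + 1e-9):
            raise ValueError("covered time must lie in [0, total]")


def coverage_vector(
    ibi: IbiLog, total_duration_s: float, fs: float = DEVICE_FS_HZ
) -> np.ndarray:
    """Per-sample beat-coverage flags for one session.

    Sample ``k`` (at time ``k/fs`` from session start) is covered when it
    lies inside some logged interval ``[offset - ibi, offset]`` (closed:
    shared endpoints of consecutive beats are simply marked once).
    """
    if ibi.beat_count and float(ibi.offsets[-1]) > total_duration_s + 1e-9:
        raise ValueError(
            f"beat offset {ibi.offsets[-1]:.3f} s exceeds recording "
            f"duration {total_duration_s:.3f} s"
        )
    n = int(round(total_duration_s * fs))
    covered = np.zeros(n, dtype=bool)
    eps = 1e-9
    for offset, interval in zip(ibi.offsets, ibi.ibis):
        start, end = offset - interval, offset
        lo = max(0, int(np.ceil(start * fs - eps)))
        hi = min(n - 1, int(np.floor(end * fs + eps)))
        if hi >= lo:
            covered[lo : hi + 1] = True
    return covered


def coverage_vector_1s_bins(
    ibi: IbiLog, total_duration_s: float, fs: float = DEVICE_FS_HZ
) -> np.ndarray:
    """Sensitivity-analysis variant: 1-second bins anchored at t=0.

    A bin is covered when any covered sample falls inside it.  This is
    the literal 1-second-segment reading of the time-vector
    construction; the per-sample vector is the primary definition.
    """
    samples = coverage_vector(ibi, total_duration_s, fs)
    n_bins = int(np.ceil(total_duration_s))
    bins = np.zeros(n_bins, dtype=bool)
    idx = (np.arange(samples.size) / fs).astype(int)
    np.logical_or.at(bins, idx[samples], True)
    return bins


def yield_quotient(covered: np.ndarray) -> float:
    """Percent of samples flagged covered."""
    covered = np.asarray(covered, dtype=bool)
    if covered.size == 0:
        raise ValueError("empty coverage vector")
    return 100.0 * float(np.count_nonzero(covered)) / covered.size


def session_yield(
    ibi: IbiLog, total_duration_s: float, fs: float = DEVICE_FS_HZ
) -> YieldReport:
    """Yield report for one session."""
    covered = coverage_vector(ibi, total_duration_s, fs)
    n_true = int(np.count_nonzero(covered))
    return YieldReport(
        covered_s=n_true / fs,
        total_s=covered.size / fs,
        quotient_pct=yield_quotient(covered) if covered.size else 0.0,
    )


def aggregate_yield(reports: Sequence[YieldReport]) -> YieldReport:
    """Pool sessions by time: quotient = 100 * sum(covered) / sum(total)."""
    if not reports:
        raise ValueError("aggregate_yield needs at least one report")
    covered = sum(r.covered_s for r in reports)
    total = sum(r.total_s for r in reports)
    return YieldReport(
        covered_s=covered,
        total_s=total,
        quotient_pct=100.0 * covered / total if total else 0.0,
        n_sessions=sum(r.n_sessions for r in reports),
    )
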