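"""Inclusion screening and paired-cohort selection.

Three checks decide whether a recorded session enters the analysis:

1. **shift overlap** — the recording interval must overlap the
   scheduled shift window (so the data reflect on-duty physiology);
2. **beat density** — the IBI log must register at least 300 beats
   (inclusive at exactly 300), ensuring enough clean signal;
3. **manual review** — a human looks at the waveform with the logged
   beats superimposed and may veto the session; the verdict enters as a
   per-session flag, the plot data are exported here.

The repeated-measures design then keeps only participants with one
included session in *both* Q1 and Q4; when a quarter has several, the
earliest-dated one is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .session_io import BvpRecording, IbiLog, SessionMeta, ShiftWindow

__all__ = [
    "DEFAULT_MIN_BEATS",
    "ScreeningResult",
    "CohortSelection",
    "OverlayData",
    "check_shift_overlap",
    "check_beat_density",
    "overlay_plot_data",
    "screen_session",
    "select_cohort",
]

#: Minimum registered beats for inclusion (boundary inclusive).
DEFAULT_MIN_BEATS = 300


@dataclass(frozen=True)
class ScreeningResult:
    """Outcome of the three inclusion checks for one session."""

    session_id: str
    meta: SessionMeta
    overlap_ok: bool
    overlap_s: float
    beat_count: int
    density_ok: bool
    manually_excluded: bool

    @property
    def included(self) -> bool:
        return self.overlap_ok and self.density_ok and not self.manually_excluded

    @property
    def exclusion_reasons(self) -> tuple[str, ...]:
        reasons = []
        if not self.overlap_ok:
            reasons.append("no shift overlap")
        if not self.density_ok:
            reasons.append("fewer than minimum beats")
        if self.manually_excluded:
            reasons.append("manual exclusion")
        return tuple(reasons)


@dataclass(frozen=True)
class CohortSelection:
    """Chosen Q1/Q4 session per retained participant, plus the attrition log."""

    #: participant_id -> {"Q1": session_id, "Q4": session_id}
    selected: dict[str, dict[str, str]]
    #: (participant_id or session_id, reason) in screening order
    exclusion_log: tuple[tuple[str, str], ...]

    @property
    def participant_ids(self) -> list[str]:
        return sorted(self.selected)

    @property
    def n_participants(self) -> int:
        return len(self.selected)


def check_shift_overlap(
    bvp: BvpRecording,
    shift: ShiftWindow,
    min_overlap_s: float = 0.0,
    utc_offset_hours: float = 0.0,
) -> tuple[bool, float]:
    """Overlap (seconds) between the recording and the scheduled shift.

    ``overlap_ok`` requires strictly positive overlap by default; a
    stricter absolute minimum can be configured.
    """
    shift_start, shift_end = shift.to_epoch(utc_offset_hours)
    lo = max(bvp.start_time, shift_start)
    hi = min(bvp.end_time, shift_end)
    overlap = max(0.0, hi - lo)
    ok = overlap >= min_overlap_s if min_overlap_s > 0 else overlap > 0
    return ok, overlap


def check_beat_density(
    ibi: IbiLog, threshold: int = DEFAULT_MIN_BEATS
) -> tuple[bool, int]:
    """At least ``threshold`` registered beats (inclusive)."""
    return ibi.beat_count >= threshold, ibi.beat_count


@dataclass(frozen=True)
class OverlayData:
    """Waveform plus beat markers on a shared session-time axis,
    ready for the visual-review plot."""

    times_s: np.ndarray
    amplitudes: np.ndarray
    marker_times_s: np.ndarray


def overlay_plot_data(
    bvp: BvpRecording, ibi: IbiLog, start_tolerance_s: float = 1.0
) -> OverlayData:
    """Data behind the review plot: BVP trace with logged beats marked.

    Both inputs must come from the same session (start times within
    ``start_tolerance_s``); markers outside the recording are an error.
    """
    if abs(bvp.start_time - ibi.session_start) > start_tolerance_s:
        raise ValueError(
            f"session mismatch: BVP starts at {bvp.start_time}, "
            f"IBI log at {ibi.session_start}"
        )
    if ibi.beat_count and float(ibi.offsets[-1]) > bvp.duration_s + 1e-9:
        raise ValueError("beat markers extend past the end of the recording")
    return OverlayData(
        times_s=bvp.sample_times(),
        amplitudes=bvp.samples.copy(),
        marker_times_s=ibi.offsets.copy(),
    )


def screen_session(
    session_id: str,
    bvp: BvpRecording,
    ibi: IbiLog,
    meta: SessionMeta,
    min_beats: int = DEFAULT_MIN_BEATS,
    min_overlap_s: float = 0.0,
    utc_offset_hours: float = 0.0,
) -> ScreeningResult:
    """Run all three inclusion checks on one session."""
    overlap_ok, overlap_s = check_shift_overlap(
        bvp, meta.shift_window, min_overlap_s, utc_offset_hours
    )
    density_ok, beat_count = check_beat_density(ibi, min_beats)
    return ScreeningResult(
        session_id=session_id,
        meta=meta,
        overlap_ok=overlap_ok,
        overlap_s=overlap_s,
        beat_count=beat_count,
        density_ok=density_ok,
        manually_excluded=meta.manually_excluded,
    )


def select_cohort(results: list[ScreeningResult]) -> CohortSelection:
    """Keep participants with an included session in both quarters.

    Multiple included sessions in one quarter are resolved to the
    earliest shift date.  The exclusion log records one line per
    excluded session (its violated rules) and one per dropped
    participant (the missing quarter).
    """
    ids = [r.session_id for r in results]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate session ids in screening results")

    log: list[tuple[str, str]] = []
    by_participant: dict[str, dict[str, list[ScreeningResult]]] = {}
    for r in results:
        if not r.included:
            log.append((r.session_id, "; ".join(r.exclusion_reasons)))
            continue
        by_participant.setdefault(r.meta.participant_id, {}).setdefault(
            r.meta.quarter, []
        ).append(r)

    selected: dict[str, dict[str, str]] = {}
    for pid in sorted(by_participant):
        quarters = by_participant[pid]
        missing = [q for q in ("Q1", "Q4") if q not in quarters]
        if missing:
            log.append((pid, f"no included {' or '.join(missing)} session"))
            continue
        choice = {}
        for q in ("Q1", "Q4"):
            best = min(quarters[q], key=lambda r: (r.meta.shift_window.start, r.session_id))
            choice[q] = best.session_id
        selected[pid] = choice
    return CohortSelection(selected=selected, exclusion_log=tuple(log))
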