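"""End-to-end run orchestration: simulate -> detect -> screen -> metrics
-> yield -> compare.

Every stage persists plain CSV/JSON intermediates so the attrition and
every table number are auditable, and every stage is a pure function of
(inputs, config, seed): the same run configuration reproduces the same
bytes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort_stats import (
    METRICS,
    ParticipantMetrics,
    UNCORRECTED_TESTS_NOTE,
    comparisons_to_frame,
    summarize_cohort,
)
from .detection import DetectorConfig, detect_beats
from .freq_domain import SpectralConfig, freq_domain_metrics
from .quality_yield import aggregate_yield, session_yield
from .screening import DEFAULT_MIN_BEATS, screen_session, select_cohort
from .session_io import (
    IbiLog,
    SessionMeta,
    ShiftWindow,
    read_bvp,
    read_ibi,
    read_meta,
    write_bvp,
    write_ibi,
    write_meta,
)
from .synthetic import SessionPair, SyntheticConfig, generate_session, make_cohort
from .time_domain import DEFAULT_CONTIGUITY_TOL_S, time_domain_metrics

__all__ = ["RunConfig", "run_pipeline", "session_metric_dict", "simulate_cohort_metrics"]

logger = logging.getLogger(__name__)


def session_metric_dict(
    ibi: IbiLog,
    spectral: SpectralConfig = SpectralConfig(),
    contiguity_tol: float = DEFAULT_CONTIGUITY_TOL_S,
) -> dict[str, float]:
    """The seven headline metrics for one session, keyed as in the tables."""
    td = time_domain_metrics(ibi, contiguity_tol)
    fd = freq_domain_metrics(ibi, spectral, contiguity_tol)
    return {
        "MPR": td.mpr_bpm,
        "MRRI": td.mrri_s,
        "SDNN": td.sdnn_s,
        "RMSSD": td.rmssd_s,
        "LF": fd.lf_power_ms2,
        "HF": fd.hf_power_ms2,
        "LHR": fd.lhr,
    }


def simulate_cohort_metrics(
    pairs: list[SessionPair],
    spectral: SpectralConfig = SpectralConfig(),
) -> list[ParticipantMetrics]:
    """Metric sets for a simulated cohort via the ideal-detector path.

    Generates each session's beat process and evaluates the metrics on
    its exact IBI log, skipping waveform rendering and detection — the
    fast path used for statistical-calibration experiments.
    """
    from .synthetic import generate_rr_series

    out = []
    for pair in pairs:
        values = {}
        for quarter, cfg in (("q1", pair.q1), ("q4", pair.q4)):
            truth = generate_rr_series(cfg)
            values[quarter] = session_metric_dict(truth.clean_ibi_log(), spectral)
        out.append(
            ParticipantMetrics(
                participant_id=pair.participant_id,
                role=pair.role,
                q1=values["q1"],
                q4=values["q4"],
            )
        )
    return out


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full simulated-study run."""

    out_dir: str
    n_participants: int = 6
    session: SyntheticConfig = field(default_factory=SyntheticConfig)
    effect: dict[str, float] = field(default_factory=dict)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    min_beats: int = DEFAULT_MIN_BEATS
    min_overlap_s: float = 0.0
    contiguity_tol_s: float = DEFAULT_CONTIGUITY_TOL_S
    subgroup: str = "all"
    utc_offset_hours: float = 0.0
    seed: int = 0

    def to_dict(self) -> dict:
        def _clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: _clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            return obj

        return _clean(self)


def _shift_window(quarter: str, participant_index: int) -> ShiftWindow:
    # Q1 shifts in August, Q4 the following May; one calendar day per
    # participant keeps shift dates distinct and inside the quarter months
    day = 1 + participant_index % 28
    if quarter == "Q1":
        return ShiftWindow.default(2016, 8, day)
    return ShiftWindow.default(2017, 5, day)


def run_pipeline(config: RunConfig) -> Path:
    """Simulate a paired cohort and run every analysis stage on it.

    Returns the run directory, which contains ``sessions/`` (BVP, IBI
    and metadata files), ``screening.csv``, ``cohort.json``,
    ``metrics/*.json``, ``yield.csv``, ``tables.csv`` and a
    ``manifest.json`` recording config hash, seed and version.
    """
    out = Path(config.out_dir)
    sessions_dir = out / "sessions"
    metrics_dir = out / "metrics"
    sessions_dir.mkdir(parents=True, exist_ok=True)
    metrics_dir.mkdir(parents=True, exist_ok=True)

    timings: dict[str, float] = {}

    # -- simulate ----------------------------------------------------------
    t0 = time.perf_counter()
    pairs = make_cohort(
        config.n_participants, config.effect, seed=config.seed, base=config.session
    )
    session_files: list[tuple[str, Path, Path, Path]] = []
    for i, pair in enumerate(pairs):
        for quarter, syn in (("Q1", pair.q1), ("Q4", pair.q4)):
            window = _shift_window(quarter, i)
            start_epoch, _ = window.to_epoch(config.utc_offset_hours)
            syn = replace(syn, start_time=start_epoch)
            truth, bvp = generate_session(syn)
            sid = f"{pair.participant_id}_{quarter}"
            meta = SessionMeta(
                participant_id=pair.participant_id,
                role=pair.role,
                quarter=quarter,
                shift_window=window,
                pgy_level=pair.pgy_level,
            )
            bvp_path = sessions_dir / f"{sid}_bvp.csv"
            ibi_path = sessions_dir / f"{sid}_ibi.csv"
            meta_path = sessions_dir / f"{sid}_meta.json"
            write_bvp(bvp, bvp_path)
            write_meta(meta, meta_path)
            session_files.append((sid, bvp_path, ibi_path, meta_path))
    timings["simulate"] = time.perf_counter() - t0
    logger.info("simulate: %d sessions in %.1f s", len(session_files), timings["simulate"])

    # -- detect ------------------------------------------------------------
    t0 = time.perf_counter()
    for sid, bvp_path, ibi_path, _ in session_files:
        bvp = read_bvp(bvp_path)
        ibi = detect_beats(bvp, config.detector)
        write_ibi(ibi, ibi_path)
    timings["detect"] = time.perf_counter() - t0
    logger.info("detect: %.1f s", timings["detect"])

    # -- screen ------------------------------------------------------------
    t0 = time.perf_counter()
    results = []
    loaded: dict[str, tuple] = {}
    for sid, bvp_path, ibi_path, meta_path in session_files:
        bvp = read_bvp(bvp_path)
        ibi = read_ibi(ibi_path)
        meta = read_meta(meta_path)
        loaded[sid] = (bvp, ibi, meta)
        results.append(
            screen_session(
                sid,
                bvp,
                ibi,
                meta,
                min_beats=config.min_beats,
                min_overlap_s=config.min_overlap_s,
                utc_offset_hours=config.utc_offset_hours,
            )
        )
    selection = select_cohort(results)
    pd.DataFrame(
        {
            "session_id": [r.session_id for r in results],
            "participant_id": [r.meta.participant_id for r in results],
            "quarter": [r.meta.quarter for r in results],
            "role": [r.meta.role for r in results],
            "overlap_s": [r.overlap_s for r in results],
            "beat_count": [r.beat_count for r in results],
            "overlap_ok": [r.overlap_ok for r in results],
            "density_ok": [r.density_ok for r in results],
            "manually_excluded": [r.manually_excluded for r in results],
            "included": [r.included for r in results],
        }
    ).to_csv(out / "screening.csv", index=False)
    (out / "cohort.json").write_text(
        json.dumps(
            {
                "selected": selection.selected,
                "exclusion_log": [list(e) for e in selection.exclusion_log],
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    timings["screen"] = time.perf_counter() - t0

    # -- metrics -----------------------------------------------------------
    t0 = time.perf_counter()
    cohort_metrics: list[ParticipantMetrics] = []
    role_by_pid = {r.meta.participant_id: r.meta.role for r in results}
    for pid in selection.participant_ids:
        per_quarter = {}
        for quarter in ("Q1", "Q4"):
            sid = selection.selected[pid][quarter]
            _, ibi, _ = loaded[sid]
            values = session_metric_dict(ibi, config.spectral, config.contiguity_tol_s)
            per_quarter[quarter] = values
            (metrics_dir / f"{sid}.json").write_text(
                json.dumps({"session_id": sid, **values}, indent=2, sort_keys=True) + "\n"
            )
        cohort_metrics.append(
            ParticipantMetrics(
                participant_id=pid,
                role=role_by_pid[pid],
                q1=per_quarter["Q1"],
                q4=per_quarter["Q4"],
            )
        )
    timings["metrics"] = time.perf_counter() - t0

    # -- yield -------------------------------------------------------------
    t0 = time.perf_counter()
    reports = []
    rows = []
    for sid, (bvp, ibi, _) in loaded.items():
        rep = session_yield(ibi, bvp.duration_s, bvp.sampling_rate_hz)
        reports.append(rep)
        rows.append((sid, rep.covered_s, rep.total_s, rep.quotient_pct))
    pooled = aggregate_yield(reports)
    rows.append(("POOLED", pooled.covered_s, pooled.total_s, pooled.quotient_pct))
    pd.DataFrame(
        rows, columns=["session_id", "covered_s", "total_s", "quotient_pct"]
    ).to_csv(out / "yield.csv", index=False)
    timings["yield"] = time.perf_counter() - t0

    # -- compare -----------------------------------------------------------
    t0 = time.perf_counter()
    comparisons = summarize_cohort(cohort_metrics, subgroup=config.subgroup)
    frame = comparisons_to_frame(comparisons)
    with (out / "tables.csv").open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# {UNCORRECTED_TESTS_NOTE}\n")
        frame.to_csv(fh, index=False)
    timings["compare"] = time.perf_counter() - t0

    config_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.seed,
        "shiftpulse_version": __version__,
        "n_sessions": len(session_files),
        "n_pairs": selection.n_participants,
        "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
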