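"""Reading and writing wrist-biosensor session exports.

A session consists of two files plus a metadata sidecar:

* a blood-volume-pulse (BVP) waveform sampled at a fixed rate (64 Hz for
  the wrist device emulated here), stored one amplitude per line after a
  two-line header (session start as UTC epoch seconds, then the sampling
  rate in Hz);
* an interbeat-interval (IBI) log: one ``offset,interval`` pair per line,
  offsets in seconds relative to the epoch timestamp on the first line.
  The offset marks the beat at the *end* of the interval;
* a JSON sidecar carrying participant id, role, PGY level, academic-year
  quarter and the scheduled shift window.

All records are validated on construction; files that do not satisfy the
dialect raise :class:`SessionFormatError` with the offending line number.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BvpRecording",
    "IbiLog",
    "SessionMeta",
    "ShiftWindow",
    "SessionFormatError",
    "read_bvp",
    "write_bvp",
    "read_ibi",
    "write_ibi",
    "read_meta",
    "write_meta",
]

#: Sampling rate of the emulated wrist device (samples per second).
DEVICE_FS_HZ = 64.0

Q1_MONTHS = (7, 8, 9)       # July-September
Q4_MONTHS = (4, 5, 6)       # April-June


class SessionFormatError(ValueError):
    """A session export file violates the expected dialect."""


@dataclass(frozen=True)
class BvpRecording:
    """Raw blood-volume-pulse waveform at a fixed sampling rate.

    Parameters
    ----------
    start_time:
        Session start as UTC epoch seconds (fractional part allowed).
    sampling_rate_hz:
        Samples per second; must be positive.
    samples:
        Ordered waveform amplitudes (nanowatts for the emulated device).
    """

    start_time: float
    sampling_rate_hz: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not np.isfinite(self.start_time):
            raise ValueError("start_time must be finite")
        if not (self.sampling_rate_hz > 0):
            raise ValueError("sampling_rate_hz must be positive")
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if samples.size and not np.all(np.isfinite(samples)):
            raise ValueError("all samples must be finite")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        """Recording length in seconds (``n_samples / fs``)."""
        return self.n_samples / self.sampling_rate_hz

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration_s

    def sample_times(self) -> np.ndarray:
        """Sample offsets in seconds from session start."""
        return np.arange(self.n_samples) / self.sampling_rate_hz

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BvpRecording):
            return NotImplemented
        return (
            self.start_time == other.start_time
            and self.sampling_rate_hz == other.sampling_rate_hz
            and np.array_equal(self.samples, other.samples)
        )


@dataclass(frozen=True)
class IbiLog:
    """Interbeat-interval log relative to a session start.

    Each entry is ``(offset_s, ibi_s)``: a beat registered ``offset_s``
    seconds after session start, terminating an interval of ``ibi_s``
    seconds.  Offsets are strictly increasing, intervals positive, and
    every interval fits inside the recording (``offset_s >= ibi_s``).
    """

    session_start: float
    offsets: np.ndarray
    ibis: np.ndarray

    def __post_init__(self) -> None:
        offsets = np.asarray(self.offsets, dtype=float)
        ibis = np.asarray(self.ibis, dtype=float)
        object.__setattr__(self, "offsets", offsets)
        object.__setattr__(self, "ibis", ibis)
        if offsets.shape != ibis.shape or offsets.ndim != 1:
            raise ValueError("offsets and ibis must be 1-D arrays of equal length")
        if offsets.size:
            if not np.all(np.isfinite(offsets)) or not np.all(np.isfinite(ibis)):
                raise ValueError("offsets and intervals must be finite")
            if np.any(np.diff(offsets) <= 0):
                raise ValueError("beat offsets must be strictly increasing")
            if np.any(ibis <= 0):
                raise ValueError("all interbeat intervals must be positive")
            if np.any(offsets < ibis - 1e-9):
                raise ValueError("every interval must fit inside the session (offset >= ibi)")

    @property
    def beat_count(self) -> int:
        return int(self.offsets.size)

    @property
    def entries(self) -> list[tuple[float, float]]:
        return list(zip(self.offsets.tolist(), self.ibis.tolist()))

    @classmethod
    def from_entries(
        cls, session_start: float, entries: Iterable[tuple[float, float]]
    ) -> "IbiLog":
        pairs = list(entries)
        offsets = np.array([p[0] for p in pairs], dtype=float)
        ibis = np.array([p[1] for p in pairs], dtype=float)
        return cls(session_start, offsets, ibis)


@dataclass(frozen=True)
class ShiftWindow:
    """Scheduled clinical shift in local wall-clock time.

    The study shifts ran 14:00-23:00 (9 hours); :meth:`default` builds
    that window for a given date.
    """

    start: datetime
    end: datetime

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("shift end must be after shift start")

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()

    @classmethod
    def default(cls, year: int, month: int, day: int) -> "ShiftWindow":
        """The study's standard 9-hour shift, 14:00-23:00 local time."""
        return cls(datetime(year, month, day, 14, 0), datetime(year, month, day, 23, 0))

    def to_epoch(self, utc_offset_hours: float = 0.0) -> tuple[float, float]:
        """Convert to UTC epoch seconds given the local UTC offset."""
        from datetime import timezone

        shift = utc_offset_hours * 3600.0
        start = self.start.replace(tzinfo=timezone.utc).timestamp() - shift
        end = self.end.replace(tzinfo=timezone.utc).timestamp() - shift
        return start, end


@dataclass(frozen=True)
class SessionMeta:
    """Participant and scheduling metadata for one recorded shift."""

    participant_id: str
    role: str                       # "resident" | "attending"
    quarter: str                    # "Q1" (Jul-Sep) | "Q4" (Apr-Jun)
    shift_window: ShiftWindow
    pgy_level: int | None = None    # 1-3, residents only
    manually_excluded: bool = False

    def __post_init__(self) -> None:
        if self.role not in ("resident", "attending"):
            raise ValueError(f"role must be 'resident' or 'attending', got {self.role!r}")
        if self.quarter not in ("Q1", "Q4"):
            raise ValueError(f"quarter must be 'Q1' or 'Q4', got {self.quarter!r}")
        months = Q1_MONTHS if self.quarter == "Q1" else Q4_MONTHS
        if self.shift_window.start.month not in months:
            raise ValueError(
                f"{self.quarter} shifts must fall in months {months}, "
                f"got month {self.shift_window.start.month}"
            )
        if self.pgy_level is not None and self.pgy_level not in (1, 2, 3):
            raise ValueError("pgy_level must be 1, 2 or 3 when given")


# ---------------------------------------------------------------------------
# file I/O

_SAMPLE_FMT = "%.6f"        # vendor-style 6-decimal amplitudes
_TIME_FMT = "%.9f"          # offsets/intervals round-trip at 1 ns


def read_bvp(path: str | Path) -> BvpRecording:
    """Read a BVP waveform export.

    Line 1 is the session start (epoch seconds), line 2 the sampling rate
    in Hz, and every following line one amplitude.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if len(lines) < 2:
        raise SessionFormatError(f"{path}: missing header (need timestamp and rate lines)")
    try:
        start_time = float(lines[0].strip().split(",")[0])
    except ValueError as exc:
        raise SessionFormatError(f"{path}:1: malformed timestamp line {lines[0]!r}") from exc
    try:
        fs = float(lines[1].strip().split(",")[0])
    except ValueError as exc:
        raise SessionFormatError(f"{path}:2: malformed sampling-rate line {lines[1]!r}") from exc
    if fs <= 0:
        raise SessionFormatError(f"{path}:2: sampling rate must be positive, got {fs}")
    try:
        samples = np.asarray(lines[2:], dtype=float)
    except ValueError:
        # slow path only to name the offending line
        for i, line in enumerate(lines[2:], start=3):
            try:
                float(line)
            except ValueError as exc:
                raise SessionFormatError(f"{path}:{i}: non-numeric sample {line!r}") from exc
        raise
    return BvpRecording(start_time=start_time, sampling_rate_hz=fs, samples=samples)


def write_bvp(record: BvpRecording, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"{record.start_time!r}\n")
        fh.write(f"{record.sampling_rate_hz!r}\n")
        np.savetxt(fh, record.samples, fmt=_SAMPLE_FMT)


def read_ibi(path: str | Path) -> IbiLog:
    """Read an IBI log export (``<epoch>, IBI`` header, then offset,ibi rows)."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise SessionFormatError(f"{path}: empty file")
    header = lines[0].split(",")
    try:
        session_start = float(header[0])
    except ValueError as exc:
        raise SessionFormatError(f"{path}:1: malformed header {lines[0]!r}") from exc
    offsets, ibis = [], []
    for i, line in enumerate(lines[1:], start=2):
        parts = line.split(",")
        if len(parts) != 2:
            raise SessionFormatError(f"{path}:{i}: expected 'offset,ibi', got {line!r}")
        try:
            offsets.append(float(parts[0]))
            ibis.append(float(parts[1]))
        except ValueError as exc:
            raise SessionFormatError(f"{path}:{i}: non-numeric field in {line!r}") from exc
    try:
        return IbiLog(session_start, np.asarray(offsets), np.asarray(ibis))
    except ValueError as exc:
        raise SessionFormatError(f"{path}: {exc}") from exc


def write_ibi(log: IbiLog, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"{log.session_start!r}, IBI\n")
        for offset, ibi in zip(log.offsets, log.ibis):
            fh.write((_TIME_FMT % offset) + "," + (_TIME_FMT % ibi) + "\n")


def read_meta(path: str | Path) -> SessionMeta:
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    window = ShiftWindow(
        start=datetime.fromisoformat(raw["shift_start"]),
        end=datetime.fromisoformat(raw["shift_end"]),
    )
    return SessionMeta(
        participant_id=raw["participant_id"],
        role=raw["role"],
        quarter=raw["quarter"],
        shift_window=window,
        pgy_level=raw.get("pgy_level"),
        manually_excluded=bool(raw.get("manually_excluded", False)),
    )


def write_meta(meta: SessionMeta, path: str | Path) -> None:
    payload = {
        "participant_id": meta.participant_id,
        "role": meta.role,
        "quarter": meta.quarter,
        "pgy_level": meta.pgy_level,
        "shift_start": meta.shift_window.start.isoformat(),
        "shift_end": meta.shift_window.end.isoformat(),
        "manually_excluded": meta.manually_excluded,
    }
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
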