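"""Paired Q1-vs-Q4 comparison of the seven PRV metrics.

For each metric (MPR, MRRI, SDNN, RMSSD, LF, HF, LHR) the two quarters
are compared with a paired Student t test on the per-participant
differences d = Q4 - Q1:

    t = mean(d) / (sd(d) / sqrt(n)),   df = n - 1,

with a two-sided p value.  Post-hoc power is the noncentral-t power at
the *observed* standardized paired effect size mean(d)/sd(d):

    power = P(|T| > t_crit),  T ~ noncentral-t(df, ncp = es * sqrt(n)).

Seven uncorrected tests are run, mirroring the analysis this package
reproduces; any report built from these rows must carry a note saying
so (see ``UNCORRECTED_TESTS_NOTE``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "METRICS",
    "UNCORRECTED_TESTS_NOTE",
    "ParticipantMetrics",
    "PairedComparison",
    "paired_t",
    "posthoc_power",
    "power_from_effect",
    "summarize_cohort",
    "comparisons_to_frame",
]

#: Canonical metric order of the report tables.
METRICS = ("MPR", "MRRI", "SDNN", "RMSSD", "LF", "HF", "LHR")

UNCORRECTED_TESTS_NOTE = (
    "Note: 7 paired t tests are reported without multiple-comparison "
    "correction, matching the design being reproduced."
)


@dataclass(frozen=True)
class ParticipantMetrics:
    """Per-quarter metric dictionaries for one paired participant."""

    participant_id: str
    role: str                       # "resident" | "attending"
    q1: dict[str, float]
    q4: dict[str, float]


@dataclass(frozen=True)
class PairedComparison:
    """One row of the comparison table."""

    metric: str
    q1_mean: float
    q1_sd: float
    q4_mean: float
    q4_sd: float
    t_stat: float
    df: int
    p_two_sided: float
    power: float
    n_pairs: int


def paired_t(
    q1_values: Sequence[float], q4_values: Sequence[float]
) -> tuple[float, int, float]:
    """Paired Student t test on differences Q4 - Q1.

    Returns ``(t, df, p_two_sided)``.  Zero difference variance with a
    nonzero mean yields an infinite t and p = 0 with a warning.
    """
    q1 = np.asarray(q1_values, dtype=float)
    q4 = np.asarray(q4_values, dtype=float)
    if q1.shape != q4.shape or q1.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    n = q1.size
    if n < 2:
        raise ValueError("paired t test needs at least 2 pairs")
    d = q4 - q1
    df = n - 1
    sd = float(np.std(d, ddof=1))
    mean = float(np.mean(d))
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, df, 1.0
        warnings.warn(
            "zero variance of paired differences with nonzero mean; "
            "t is infinite and p reported as 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(np.sign(mean)) * np.inf, df, 0.0
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), df, p


def power_from_effect(
    effect_size: float, n: int, alpha: float = 0.05
) -> float:
    """Power of a two-sided paired t test at standardized effect ``d``.

    ``effect_size`` is mean(d)/sd(d); the noncentrality parameter is
    ``effect_size * sqrt(n)``.  At effect 0 this returns exactly
    ``alpha`` (the test's size).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    df = n - 1
    ncp = effect_size * np.sqrt(n)
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    power = stats.nct.sf(t_crit, df, ncp) + stats.nct.cdf(-t_crit, df, ncp)
    if not np.isfinite(power):
        # extreme noncentrality overflows the nct quadrature; use the
        # asymptotic normal shift, accurate to ~1e-3 where it kicks in
        power = stats.norm.sf(t_crit - ncp) + stats.norm.cdf(-t_crit - ncp)
    return float(min(max(power, 0.0), 1.0))


def posthoc_power(
    q1_values: Sequence[float], q4_values: Sequence[float], alpha: float = 0.05
) -> float:
    """Post-hoc power at the observed paired effect size."""
    q1 = np.asarray(q1_values, dtype=float)
    q4 = np.asarray(q4_values, dtype=float)
    if q1.shape != q4.shape or q1.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    d = q4 - q1
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        raise ValueError("post-hoc power undefined: zero variance of differences")
    return power_from_effect(float(np.mean(d)) / sd, q1.size, alpha)


def summarize_cohort(
    cohort: Iterable[ParticipantMetrics],
    subgroup: str = "all",
    metrics: Sequence[str] = METRICS,
    alpha: float = 0.05,
) -> list[PairedComparison]:
    """One paired comparison per metric for a (sub)cohort.

    ``subgroup`` filters on role: "all", "residents" or "attendings".
    Quarter means and SDs use the sample (n-1) SD.
    """
    if subgroup not in ("all", "residents", "attendings"):
        raise ValueError("subgroup must be 'all', 'residents' or 'attendings'")
    rows = [
        p
        for p in cohort
        if subgroup == "all" or p.role == subgroup.rstrip("s")
    ]
    n = len(rows)
    if n < 2:
        raise ValueError(f"subgroup {subgroup!r} has {n} pairs; need at least 2")
    out = []
    for metric in metrics:
        q1 = np.array([p.q1[metric] for p in rows])
        q4 = np.array([p.q4[metric] for p in rows])
        t, df, p = paired_t(q1, q4)
        out.append(
            PairedComparison(
                metric=metric,
                q1_mean=float(np.mean(q1)),
                q1_sd=float(np.std(q1, ddof=1)),
                q4_mean=float(np.mean(q4)),
                q4_sd=float(np.std(q4, ddof=1)),
                t_stat=t,
                df=df,
                p_two_sided=p,
                power=posthoc_power(q1, q4, alpha),
                n_pairs=n,
            )
        )
    return out


def comparisons_to_frame(rows: Sequence[PairedComparison]) -> pd.DataFrame:
    """Tabulate comparisons in the mean (SD) / P / power layout."""
    frame = pd.DataFrame(
        {
            "metric": [r.metric for r in rows],
            "q1_mean": [r.q1_mean for r in rows],
            "q1_sd": [r.q1_sd for r in rows],
            "q4_mean": [r.q4_mean for r in rows],
            "q4_sd": [r.q4_sd for r in rows],
            "t_stat": [r.t_stat for r in rows],
            "df": [r.df for r in rows],
            "p_value": [r.p_two_sided for r in rows],
            "power": [r.power for r in rows],
            "n_pairs": [r.n_pairs for r in rows],
        }
    )
    frame.attrs["note"] = UNCORRECTED_TESTS_NOTE
    return frame
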