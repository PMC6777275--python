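"""Independent brute-force reference implementations used only by tests.

Deliberately naive (pure-Python loops, textbook formulas) and kept
separate from the package so that agreement is a genuine cross-check.
"""

from __future__ import annotations

import math


def brute_median_rate_bpm(ibis: list[float]) -> float:
    rates = sorted(60.0 / x for x in ibis)
    n = len(rates)
    mid = n // 2
    if n % 2:
        return rates[mid]
    return 0.5 * (rates[mid - 1] + rates[mid])


def brute_mean(ibis: list[float]) -> float:
    return sum(ibis) / len(ibis)


def brute_sample_sd(ibis: list[float]) -> float:
    n = len(ibis)
    m = brute_mean(ibis)
    return math.sqrt(sum((x - m) ** 2 for x in ibis) / (n - 1))


def brute_rmssd(run_rr: list[float]) -> float:
    diffs = [run_rr[i + 1] - run_rr[i] for i in range(len(run_rr) - 1)]
    return math.sqrt(sum(d * d for d in diffs) / len(diffs))


def brute_longest_run(offsets: list[float], ibis: list[float], tol: float) -> tuple[int, int]:
    """(start, end) inclusive indices of the earliest longest contiguous run."""
    runs = []
    start = 0
    for i in range(1, len(offsets)):
        if abs(offsets[i] - offsets[i - 1] - ibis[i]) > tol * (1 + 1e-9):
            runs.append((start, i - 1))
            start = i
    runs.append((start, len(offsets) - 1))
    best = max(runs, key=lambda r: r[1] - r[0])  # max is stable: earliest wins ties
    return best
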