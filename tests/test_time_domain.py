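import numpy as np
import pytest
from hypothesis import given, strategies as st

from shiftpulse.session_io import IbiLog
from shiftpulse.time_domain import (
    BeatRun,
    longest_contiguous_run,
    mean_rr,
    median_pulse_rate,
    rmssd,
    sdnn,
    time_domain_metrics,
)

from ._oracles import (
    brute_longest_run,
    brute_mean,
    brute_median_rate_bpm,
    brute_rmssd,
    brute_sample_sd,
)
from .conftest import make_random_ibi


def _contiguous_log(ibis) -> IbiLog:
    ibis = np.asarray(ibis, dtype=float)
    return IbiLog(0.0, np.cumsum(ibis), ibis)


def _run(ibis) -> BeatRun:
    log = _contiguous_log(ibis)
    return longest_contiguous_run(log)


class TestExamples:
    @pytest.mark.parametrize(
        "ibis, expected",
        [
            ([0.8] * 5, 75.0),
            ([0.5, 1.0, 1.5], 60.0),
            ([0.5, 1.0], 90.0),     # even count: mean of middle rates
        ],
    )
    def test_median_pulse_rate(self, ibis, expected):
        assert median_pulse_rate(_contiguous_log(ibis)) == pytest.approx(expected)

    @pytest.mark.parametrize("ibis, expected", [([0.8] * 4, 0.8), ([0.7, 0.9], 0.8)])
    def test_mean_rr(self, ibis, expected):
        assert mean_rr(_contiguous_log(ibis)) == pytest.approx(expected)

    def test_sdnn_closed_form(self):
        assert sdnn(_contiguous_log([0.8] * 10)) == 0.0
        assert sdnn(_contiguous_log([0.7, 0.9])) == pytest.approx(np.sqrt(0.02), abs=1e-12)

    def test_rmssd_examples(self):
        assert rmssd(_run([0.8] * 10)) == 0.0
        assert rmssd(_run([0.8, 0.9] * 5)) == pytest.approx(0.1, abs=1e-12)

    @pytest.mark.parametrize(
        "func, min_beats",
        [(median_pulse_rate, 1), (mean_rr, 1), (sdnn, 2)],
    )
    def test_empty_or_tiny_logs_rejected(self, func, min_beats):
        empty = IbiLog(0.0, np.empty(0), np.empty(0))
        with pytest.raises(ValueError):
            func(empty)


class TestLongestRun:
    def test_fully_contiguous_log_is_one_run(self):
        run = longest_contiguous_run(_contiguous_log([0.8] * 100))
        assert (run.start_index, run.end_index) == (0, 99)
        assert run.n_beats == 100

    def test_gap_splits_log_and_longer_segment_wins(self):
        ibis = np.full(100, 0.8)
        offsets = np.cumsum(ibis)
        offsets[40:] += 5.0          # 5 s gap after beat index 39
        run = longest_contiguous_run(IbiLog(0.0, offsets, ibis))
        assert (run.start_index, run.end_index) == (40, 99)
        assert run.n_beats == 60

    def test_gap_of_one_sample_period_is_contiguous(self):
        ibis = np.full(10, 0.8)
        offsets = np.cumsum(ibis)
        offsets[5:] += 1.0 / 64.0
        run = longest_contiguous_run(IbiLog(0.0, offsets, ibis))
        assert run.n_beats == 10

    def test_gap_of_two_sample_periods_splits(self):
        ibis = np.full(10, 0.8)
        offsets = np.cumsum(ibis)
        offsets[5:] += 2.0 / 64.0
        run = longest_contiguous_run(IbiLog(0.0, offsets, ibis))
        assert run.n_beats == 5

    def test_equal_length_runs_tie_break_to_earliest(self):
        ibis = np.full(10, 0.8)
        offsets = np.cumsum(ibis)
        offsets[5:] += 5.0
        run = longest_contiguous_run(IbiLog(0.0, offsets, ibis))
        assert (run.start_index, run.end_index) == (0, 4)

    def test_no_run_of_two_raises(self):
        ibis = np.array([0.8, 0.8])
        offsets = np.array([0.8, 10.0])
        with pytest.raises(ValueError, match="contiguous"):
            longest_contiguous_run(IbiLog(0.0, offsets, ibis))


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_logs(self, seed):
        rng = np.random.default_rng(seed)
        log = make_random_ibi(rng, 200)
        ibis = log.ibis.tolist()
        assert median_pulse_rate(log) == pytest.approx(
            brute_median_rate_bpm(ibis), rel=1e-12
        )
        assert mean_rr(log) == pytest.approx(brute_mean(ibis), rel=1e-12)
        assert sdnn(log) == pytest.approx(brute_sample_sd(ibis), rel=1e-12)
        run = longest_contiguous_run(log)
        s, e = brute_longest_run(log.offsets.tolist(), ibis, 1.0 / 64.0)
        assert (run.start_index, run.end_index) == (s, e)
        assert rmssd(run) == pytest.approx(brute_rmssd(run.rr.tolist()), rel=1e-12)


class TestProperties:
    @given(st.floats(0.5, 3.0), st.integers(0, 100))
    def test_scale_equivariance(self, c, seed):
        rng = np.random.default_rng(seed)
        ibis = rng.uniform(0.5, 1.2, 30)
        log = _contiguous_log(ibis)
        scaled = _contiguous_log(c * ibis)
        assert mean_rr(scaled) == pytest.approx(c * mean_rr(log), rel=1e-9)
        assert sdnn(scaled) == pytest.approx(c * sdnn(log), rel=1e-9)
        assert median_pulse_rate(scaled) == pytest.approx(
            median_pulse_rate(log) / c, rel=1e-9
        )
        assert rmssd(longest_contiguous_run(scaled)) == pytest.approx(
            c * rmssd(longest_contiguous_run(log)), rel=1e-9
        )

    @given(st.integers(0, 100))
    def test_permutation_invariance_except_rmssd(self, seed):
        rng = np.random.default_rng(seed)
        ibis = rng.uniform(0.5, 1.2, 40)
        log = _contiguous_log(ibis)
        perm = _contiguous_log(rng.permutation(ibis))
        assert median_pulse_rate(perm) == pytest.approx(median_pulse_rate(log))
        assert mean_rr(perm) == pytest.approx(mean_rr(log))
        assert sdnn(perm) == pytest.approx(sdnn(log))

    def test_rmssd_is_order_sensitive(self):
        sorted_run = _run(sorted([0.5, 1.2, 0.6, 1.1, 0.7, 1.0]))
        alternating = _run([0.5, 1.2, 0.6, 1.1, 0.7, 1.0])
        assert rmssd(alternating) > rmssd(sorted_run)

    @given(st.integers(0, 100))
    def test_rmssd_bounded_by_successive_differences(self, seed):
        rng = np.random.default_rng(seed)
        run = _run(rng.uniform(0.5, 1.2, 25))
        diffs = np.abs(np.diff(run.rr))
        assert diffs.min() - 1e-12 <= rmssd(run) <= diffs.max() + 1e-12


def test_full_metric_bundle_reports_run_sizes():
    ibis = np.full(50, 0.8)
    offsets = np.cumsum(ibis)
    offsets[30:] += 4.0
    m = time_domain_metrics(IbiLog(0.0, offsets, ibis))
    assert m.n_beats_used == 50
    assert m.longest_run_beats == 30
    assert m.mpr_bpm == pytest.approx(75.0)
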