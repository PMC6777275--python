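import numpy as np
import pytest

from shiftpulse.detection import detect_beats
from shiftpulse.session_io import DEVICE_FS_HZ
from shiftpulse.synthetic import (
    SyntheticConfig,
    generate_rr_series,
    generate_session,
    make_cohort,
    modulation_transfer,
    rate_amplitude_for_rr_amplitude,
    render_bvp,
)
from shiftpulse.time_domain import mean_rr, sdnn


def _quiet(duration_s, **kw):
    defaults = dict(
        duration_s=duration_s,
        mean_rr_s=0.8,
        lf_mod=(0.10, 0.0),
        hf_mod=(0.25, 0.0),
        white_noise_sd=0.0,
        dropout_fraction=0.0,
    )
    defaults.update(kw)
    return SyntheticConfig(**defaults)


class TestBeatProcess:
    def test_unmodulated_integrator_fires_at_exact_multiples(self):
        truth = generate_rr_series(_quiet(8.0))
        np.testing.assert_allclose(truth.beat_times, 0.8 * np.arange(1, 11), atol=1e-9)
        np.testing.assert_allclose(truth.rr, 0.8, atol=1e-9)

    def test_beat_times_strictly_increasing_and_in_range(self):
        truth = generate_rr_series(SyntheticConfig(duration_s=300.0, seed=5))
        assert np.all(np.diff(truth.beat_times) > 0)
        assert truth.beat_times[0] > 0
        assert truth.beat_times[-1] <= 300.0

    def test_same_seed_reproduces_identical_beats(self):
        cfg = SyntheticConfig(duration_s=120.0, seed=11)
        a = generate_rr_series(cfg)
        b = generate_rr_series(cfg)
        np.testing.assert_array_equal(a.beat_times, b.beat_times)

    def test_distinct_seeds_differ(self):
        a = generate_rr_series(SyntheticConfig(duration_s=120.0, seed=1))
        b = generate_rr_series(SyntheticConfig(duration_s=120.0, seed=2))
        assert not np.array_equal(a.beat_times, b.beat_times)

    def test_single_band_modulation_concentrates_spectral_power(self):
        """Oracle DFT of the RR tachogram: >=90% of LF+HF power in the
        modulated band, for each band in turn."""
        amp = rate_amplitude_for_rr_amplitude(0.03, 0.8, 0.25)
        for band, mod in (("hf", (0.25, amp)), ("lf", (0.10, amp))):
            kw = {"lf_mod": (0.10, 0.0), "hf_mod": (0.25, 0.0)}
            kw[f"{band}_mod"] = mod
            truth = generate_rr_series(_quiet(600.0, **kw))
            # independent resample + rFFT, no package spectral code
            fs = 4.0
            t = np.arange(truth.beat_times[0], truth.beat_times[-1], 1 / fs)
            rr = np.interp(t, truth.beat_times, truth.rr)
            rr = rr - rr.mean()
            power = np.abs(np.fft.rfft(rr)) ** 2
            freqs = np.fft.rfftfreq(rr.size, 1 / fs)
            lf = power[(freqs >= 0.05) & (freqs < 0.15)].sum()
            hf = power[(freqs >= 0.15) & (freqs < 0.40)].sum()
            share = (lf if band == "lf" else hf) / (lf + hf)
            assert share >= 0.90

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError):
            SyntheticConfig(mean_rr_s=0.1)
        with pytest.raises(ValueError):
            SyntheticConfig(lf_mod=(0.2, 0.1))
        with pytest.raises(ValueError):
            SyntheticConfig(dropout_fraction=1.0)

    def test_modulation_transfer_is_beat_averaging_sinc(self):
        assert modulation_transfer(0.0, 0.8) == 1.0
        assert modulation_transfer(0.25, 0.8) == pytest.approx(
            np.sin(np.pi * 0.2) / (np.pi * 0.2)
        )


class TestWaveformRenderer:
    def test_sample_count_matches_duration(self):
        truth = generate_rr_series(_quiet(10.0))
        bvp = render_bvp(truth)
        assert bvp.n_samples == 640

    def test_no_dropout_gives_full_coverage(self):
        truth = generate_rr_series(_quiet(30.0))
        assert truth.coverage_mask.all()
        assert truth.dropout_intervals == ()

    def test_coverage_fraction_tracks_dropout_fraction(self):
        cfg = SyntheticConfig(duration_s=600.0, dropout_fraction=0.4, seed=9)
        truth = generate_rr_series(cfg)
        frac = 1.0 - truth.coverage_mask.mean()
        assert frac == pytest.approx(0.4, abs=2.0 / 600.0)

    def test_one_rendered_peak_per_clean_beat(self):
        truth = generate_rr_series(_quiet(20.0, baseline_noise_sd=0.0))
        bvp = render_bvp(truth)
        fs = DEVICE_FS_HZ
        for bt in truth.beat_times[:-1]:
            k = int(round(bt * fs))
            window = bvp.samples[max(0, k - 3) : k + 4]
            assert bvp.samples[k] >= window.max() - 1e-9

    def test_clean_ibi_log_excludes_dropout_straddlers(self):
        cfg = SyntheticConfig(duration_s=400.0, dropout_fraction=0.25, dropout_block_s=100.0, seed=2)
        truth = generate_rr_series(cfg)
        log = truth.clean_ibi_log()
        assert not truth.in_dropout(log.offsets).any()
        assert not truth.in_dropout(log.offsets - log.ibis).any()


class TestCohortSimulator:
    def test_zero_effect_gives_identical_generating_parameters(self):
        for pair in make_cohort(5, {}, seed=3):
            assert pair.q1.mean_rr_s == pair.q4.mean_rr_s
            assert pair.q1.lf_mod == pair.q4.lf_mod
            assert pair.q1.hf_mod == pair.q4.hf_mod

    def test_same_seed_reproduces_cohort(self):
        assert make_cohort(6, {"mean_rr_s": 0.05}, seed=4) == make_cohort(
            6, {"mean_rr_s": 0.05}, seed=4
        )

    def test_mean_rr_effect_recovered_in_measured_mrri(self):
        base = SyntheticConfig(duration_s=300.0, dropout_fraction=0.0)
        pairs = make_cohort(8, {"mean_rr_s": 0.05}, seed=5, base=base)
        diffs = []
        for pair in pairs:
            q1 = mean_rr(generate_rr_series(pair.q1).clean_ibi_log())
            q4 = mean_rr(generate_rr_series(pair.q4).clean_ibi_log())
            diffs.append(q4 - q1)
        assert np.mean(diffs) == pytest.approx(0.05, abs=0.01)

    def test_requires_two_participants(self):
        with pytest.raises(ValueError):
            make_cohort(1)


class TestParameterRecovery:
    def test_downstream_estimates_recover_generator_truth(self):
        """Full detect path on a clean 10-minute session: MRRI within 1%
        of the configured mean; SDNN within 10% of the generated RR SD."""
        cfg = SyntheticConfig(duration_s=600.0, dropout_fraction=0.0, seed=7)
        truth, bvp = generate_session(cfg)
        ibi = detect_beats(bvp)
        assert mean_rr(ibi) == pytest.approx(cfg.mean_rr_s, rel=0.01)
        assert sdnn(ibi) == pytest.approx(float(np.std(truth.rr, ddof=1)), rel=0.10)
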