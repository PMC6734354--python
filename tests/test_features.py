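import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import rr_from_values
from richrv.features import (
    band_powers,
    compute_all,
    correct_ectopics,
    poincare,
    resample_tachogram,
    time_domain,
    welch_psd,
)
from richrv.synthetic import RRGenParams, generate_rr_series
from richrv.types import RRSeries, Segment


class TestTimeDomain:
    def test_worked_example(self, toy_rr):
        # diffs (60, -40, 80, -60): three exceed 50 ms
        f = time_domain(toy_rr)
        assert f["mean_rr_ms"] == pytest.approx(844.0)
        assert f["median_rr_ms"] == pytest.approx(840.0)
        assert f["nn50"] == 3
        assert f["pnn50"] == pytest.approx(60.0)
        assert f["rmssd_ms"] == pytest.approx(math.sqrt(3800.0))

    def test_constant_series_has_zero_variability(self, constant_rr):
        f = time_domain(constant_rr)
        assert f["sdrr_ms"] == 0.0
        assert f["sdsd_ms"] == 0.0
        assert f["rmssd_ms"] == 0.0
        assert f["pnn50"] == 0.0

    def test_nn50_threshold_is_strict(self):
        f = time_domain(rr_from_values([1000.0, 1051.0, 1051.0]))
        assert f["nn50"] == 1
        # exactly 50 ms does not count
        f50 = time_domain(rr_from_values([1000.0, 1050.0, 1050.0]))
        assert f50["nn50"] == 0

    def test_pnn50_interval_denominator(self):
        # two intervals, one qualifying difference -> 50% under the
        # interval-count convention, 100% under the diff-count one
        rr = rr_from_values([1000.0, 1051.0])
        with pytest.raises(ValueError):
            time_domain(rr)  # needs >= 3 intervals
        rr3 = rr_from_values([1000.0, 1051.0, 1051.0])
        assert time_domain(rr3)["pnn50"] == pytest.approx(100.0 / 3)
        assert time_domain(rr3, denominator="diffs")["pnn50"] == pytest.approx(50.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            time_domain(rr_from_values([800.0, 810.0]))


class TestCorrectEctopics:
    def test_clean_series_untouched(self, constant_rr):
        out, idx, qc = correct_ectopics(constant_rr)
        assert idx == []
        np.testing.assert_array_equal(out.rr_ms, constant_rr.rr_ms)

    def test_single_outlier_interpolated(self, constant_rr):
        x = constant_rr.rr_ms.copy()
        x[40] = 600.0
        out, idx, _ = correct_ectopics(RRSeries(constant_rr.beat_time_s, x, check_consistency=False))
        assert idx == [40]
        assert out.rr_ms[40] == pytest.approx(1000.0)

    def test_adjacent_same_sign_pair_left_with_note(self, constant_rr):
        x = constant_rr.rr_ms.copy()
        x[40] = 600.0
        x[41] = 600.0
        out, idx, qc = correct_ectopics(RRSeries(constant_rr.beat_time_s, x, check_consistency=False))
        assert idx == []
        assert "unresolved_ectopic_run" in qc
        assert out.rr_ms[40] == 600.0

    def test_compensatory_couplet_corrected(self, constant_rr):
        x = constant_rr.rr_ms.copy()
        x[40] = 600.0
        x[41] = 1400.0
        out, idx, _ = correct_ectopics(RRSeries(constant_rr.beat_time_s, x, check_consistency=False))
        assert idx == [40, 41]
        np.testing.assert_allclose(out.rr_ms[40:42], [1000.0, 1000.0])

    def test_high_load_flagged(self):
        vals = np.full(60, 1000.0)
        vals[::10] = 600.0  # 10% deviant
        out, _, qc = correct_ectopics(
            RRSeries(np.cumsum(np.full(60, 1.0)), vals, check_consistency=False)
        )
        assert "high_ectopic_load" in qc


class TestResampleTachogram:
    def test_constant_series_gives_zero_tachogram(self, constant_rr):
        _, x = resample_tachogram(constant_rr)
        np.testing.assert_allclose(x, 0.0, atol=1e-9)

    def test_grid_spacing_is_inverse_fs(self, toy_rr):
        t, _ = resample_tachogram(toy_rr, fs_hz=10.0)
        np.testing.assert_allclose(np.diff(t), 0.1)

    def test_spline_reproduces_smooth_modulation(self):
        beat_t = np.arange(1.0, 61.0)
        vals = 1000.0 + 100.0 * np.sin(2 * np.pi * 0.1 * beat_t)
        rr = RRSeries(beat_t, vals, check_consistency=False)
        t, x = resample_tachogram(rr)
        expected = 1000.0 + 100.0 * np.sin(2 * np.pi * 0.1 * t)
        expected -= np.mean(expected)
        inner = (t > beat_t[2]) & (t < beat_t[-3])
        assert np.max(np.abs(x[inner] - expected[inner])) < 1.0

    def test_too_few_knots_rejected(self):
        with pytest.raises(ValueError):
            resample_tachogram(rr_from_values([800.0, 820.0, 810.0]))


class TestWelchPSD:
    def test_zero_signal_zero_psd(self):
        f, pxx = welch_psd(np.zeros(3000))
        assert np.all(pxx == 0.0)

    def test_parseval_for_sinusoid(self):
        t = np.arange(3000) / 10.0  # 300 s at 10 Hz
        x = 40.0 * np.sin(2 * np.pi * 0.25 * t)
        f, pxx = welch_psd(x)
        assert np.trapezoid(pxx, f) == pytest.approx(40.0**2 / 2, rel=0.05)

    def test_parseval_for_white_noise(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0.0, 5.0, size=3000)
        f, pxx = welch_psd(x)
        assert np.trapezoid(pxx, f) == pytest.approx(np.var(x), rel=0.10)

    def test_short_input_rejected_with_minimum_named(self):
        with pytest.raises(ValueError, match="256"):
            welch_psd(np.zeros(100))


class TestBandPowers:
    def test_single_hf_line(self):
        t = np.arange(6000) / 10.0
        x = 30.0 * np.sin(2 * np.pi * 0.25 * t)
        f, pxx = welch_psd(x)
        powers, qc = band_powers(f, pxx)
        assert powers["nu_hf"] > 99.0
        assert powers["nu_lf"] < 1.0
        assert powers["lf_hf"] < 0.01

    def test_equal_band_power_symmetry(self):
        # identical spectral bumps centred in the LF and HF bands
        f = np.arange(0, 0.5, 0.001)
        bump = lambda c: np.exp(-0.5 * ((f - c) / 0.01) ** 2)
        pxx = bump(0.095) + bump(0.275)
        powers, _ = band_powers(f, pxx)
        assert powers["nu_lf"] == pytest.approx(50.0, abs=0.5)
        assert powers["nu_hf"] == pytest.approx(50.0, abs=0.5)
        assert powers["lf_hf"] == pytest.approx(1.0, abs=0.02)

    def test_normalized_powers_sum_to_100(self):
        rng = np.random.default_rng(3)
        f = np.arange(0, 0.5, 0.005)
        pxx = rng.uniform(0.1, 2.0, size=f.size)
        powers, _ = band_powers(f, pxx)
        assert powers["nu_lf"] + powers["nu_hf"] == pytest.approx(100.0, abs=0.5)

    def test_zero_spectrum_gives_missing_normalized_powers(self):
        f = np.arange(0, 0.5, 0.01)
        powers, qc = band_powers(f, np.zeros_like(f))
        assert math.isnan(powers["nu_lf"])
        assert "zero_normalizable_power" in qc


class TestPoincare:
    def test_worked_example(self, toy_rr):
        # SDSD^2 = 3700, SDRR^2 = 1184 (population convention)
        p = poincare(toy_rr)
        assert p.sd1_ms == pytest.approx(math.sqrt(1850.0))
        assert p.sd2_ms == pytest.approx(math.sqrt(518.0))

    def test_constant_series(self, constant_rr):
        p = poincare(constant_rr)
        assert p.sd1_ms == 0.0
        assert p.sd2_ms == 0.0

    def test_alternating_series_limit(self):
        vals = np.tile([800.0, 900.0], 500)
        p = poincare(rr_from_values(vals))
        assert p.sd1_ms == pytest.approx(100.0 / math.sqrt(2), rel=1e-3)
        assert p.sd2_ms < 2.0  # -> 0 in the limit

    def test_negative_sd2_clamped_with_flag(self):
        p = poincare(rr_from_values([800.0, 900.0, 800.0, 900.0, 800.0]))
        assert p.sd2_sq_raw_ms2 < 0
        assert p.sd2_ms == 0.0
        assert "sd2_clamped" in p.qc_flags
        assert math.isnan(p.sd1_sd2)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=300.0, max_value=2000.0), min_size=3, max_size=200))
    def test_identity_sd1_sq_plus_sd2_sq(self, vals):
        rr = rr_from_values(vals)
        p = poincare(rr)
        sdrr_sq = float(np.var(rr.rr_ms))
        assert p.sd1_ms**2 + p.sd2_sq_raw_ms2 == pytest.approx(2 * sdrr_sq, rel=1e-9, abs=1e-9)

    def test_rmssd_equals_sdsd_for_zero_mean_differences(self):
        # periodic series: first differences sum to zero over full cycles
        vals = np.tile([800.0, 850.0, 900.0, 850.0], 50)
        vals = np.append(vals, 800.0)  # close the cycle
        f = time_domain(rr_from_values(vals))
        d = np.diff(vals)
        assert np.mean(d) == pytest.approx(0.0, abs=1e-12)
        assert f["rmssd_ms"] == pytest.approx(f["sdsd_ms"], rel=1e-12)


class TestComputeAll:
    def test_constant_segment_flags_degenerate_spectrum(self, constant_rr):
        feats = compute_all(Segment("baseline_1", constant_rr))
        assert feats.sdrr_ms == 0.0
        assert feats.sd1_ms == 0.0
        assert math.isnan(feats.nu_lf)
        assert "zero_normalizable_power" in feats.qc_flags

    def test_hf_only_modulation_dominates_hf_band(self):
        rr = generate_rr_series(RRGenParams(duration_s=300, mean_rr_ms=900, hf_amp_ms=40, seed=2))
        feats = compute_all(Segment("occlusion_1", rr))
        assert feats.nu_hf > 90.0

    def test_deterministic(self, toy_rr):
        rr = generate_rr_series(
            RRGenParams(duration_s=300, mean_rr_ms=850, lf_amp_ms=30, noise_sd_ms=10, seed=4)
        )
        seg = Segment("post_rest", rr)
        a, b = compute_all(seg), compute_all(seg)
        assert a.as_dict() == b.as_dict()

    def test_errors_annotated_with_segment_label(self, toy_rr):
        with pytest.raises(ValueError, match="occlusion_3"):
            compute_all(Segment("occlusion_3", toy_rr))  # too short for spectrum
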