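import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from _oracle import brute_force_wilcoxon_two_sided
from richrv.segmentation import build_timeline
from richrv.features import cohort_feature_table
from richrv.stats import (
    NON_OCCLUSION_PHASES,
    OCCLUSION_PHASES,
    POST_PHASES,
    PRE_PHASES,
    assign_subsets,
    compare_occlusion,
    compare_pre_post,
    correlate_deltas,
    wilcoxon_signed_rank,
)
from richrv.synthetic import CohortSpec, RRGenParams, generate_ric_cohort


class TestWilcoxon:
    def test_three_positive_differences_exact_quarter(self):
        res = wilcoxon_signed_rank(np.array([2.0, 3.0, 4.0]), np.array([1.0, 1.0, 1.0]))
        assert res.p_value == pytest.approx(0.25)
        assert res.statistic == 0.0
        assert res.direction == 1

    def test_identical_samples_degenerate(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="degenerate"):
            wilcoxon_signed_rank(x, x)

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(7)
        d = rng.normal(size=10)
        p1 = wilcoxon_signed_rank(d, np.zeros(10)).p_value
        p2 = wilcoxon_signed_rank(-d, np.zeros(10)).p_value
        assert p1 == pytest.approx(p2)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 15))
            d = rng.normal(size=n)
            mine = wilcoxon_signed_rank(d, np.zeros(n)).p_value
            ref = sp_stats.wilcoxon(d, mode="exact").pvalue
            assert mine == pytest.approx(ref, rel=1e-12)

    def test_matches_enumeration_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(60):
            n = int(rng.integers(3, 9))
            d = rng.integers(-4, 5, size=n).astype(float)
            d = d[d != 0]
            if d.size == 0:
                continue
            mine = wilcoxon_signed_rank(d, np.zeros_like(d)).p_value
            ref = brute_force_wilcoxon_two_sided(d)
            assert mine == pytest.approx(ref, rel=1e-12)

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(5)
        d = rng.normal(0.3, 1.0, size=60)
        mine = wilcoxon_signed_rank(d, np.zeros(60))
        ref = sp_stats.wilcoxon(d, correction=True, mode="approx").pvalue
        assert mine.p_value == pytest.approx(ref, rel=1e-6)


def _make_cohort_table(n_young=4, n_senior=4, mult=1.0, seed=0, noise=6.0):
    tl = build_timeline()
    young = RRGenParams(3300, 800, vlf_amp_ms=30, lf_amp_ms=25, hf_amp_ms=20, noise_sd_ms=noise)
    senior = RRGenParams(3300, 900, vlf_amp_ms=18, lf_amp_ms=14, hf_amp_ms=10, noise_sd_ms=noise)
    cohort = generate_ric_cohort(
        CohortSpec(n_young, n_senior, tl, young, senior, post_effect_multiplier=mult, seed=seed)
    )
    return cohort_feature_table(cohort, tl, domains=("time", "poincare"))


class TestComparisons:
    def test_pre_post_reports_one_result_per_feature(self):
        table = _make_cohort_table(seed=3)
        feats = ["sd2_ms", "rmssd_ms", "mean_rr_ms"]
        results = compare_pre_post(table, features=feats)
        assert [r.feature for r in results] == feats
        assert all(r.comparison == "pre_vs_post" for r in results)
        assert all(r.n_pairs == 8 for r in results)

    def test_missing_phase_excludes_subject(self):
        table = _make_cohort_table(seed=3)
        drop = (table["subject_id"] == "S01") & (table["phase"] == "baseline_1")
        reduced = table[~drop]
        res = compare_pre_post(reduced, features=["sd2_ms"])[0]
        assert res.n_pairs == 7

    def test_subset_with_single_subject_rejected(self):
        table = _make_cohort_table(n_young=3, n_senior=1, seed=2)
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_pre_post(table, subset="senior", features=["sd2_ms"])

    def test_amplified_slow_band_detected_as_sd2_increase(self):
        table = _make_cohort_table(n_young=9, n_senior=8, mult=1.5, seed=11)
        res = compare_pre_post(table, features=["sd2_ms"])[0]
        assert res.significant
        assert res.direction == 1

    def test_occlusion_comparison_uses_all_eight_phases(self):
        table = _make_cohort_table(seed=5)
        res = compare_occlusion(table, features=["sd2_ms"])[0]
        assert res.comparison == "occlusion_vs_non_occlusion"
        assert res.n_pairs == 8

    def test_invariance_to_subject_order(self):
        table = _make_cohort_table(seed=7)
        shuffled = table.sample(frac=1.0, random_state=1)
        a = compare_pre_post(table, features=["sd2_ms"])[0]
        b = compare_pre_post(shuffled, features=["sd2_ms"])[0]
        assert a.p_value == pytest.approx(b.p_value)

    def test_invariance_to_increasing_affine_transform(self):
        # positive rescaling + shift of the feature preserves the ranks of
        # the paired differences, hence the exact p-value
        table = _make_cohort_table(seed=9)
        transformed = table.copy()
        transformed["sd2_ms"] = 3.7 * transformed["sd2_ms"] + 120.0
        a = compare_pre_post(table, features=["sd2_ms"])[0]
        b = compare_pre_post(transformed, features=["sd2_ms"])[0]
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)
        assert a.direction == b.direction


class TestCorrelations:
    def _delta_table(self, slopes):
        rows = []
        for i, s in enumerate(slopes):
            sid = f"S{i:02d}"
            for phase in PRE_PHASES:
                rows.append({"subject_id": sid, "phase": phase, "a": 10.0, "b": 5.0})
            for phase in POST_PHASES:
                rows.append({"subject_id": sid, "phase": phase, "a": 10.0 + s, "b": 5.0 + 2 * s})
        return pd.DataFrame(rows)

    def test_perfect_monotone_association(self):
        res = correlate_deltas(self._delta_table([1.0, 2.0, 3.0, 4.0, 5.0]), "a", "b")
        assert res.rho == pytest.approx(1.0)

    def test_antitone_association(self):
        table = self._delta_table([1.0, 2.0, 3.0, 4.0])
        table.loc[table["phase"].isin(POST_PHASES), "b"] = (
            5.0 - 2 * (table.loc[table["phase"].isin(POST_PHASES), "a"] - 10.0)
        )
        res = correlate_deltas(table, "a", "b")
        assert res.rho == pytest.approx(-1.0)

    def test_null_association_near_zero_on_average(self):
        rng = np.random.default_rng(21)
        rhos = []
        for _ in range(200):
            rows = []
            for i in range(10):
                sid = f"S{i:02d}"
                da, db = rng.normal(), rng.normal()
                for phase in PRE_PHASES:
                    rows.append({"subject_id": sid, "phase": phase, "a": 0.0, "b": 0.0})
                for phase in POST_PHASES:
                    rows.append({"subject_id": sid, "phase": phase, "a": da, "b": db})
            rhos.append(correlate_deltas(pd.DataFrame(rows), "a", "b").rho)
        assert abs(np.mean(rhos)) < 0.05

    def test_constant_delta_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            correlate_deltas(self._delta_table([2.0, 2.0, 2.0, 2.0]), "a", "b")

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            correlate_deltas(self._delta_table([1.0, 2.0, 3.0]), "a", "b")


class TestAssignSubsets:
    @pytest.mark.parametrize("age,expected", [(61, "senior"), (60, "young"), (25, "young")])
    def test_strict_cutoff(self, age, expected):
        table = pd.DataFrame({"subject_id": ["x"], "age": [age], "phase": ["baseline_1"]})
        assert assign_subsets(table)["subset"].iloc[0] == expected

    def test_missing_age_rejected(self):
        table = pd.DataFrame({"subject_id": ["x"], "age": [np.nan], "phase": ["baseline_1"]})
        with pytest.raises(ValueError):
            assign_subsets(table)
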