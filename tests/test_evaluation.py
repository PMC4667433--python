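"""Segmentation scores, agreement statistics, repeatability, jitter CV."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stridekit.evaluation import (
    InsufficientDataError,
    agreement,
    concordance_correlation,
    jitter_cv,
    loso_evaluate,
    overlap_percentage,
    repeatability,
    segmentation_score,
)
from stridekit.io import FootEvents, StrideAnnotation
from stridekit.segmentation import FootSegmentation
from stridekit.synth import SynthConfig, SubjectParams, generate_trial_walk


def seg_from_events(side, heel_strikes, toe_offs):
    return FootSegmentation(
        side=side,
        n_strides=len(heel_strikes) - 1,
        spans=[(a, b - 1) for a, b in zip(heel_strikes, heel_strikes[1:])],
        heel_strike_frames=list(heel_strikes),
        toe_off_frames=list(toe_offs),
    )


class TestOverlap:
    @pytest.mark.parametrize("t,g,expected", [
        ((5, 10), (5, 10), 1.0),
        ((1, 4), (5, 8), 0.0),
        ((3, 6), (5, 8), 2.0 / 6.0),
    ])
    def test_reference_values(self, t, g, expected):
        assert overlap_percentage(t, g) == pytest.approx(expected)

    def test_invalid_span_rejected(self):
        with pytest.raises(ValueError):
            overlap_percentage((5, 3), (1, 2))

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 50), st.integers(0, 20),
           st.integers(0, 50), st.integers(0, 20))
    def test_symmetry_and_identity(self, a, la, b, lb):
        t, g = (a, a + la), (b, b + lb)
        assert overlap_percentage(t, g) == overlap_percentage(g, t)
        assert (overlap_percentage(t, g) == 1.0) == (t == g)


class TestSegmentationScore:
    def test_perfect_prediction(self):
        ann = StrideAnnotation(right=FootEvents(
            heel_strikes=[10, 30, 50], toe_offs=[22, 42]))
        pred = seg_from_events("right", [10, 30, 50], [22, 42])
        s = segmentation_score(pred, ann, frame_rate=30.0)
        assert s.aod == 1.0
        assert s.rand_index == 1.0
        assert s.instant_error_sd == 0.0

    def test_constant_shift_has_zero_error_sd(self):
        ann = StrideAnnotation(right=FootEvents(
            heel_strikes=[10, 30, 50], toe_offs=[22, 42]))
        pred = seg_from_events("right", [11, 31, 51], [23, 43])
        s = segmentation_score(pred, ann, frame_rate=30.0)
        assert s.aod < 1.0
        assert s.instant_error_sd == pytest.approx(0.0)

    def test_rand_index_by_explicit_pair_counting(self):
        # 5 frames over the annotated span; pred splits the first stride
        ann = StrideAnnotation(right=FootEvents(
            heel_strikes=[0, 4, 6], toe_offs=[2, 5]))
        pred = seg_from_events("right", [0, 2, 6], [1, 4])
        s = segmentation_score(pred, ann, frame_rate=30.0)
        gt_labels = [1, 1, 1, 1, 2, 2]
        pr_labels = [1, 1, 2, 2, 2, 2]
        agree = 0
        pairs = list(itertools.combinations(range(6), 2))
        for i, j in pairs:
            same_gt = gt_labels[i] == gt_labels[j]
            same_pr = pr_labels[i] == pr_labels[j]
            agree += same_gt == same_pr
        assert s.rand_index == pytest.approx(agree / len(pairs))

    def test_unmatched_strides_count_as_zero_overlap(self):
        ann = StrideAnnotation(right=FootEvents(
            heel_strikes=[0, 10, 20, 30], toe_offs=[5, 15, 25]))
        pred = seg_from_events("right", [0, 10], [5])  # one of three found
        s = segmentation_score(pred, ann, frame_rate=30.0)
        assert s.aod == pytest.approx(1.0 / 3.0)


class TestAgreement:
    def test_perfect_agreement(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rep = agreement(a, a)
        assert rep.pearson == pytest.approx(1.0)
        assert rep.ccc == pytest.approx(1.0)
        assert rep.icc_2k == pytest.approx(1.0)
        assert rep.bias == 0.0
        assert rep.pe == 0.0

    def test_constant_shift_lowers_ccc_not_pearson(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = a + 2.0
        rep = agreement(a, b)
        assert rep.pearson == pytest.approx(1.0)
        assert rep.ccc < 1.0
        assert rep.bias == pytest.approx(2.0)
        assert rep.loa_low <= rep.bias <= rep.loa_high

    def test_against_textbook_formulas(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([1.1, 2.0, 2.9, 4.2])
        rep = agreement(a, b)

        # independent implementation from the published definitions
        ma, mb = a.mean(), b.mean()
        sa2 = ((a - ma) ** 2).sum() / 3
        sb2 = ((b - mb) ** 2).sum() / 3
        sab = ((a - ma) * (b - mb)).sum() / 3
        rho = sab / math.sqrt(sa2 * sb2)
        ccc = 2 * sab / (sa2 + sb2 + (ma - mb) ** 2)
        diff = b - a
        bias = diff.mean()
        sd = diff.std(ddof=1)
        pe = 100 * 4 * sd / (ma + mb)

        # ICC(2,k) from two-way mean squares (subjects x raters)
        X = np.column_stack([a, b])
        n, k = X.shape
        grand = X.mean()
        ms_rows = k * ((X.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        ms_cols = n * ((X.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        ss_err = (((X - X.mean(axis=1, keepdims=True)
                    - X.mean(axis=0, keepdims=True) + grand)) ** 2).sum()
        ms_err = ss_err / ((n - 1) * (k - 1))
        icc2k = (ms_rows - ms_err) / (ms_rows + (ms_cols - ms_err) / n)

        assert rep.pearson == pytest.approx(rho, abs=1e-9)
        assert rep.ccc == pytest.approx(ccc, abs=1e-9)
        assert rep.bias == pytest.approx(bias, abs=1e-9)
        assert rep.loa_high == pytest.approx(bias + 1.96 * sd, abs=1e-9)
        assert rep.pe == pytest.approx(pe, abs=1e-9)
        assert rep.icc_2k == pytest.approx(icc2k, abs=1e-6)

    def test_ccc_bounded_by_pearson(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.normal(0, 1, 8)
            b = 0.5 * a + rng.normal(0.3, 0.7, 8)
            rho = np.corrcoef(a, b)[0, 1]
            assert abs(concordance_correlation(a, b)) <= abs(rho) + 1e-12

    def test_ccc_equals_pearson_under_matched_moments(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 50)
        b = rng.normal(0, 1, 50)
        # standardize both to identical mean/variance
        a = (a - a.mean()) / a.std(ddof=1)
        b = (b - b.mean()) / b.std(ddof=1)
        rho = np.corrcoef(a, b)[0, 1]
        assert concordance_correlation(a, b) == pytest.approx(rho, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            agreement([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRepeatability:
    def test_identical_pairs(self):
        assert repeatability([(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)]) == (0.0, 0.0)

    def test_constant_difference_has_zero_sd(self):
        absolute, pct = repeatability([(1.0, 1.5), (2.0, 2.5), (3.0, 3.5)])
        assert absolute == pytest.approx(0.0)
        assert pct == pytest.approx(0.0)

    def test_monte_carlo_convergence_to_two_sd(self):
        rng = np.random.default_rng(2)
        s = 0.25
        first = rng.normal(10.0, 1.0, 10_000)
        second = first + rng.normal(0.0, s, 10_000)
        absolute, _ = repeatability(np.column_stack([first, second]))
        assert absolute == pytest.approx(2 * s, rel=0.03)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            repeatability([(1.0, 2.0), (2.0, 3.0)])


class TestJitterCv:
    def test_published_operating_point(self):
        assert round(jitter_cv(33.4, 3.7, 24, 3, 4), 2) == 0.65

    def test_zero_jitter(self):
        assert jitter_cv(33.4, 0.0, 24, 3, 4) == 0.0

    def test_single_stride_single_trial(self):
        assert round(jitter_cv(33.4, 3.7, 24, 1, 1), 2) == 2.26

    def test_matches_monte_carlo_simulation(self):
        mean, sd, q = 33.4, 3.7, 24
        n_trials, strides = 3, 4
        rng = np.random.default_rng(3)
        draws = 200_000
        periods = rng.normal(mean, sd, (draws, n_trials * strides, q))
        stride_times = periods.sum(axis=2)       # one stride = q periods
        mean_stride = stride_times.mean(axis=1)  # averaged per protocol
        cv_mc = 100 * mean_stride.std(ddof=1) / mean_stride.mean()
        cv = jitter_cv(mean, sd, q, n_trials, strides)
        se = cv_mc / math.sqrt(2 * draws)
        assert cv == pytest.approx(cv_mc, abs=3 * se + 1e-3)

    def test_nonpositive_arguments_rejected(self):
        with pytest.raises(ValueError):
            jitter_cv(-1.0, 3.7, 24, 3, 4)


class TestLoso:
    def test_identical_gait_two_subjects_noiseless_is_perfect(self):
        cfg = SynthConfig(joint_noise_sd=0.0, within_subject_period_cv=0.0,
                          snap_period_to_frames=True, seed=9)
        subject = SubjectParams("s", stride_period=0.8, stride_length=0.7)
        cohort = []
        for sid in ("a", "b"):
            trials = []
            for t in range(2):
                walk, gt = generate_trial_walk(
                    cfg, SubjectParams(sid, 0.8, 0.7),
                    trial_seed=[9, 0, t])
                trials.append((walk, gt.annotation))
            cohort.append((sid, trials))
        res = loso_evaluate(cohort)
        assert res.pooled_aod == pytest.approx(1.0)
        assert res.pooled_rand == pytest.approx(1.0)
        assert res.heel_strike_mae == 0.0

    def test_single_subject_rejected(self):
        with pytest.raises(InsufficientDataError):
            loso_evaluate([("only", [])])
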