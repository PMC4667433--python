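"""Distance kernels: fixed-length, uniform scaling, DTW, SDTW, SSWM."""

import numpy as np
import pytest

from conftest import identity_template, random_template
from stridekit.matching import (
    NoMatchError,
    WarpingPath,
    cost_matrix,
    dtw_ml,
    mahalanobis_sq,
    match_fixed_euclidean,
    match_fixed_ml,
    sdtw_ml,
    sswm,
    swm_oracle,
    uniform_scaling_match,
)


def enumerate_paths(v, m):
    """All monotone warping paths from (0,0) to (v-1,m-1)."""
    def rec(t, i):
        if t == 0 and i == 0:
            yield [(0, 0)]
            return
        for dt, di in ((1, 1), (1, 0), (0, 1)):
            if t - dt >= 0 and i - di >= 0:
                for p in rec(t - dt, i - di):
                    yield p + [(t, i)]
    yield from rec(v - 1, m - 1)


class TestMahalanobis:
    def test_zero_at_mean(self):
        assert mahalanobis_sq([1.0, 2.0], [1.0, 2.0], np.eye(2)) == 0.0

    def test_identity_covariance_is_squared_euclidean(self):
        rng = np.random.default_rng(0)
        x, mu = rng.normal(0, 1, 4), rng.normal(0, 1, 4)
        assert mahalanobis_sq(x, mu, np.eye(4)) == pytest.approx(
            float(np.sum((x - mu) ** 2)))

    def test_anisotropic_example(self):
        assert mahalanobis_sq([1.0, 0.0], [0.0, 0.0],
                              np.diag([4.0, 1.0])) == pytest.approx(0.25)

    def test_cost_matrix_matches_direct_solve(self):
        rng = np.random.default_rng(1)
        tpl = random_template(rng, 6, 4)
        X = rng.normal(0, 1, (9, 4))
        C = cost_matrix(X, tpl)
        for t in range(9):
            for i in range(6):
                assert C[t, i] == pytest.approx(
                    mahalanobis_sq(X[t], tpl.means[i], tpl.covariances[i]),
                    abs=1e-9)


class TestFixedLength:
    def test_walk_equal_to_means_is_zero(self):
        rng = np.random.default_rng(2)
        tpl = identity_template(rng.normal(0, 1, (5, 3)))
        X = tpl.means.copy()
        assert match_fixed_euclidean(X, 0, tpl) == 0.0
        assert match_fixed_ml(X, 0, tpl) == 0.0

    def test_constant_offset_accumulates(self):
        m, d, delta = 4, 3, 0.5
        tpl = identity_template(np.zeros((m, d)))
        X = np.full((m, d), delta)
        assert match_fixed_euclidean(X, 0, tpl) == pytest.approx(
            m * d * delta ** 2)

    def test_ml_reduces_to_euclidean_under_identity_covariance(self):
        rng = np.random.default_rng(3)
        tpl = identity_template(rng.normal(0, 1, (6, 4)))
        X = rng.normal(0, 1, (12, 4))
        for t_s in range(6):
            assert match_fixed_ml(X, t_s, tpl) == pytest.approx(
                match_fixed_euclidean(X, t_s, tpl), abs=1e-9)

    def test_seeded_instance_against_naive_loop(self):
        rng = np.random.default_rng(4)
        tpl = random_template(rng, 5, 3)
        X = rng.normal(0, 1, (10, 3))
        expected = sum(
            mahalanobis_sq(X[2 + i], tpl.means[i], tpl.covariances[i])
            for i in range(5))
        assert match_fixed_ml(X, 2, tpl) == pytest.approx(expected, abs=1e-9)

    def test_window_overrun_rejected(self):
        tpl = identity_template(np.zeros((5, 2)))
        with pytest.raises(ValueError):
            match_fixed_ml(np.zeros((6, 2)), 2, tpl)


class TestUniformScaling:
    def test_direct_evaluation_of_normalized_minimum(self):
        # D_L(m=2)=4 and D_L(m=4)=6 -> normalized 2.0 vs 1.5 -> m=4
        t2 = identity_template(np.full((2, 1), 2.0))   # cost 2*(2^2)=8? no:
        # walk zeros: D_L = sum over i of mu_i^2
        t2 = identity_template(np.array([[np.sqrt(2.0)], [np.sqrt(2.0)]]))
        t4 = identity_template(np.array([[np.sqrt(1.5)]] * 4))
        X = np.zeros((6, 1))
        m, val = uniform_scaling_match(X, 0, [t2, t4])
        assert (m, val) == (4, pytest.approx(1.5))

    def test_exact_template_copy_wins_with_zero_distance(self):
        rng = np.random.default_rng(5)
        t3 = identity_template(rng.normal(0, 1, (3, 2)))
        t5 = identity_template(rng.normal(0, 1, (5, 2)))
        X = np.vstack([t5.means, rng.normal(0, 1, (2, 2))])
        m, val = uniform_scaling_match(X, 0, [t3, t5])
        assert (m, val) == (5, 0.0)

    def test_single_scale_bank(self):
        tpl = identity_template(np.zeros((3, 2)))
        m, _ = uniform_scaling_match(np.zeros((4, 2)), 0, [tpl])
        assert m == 3

    def test_no_fitting_scale_raises(self):
        tpl = identity_template(np.zeros((5, 2)))
        with pytest.raises(NoMatchError):
            uniform_scaling_match(np.zeros((6, 2)), 4, [tpl])

    def test_upper_bounds_every_fixed_scale(self):
        rng = np.random.default_rng(6)
        templates = [random_template(rng, m, 3) for m in (4, 5, 6)]
        X = rng.normal(0, 1, (15, 3))
        _, best = uniform_scaling_match(X, 2, templates)
        for tpl in templates:
            assert best <= match_fixed_ml(X, 2, tpl) / tpl.m + 1e-12


class TestDtw:
    def test_exact_copy_gives_zero_and_diagonal_path(self):
        rng = np.random.default_rng(7)
        tpl = identity_template(rng.normal(0, 1, (6, 2)))
        res = dtw_ml(tpl.means.copy(), tpl)
        assert res.distance == pytest.approx(0.0, abs=1e-18)
        assert res.path.pairs == tuple((i, i) for i in range(6))

    def test_small_instance_equals_path_enumeration(self):
        # v=3, m=2, 1-D means [0, 1], unit variances
        tpl = identity_template(np.array([[0.0], [1.0]]))
        X = np.array([[0.0], [0.5], [1.0]])
        C = cost_matrix(X, tpl)
        brute = min(sum(C[t, i] for t, i in p) for p in enumerate_paths(3, 2))
        res = dtw_ml(X, tpl)
        assert res.distance == pytest.approx(brute)
        assert len(list(enumerate_paths(3, 2))) == 5

    @pytest.mark.parametrize("seed", range(10))
    def test_random_instances_match_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        v, m = int(rng.integers(1, 7)), int(rng.integers(1, 7))
        tpl = random_template(rng, m, 2)
        X = rng.normal(0, 1, (v, 2))
        C = cost_matrix(X, tpl)
        brute = min(sum(C[t, i] for t, i in p)
                    for p in enumerate_paths(v, m))
        res = dtw_ml(X, tpl)
        assert res.distance == pytest.approx(brute)
        res.path.validate(m)
        assert res.distance >= 0.0

    def test_dtw_never_exceeds_fixed_length_match(self):
        rng = np.random.default_rng(8)
        tpl = random_template(rng, 6, 3)
        X = rng.normal(0, 1, (6, 3))
        assert dtw_ml(X, tpl).distance <= match_fixed_ml(X, 0, tpl) + 1e-9


class TestSdtw:
    def test_recovers_embedded_exact_span(self):
        rng = np.random.default_rng(9)
        tpl = identity_template(rng.normal(0, 1, (5, 2)))
        noise = rng.normal(20.0, 1.0, (4, 2))     # far from the template
        X = np.vstack([noise, tpl.means, noise])
        res = sdtw_ml(X, tpl)
        assert (res.t_s, res.t_e) == (4, 8)
        assert res.distance == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_bruteforce_subsequence_minimum(self, seed):
        rng = np.random.default_rng(200 + seed)
        n, m = int(rng.integers(4, 40)), int(rng.integers(2, 11))
        tpl = random_template(rng, m, 2)
        X = rng.normal(0, 1, (n, 2))
        brute = min(dtw_ml(X[ts:te + 1], tpl).distance
                    for ts in range(n) for te in range(ts, n))
        res = sdtw_ml(X, tpl)
        assert res.distance == pytest.approx(brute)
        res.path.validate(m)

    def test_appending_frames_never_increases_distance(self):
        rng = np.random.default_rng(10)
        tpl = random_template(rng, 5, 2)
        X = rng.normal(0, 1, (30, 2))
        prev = np.inf
        for n in range(6, 31, 6):
            d = sdtw_ml(X[:n], tpl).distance
            assert d <= prev + 1e-12
            prev = d


class TestSswm:
    def test_matches_oracle_on_seeded_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n, d = int(rng.integers(12, 40)), int(rng.integers(1, 4))
            templates = [random_template(rng, m, d) for m in range(6, 9)]
            X = rng.normal(0, 1, (n, d))
            a, b = sswm(X, templates), swm_oracle(X, templates)
            assert a.distance == pytest.approx(b.distance)
            assert (a.t_s, a.t_e, a.m_star) == (b.t_s, b.t_e, b.m_star)

    def test_exact_means_walk_full_span(self):
        rng = np.random.default_rng(12)
        tpl = identity_template(rng.normal(0, 1, (6, 2)))
        res = sswm(tpl.means.copy(), [tpl])
        assert (res.t_s, res.t_e) == (0, 5)
        assert res.distance == pytest.approx(0.0, abs=1e-15)

    def test_oracle_tie_break_prefers_earliest_span(self):
        tpl = identity_template(np.array([[1.0], [2.0]]))
        X = np.array([[1.0], [2.0], [5.0], [1.0], [2.0]])
        res = swm_oracle(X, [tpl])
        assert (res.t_s, res.t_e) == (0, 1)

    def test_cell_counts_linear_vs_cubic(self):
        rng = np.random.default_rng(13)
        d = 2
        templates = [random_template(rng, m, d) for m in (4, 5)]
        counts = {}
        for n in (20, 40):
            X = rng.normal(0, 1, (n, d))
            counts[n] = (sswm(X, templates).cells,
                         swm_oracle(X, templates).cells)
        sswm_ratio = counts[40][0] / counts[20][0]
        oracle_ratio = counts[40][1] / counts[20][1]
        assert sswm_ratio == pytest.approx(2.0, rel=0.05)
        assert oracle_ratio > 6.5          # cubic: -> 8x asymptotically

    def test_empty_bank_rejected(self):
        with pytest.raises(NoMatchError):
            sswm(np.zeros((5, 2)), [])


class TestWarpingPath:
    def test_invariant_violations_detected(self):
        with pytest.raises(ValueError):
            WarpingPath(((0, 0), (2, 1))).validate(2)     # bad step
        with pytest.raises(ValueError):
            WarpingPath(((0, 1), (1, 2))).validate(3)     # bad start
        WarpingPath(((0, 0), (1, 1), (1, 2))).validate(3)  # valid
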