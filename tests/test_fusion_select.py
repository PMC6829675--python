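"""Overlap filtering, jackknife structural features, the k-support norm and
its proximal operator, and the fusion fit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from connfuse.fusion_select import (
    EmptySelectionError,
    build_design,
    default_k,
    filter_cutoff,
    filter_features,
    fit_fusion,
    ksupport_dual_norm,
    ksupport_norm,
    ksupport_prox,
    ksupport_split,
    subject_structural_features,
)

finite_vectors = st.lists(
    st.floats(-10, 10, allow_nan=False, allow_infinity=False), min_size=2, max_size=30
).map(np.array)


class TestFilterCutoff:
    def test_cutoff_counts_entries_at_or_above_mean(self):
        assert filter_cutoff(np.array([0.9, 0.5, 0.4, 0.2])) == 2

    def test_all_equal_keeps_everything(self):
        assert filter_cutoff(np.full(4005, 0.3)) == 4005

    def test_selected_is_ordered_intersection_of_top_lists(self, rng):
        n = 60
        ms_a = rng.uniform(-1, 1, 55)
        ms_b = rng.uniform(-1, 1, 55)
        feats = rng.standard_normal((n, 55))
        labels = np.where(rng.random(n) < 0.5, 1, -1)
        res = filter_features(ms_a, ms_b, feats, labels)
        c = res.cutoff_c
        expected = np.intersect1d(res.structural_rank[:c], res.functional_rank[:c])
        assert np.array_equal(res.selected, expected)
        assert np.all(np.diff(res.selected) > 0)

    def test_empty_overlap_raises(self):
        # structural top-1 and functional top-1 disagree
        ms_a = np.array([0.0, 0.0, 10.0])
        ms_b = np.zeros(3)
        feats = np.vstack([np.eye(3)] * 8)
        labels = np.array(([1] * 3 + [-1] * 3) * 4)
        feats = feats + np.random.default_rng(0).standard_normal(feats.shape) * 1e-3
        feats[labels > 0, 0] += 5.0  # functional signal on edge 0 only
        with pytest.raises(EmptySelectionError):
            filter_features(ms_a, ms_b, feats, labels)


class TestJackknifeStructuralFeatures:
    def test_matches_naive_leave_one_out(self, rng):
        v = rng.standard_normal((14, 8))
        groups = np.array([1] * 8 + [-1] * 6)
        got = subject_structural_features(v, groups)
        rows, cols = np.tril_indices(8, -1)
        for g in (1, -1):
            sel = np.flatnonzero(groups == g)
            sub = v[sel]
            n = sel.size
            r_full = np.corrcoef(sub, rowvar=False)[rows, cols]
            for pos, i in enumerate(sel):
                r_loo = np.corrcoef(np.delete(sub, pos, 0), rowvar=False)[rows, cols]
                assert np.allclose(got[i], n * r_full - (n - 1) * r_loo, atol=1e-10)

    def test_stable_profiles_cluster_near_group_value(self, rng):
        base = rng.standard_normal((1, 6))
        v = np.tile(base, (30, 1)) + rng.standard_normal((30, 6)) * 1e-2
        shared = rng.standard_normal(30)
        v[:, 0] += shared
        v[:, 1] += shared  # strong common edge
        groups = np.ones(30)
        m = subject_structural_features(v, groups)
        r_g = np.corrcoef(v, rowvar=False)[1, 0]
        pos = 0  # edge (1, 0) is the first lower-triangle position
        assert np.abs(m[:, pos] - r_g).max() < 0.35
        assert m[:, pos].mean() == pytest.approx(
            30 * r_g - 29 * np.mean(
                [np.corrcoef(np.delete(v, i, 0), rowvar=False)[1, 0] for i in range(30)]
            ),
            abs=1e-10,
        )

    def test_outlier_subject_has_most_extreme_pseudo_value(self, rng):
        v = rng.standard_normal((20, 5)) * 0.3
        v[7, 0] = 8.0
        v[7, 1] = 8.0  # one subject inflates edge (1, 0)
        m = subject_structural_features(v, np.ones(20))
        assert np.abs(m[:, 0]).argmax() == 7

    def test_small_group_rejected(self, rng):
        with pytest.raises(ValueError, match="fewer than 5"):
            subject_structural_features(rng.standard_normal((8, 4)),
                                        np.array([1] * 4 + [-1] * 4))


class TestKSupportSplit:
    def test_k_equal_large_entries_give_r_zero(self):
        p = np.array([2.0, 2.0, 2.0, 0.0, 0.0])
        assert ksupport_split(p, 3) == 0

    def test_all_equal_with_k_equal_d_boundary_is_handled(self):
        # fully tied vector at k = d: every r is norm-equivalent (the left
        # comparison uses the +inf sentinel at r = k-1); the returned r must
        # be valid and the norm must equal the Euclidean norm exactly
        p = np.full(6, 1.3)
        r = ksupport_split(p, 6)
        assert 0 <= r <= 5
        assert ksupport_norm(p, 6) == pytest.approx(np.linalg.norm(p), abs=1e-12)

    def test_single_nonzero_support(self):
        p = np.array([4.0, 0.0, 0.0])
        for k in (1, 2, 3):
            assert ksupport_norm(p, k) == pytest.approx(4.0)

    @given(w=finite_vectors, frac=st.floats(0.01, 1.0))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_split_satisfies_its_defining_inequalities(self, w, frac):
        p = np.sort(np.abs(w))[::-1]
        if p[0] == 0:
            return
        d = p.size
        k = max(1, min(d, int(round(frac * d))))
        r = ksupport_split(p, k)
        tail = p[k - r - 1 :].sum() / (r + 1)
        left = p[k - r - 2] if k - r - 1 >= 1 else np.inf
        assert left > tail - 1e-12
        assert tail >= p[k - r - 1] - 1e-12


class TestKSupportNorm:
    def test_k1_is_l1_and_kd_is_l2(self, rng):
        for _ in range(100):
            w = rng.standard_normal(rng.integers(2, 40))
            assert ksupport_norm(w, 1) == pytest.approx(np.abs(w).sum(), abs=1e-10)
            assert ksupport_norm(w, w.size) == pytest.approx(
                np.linalg.norm(w), abs=1e-10
            )

    def test_zero_vector(self):
        assert ksupport_norm(np.zeros(7), 3) == 0.0

    @given(w=finite_vectors, alpha=st.floats(-4, 4, allow_nan=False))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_absolute_homogeneity(self, w, alpha):
        k = max(1, w.size // 2)
        assert ksupport_norm(alpha * w, k) == pytest.approx(
            abs(alpha) * ksupport_norm(w, k), rel=1e-9, abs=1e-9
        )

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_triangle_inequality(self, seed):
        r = np.random.default_rng(seed)
        d = int(r.integers(2, 25))
        k = int(r.integers(1, d + 1))
        a, b = r.standard_normal(d), r.standard_normal(d)
        assert ksupport_norm(a + b, k) <= (
            ksupport_norm(a, k) + ksupport_norm(b, k) + 1e-9
        )

    def test_norm_non_increasing_in_k(self, rng):
        for _ in range(20):
            w = rng.standard_normal(15)
            values = [ksupport_norm(w, k) for k in range(1, 16)]
            assert np.all(np.diff(values) <= 1e-12)

    def test_dual_norm_is_topk_euclidean(self, rng):
        u = rng.standard_normal(9)
        top = np.sort(np.abs(u))[::-1][:4]
        assert ksupport_dual_norm(u, 4) == pytest.approx(np.linalg.norm(top))


class TestKSupportProx:
    def test_zero_threshold_is_identity(self, rng):
        v = rng.standard_normal(12)
        assert np.array_equal(ksupport_prox(v, 0.0, 3), v)

    def test_zero_vector_stays_zero(self):
        assert np.array_equal(ksupport_prox(np.zeros(5), 1.0, 2), np.zeros(5))

    def test_k1_equals_soft_thresholding(self, rng):
        for _ in range(25):
            v = rng.standard_normal(15) * 3
            th = rng.uniform(0.1, 2.0)
            expected = np.sign(v) * np.maximum(np.abs(v) - th, 0.0)
            assert np.allclose(ksupport_prox(v, th, 1), expected, atol=1e-9)

    def test_kd_equals_euclidean_shrinkage(self, rng):
        for _ in range(25):
            v = rng.standard_normal(15) * 3
            th = rng.uniform(0.1, 2.0)
            nv = np.linalg.norm(v)
            expected = v * max(1 - th / nv, 0.0)
            assert np.allclose(ksupport_prox(v, th, 15), expected, atol=1e-9)

    def test_preserves_signs_and_magnitude_order(self, rng):
        v = rng.standard_normal(20)
        w = ksupport_prox(v, 0.8, 5)
        nz = w != 0
        assert np.all(np.sign(w[nz]) == np.sign(v[nz]))
        order = np.argsort(-np.abs(v))
        assert np.all(np.diff(np.abs(w[order])) <= 1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_no_descent_direction_at_the_prox_point(self, seed):
        r = np.random.default_rng(seed)
        d = int(r.integers(3, 20))
        k = int(r.integers(1, d + 1))
        v = r.standard_normal(d) * 2
        th = float(r.uniform(0.05, 3.0))
        w = ksupport_prox(v, th, k)

        def objective(x):
            return 0.5 * np.sum((x - v) ** 2) + th * ksupport_norm(x, k)

        base = objective(w)
        for scale in (1e-3, 1e-5):
            for _ in range(30):
                assert objective(w + r.standard_normal(d) * scale) >= base - 1e-10


class TestFitFusion:
    def _design(self, rng, n=40, d=12, m_noise=0.1):
        x = rng.standard_normal((n, d))
        m = x + rng.standard_normal((n, d)) * m_noise
        y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        return build_design(x, m, y, np.arange(d))

    def test_unregularized_limit_matches_least_squares(self, rng):
        design = self._design(rng, n=50, d=8)
        fit = fit_fusion(design, 0.0, 0.0, k=4, tol=1e-14, max_iter=50_000)
        w_ls, *_ = np.linalg.lstsq(design.x, design.y, rcond=None)
        assert np.abs(fit.w - w_ls).max() < 1e-6

    def test_objective_trace_is_monotone(self, rng):
        design = self._design(rng)
        fit = fit_fusion(design, 2.0, 1.0, k=3)
        assert np.all(np.diff(fit.objective_trace) <= 1e-10)
        assert fit.converged

    def test_high_distance_features_shrink_monotonically_with_lambda2(self, rng):
        design = self._design(rng, n=60, d=10, m_noise=0.0)
        # make one feature disagree strongly across modalities
        design.m[:, 4] = -design.x[:, 4] * 3
        design.d_weights = ((design.x - design.m) ** 2).sum(axis=0)
        mags = []
        for lam2 in (0.0, 0.5, 2.0, 8.0):
            fit = fit_fusion(design, 0.0, lam2, k=3)
            mags.append(abs(fit.w[4]))
        assert np.all(np.diff(mags) <= 1e-9)
        assert mags[-1] < mags[0]

    def test_matches_sklearn_lasso_objective_at_k1(self, rng):
        from sklearn.linear_model import Lasso

        design = self._design(rng, n=60, d=15)
        lam1 = 3.0
        fit = fit_fusion(design, lam1, 0.0, k=1, tol=1e-12, max_iter=100_000)
        n = design.x.shape[0]
        ref = Lasso(alpha=lam1 / (2 * n), fit_intercept=False, tol=1e-12,
                    max_iter=200_000)
        ref.fit(design.x, design.y)

        def objective(w):
            return float(
                np.sum((design.x @ w - design.y) ** 2) + lam1 * np.abs(w).sum()
            )

        assert objective(fit.w) == pytest.approx(objective(ref.coef_), abs=1e-6)

    def test_sparse_support_recovery(self, rng):
        n, d = 150, 100
        x = rng.standard_normal((n, d))
        true_w = np.zeros(d)
        support = rng.choice(d, 5, replace=False)
        true_w[support] = rng.choice([-1.0, 1.0], 5) * rng.uniform(0.8, 1.5, 5)
        y = x @ true_w + rng.standard_normal(n) * 0.1
        design = build_design(x, x.copy(), y, np.arange(d))
        fit = fit_fusion(design, 30.0, 0.0, k=5, tol=1e-10, max_iter=20_000)
        found = set(np.flatnonzero(np.abs(fit.w) > 1e-6).tolist())
        tp = len(found & set(support.tolist()))
        precision = tp / max(len(found), 1)
        recall = tp / 5
        f1 = 2 * precision * recall / max(precision + recall, 1e-12)
        assert f1 >= 0.8

    def test_final_iterate_is_a_prox_gradient_fixed_point(self, rng):
        design = self._design(rng, n=45, d=9)
        fit = fit_fusion(design, 1.5, 0.7, k=3, tol=1e-12, max_iter=100_000)
        dw = design.d_weights
        lip = 2.0 * (design.x_spectral_norm**2 + 0.7 * dw.max())
        grad = 2.0 * design.x.T @ (design.x @ fit.w - design.y) + 2 * 0.7 * dw * fit.w
        step = 1.0 / lip
        w_next = ksupport_prox(fit.w - step * grad, 1.5 * step, 3)
        assert np.abs(w_next - fit.w).max() < 1e-5

    def test_constant_intermodality_mode_is_a_noop_penalty(self, rng):
        design = self._design(rng)
        a = fit_fusion(design, 1.0, 5.0, k=3, tol=1e-12, intermodality="constant")
        b = fit_fusion(design, 1.0, 0.0, k=3, tol=1e-12, intermodality="constant")
        assert np.allclose(a.w, b.w, atol=1e-6)
        # reported objective carries the constant distance term
        assert a.objective_trace[-1] == pytest.approx(
            b.objective_trace[-1] + 5.0 * design.d_weights.sum(), rel=1e-6
        )

    def test_default_k_rule(self):
        assert default_k(700) == 70
        assert default_k(3) == 1
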