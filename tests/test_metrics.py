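"""Distribution distances, centers and repulsion matrices against oracles."""

import numpy as np
import pytest

from edpc import (
    DomainPair,
    class_centers,
    empirical_kernel_map,
    mmd_sq,
    one_center_bound,
    pc_distance,
    repulsion_matrix,
)


class TestEmpiricalKernelMap:
    def test_single_point_self_similarity(self):
        p = np.array([[1.0], [2.0]])
        assert empirical_kernel_map(p, p, 1.0) == pytest.approx(1.0)

    def test_gaussian_closed_form_at_sigma_sqrt2(self):
        sigma = 0.7
        a = np.zeros((3, 1))
        b = np.zeros((3, 1))
        b[0] = sigma * np.sqrt(2.0)
        K = empirical_kernel_map(np.hstack([a, b]), np.hstack([a, b]), sigma)
        assert K[0, 1] == pytest.approx(np.exp(-1.0), abs=1e-12)
        assert K[1, 0] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        ref, X = rng.normal(size=(4, 4)), rng.normal(size=(4, 3))
        sigma = 1.3
        K = empirical_kernel_map(ref, X, sigma)
        for i in range(4):
            for j in range(3):
                expect = np.exp(
                    -np.sum((ref[:, i] - X[:, j]) ** 2) / (2 * sigma**2)
                )
                assert K[i, j] == pytest.approx(expect, abs=1e-12)

    def test_entries_bounded_and_self_diagonal_one(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 10))
        K = empirical_kernel_map(X, X, 2.0)
        assert np.all(K > 0) and np.all(K <= 1)
        assert np.allclose(np.diag(K), 1.0)

    @pytest.mark.parametrize("sigma", [0.0, -1.0])
    def test_nonpositive_sigma_rejected(self, sigma):
        X = np.ones((2, 2))
        with pytest.raises(ValueError):
            empirical_kernel_map(X, X, sigma)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            empirical_kernel_map(np.ones((2, 3)), np.ones((3, 3)), 1.0)


class TestMMD:
    def test_identical_multisets_give_zero(self):
        X = np.random.default_rng(0).normal(size=(3, 7))
        assert mmd_sq(X, X[:, ::-1]) == pytest.approx(0.0, abs=1e-15)

    def test_singletons_give_squared_distance(self):
        u, v = np.array([[1.0], [0.0]]), np.array([[4.0], [4.0]])
        assert mmd_sq(u, v) == pytest.approx(25.0)

    def test_matches_mean_difference_oracle(self):
        rng = np.random.default_rng(11)
        Zs, Zt = rng.normal(size=(4, 10)), rng.normal(size=(4, 10))
        diff = Zs.mean(axis=1) - Zt.mean(axis=1)
        assert mmd_sq(Zs, Zt) == pytest.approx(float(diff @ diff), abs=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            mmd_sq(np.empty((3, 0)), np.ones((3, 2)))


class TestOneCenterBound:
    def test_coincident_points_give_zero(self):
        Z = np.ones((2, 4))
        assert one_center_bound(Z, Z, 0.5) == pytest.approx(0.0, abs=1e-15)

    def test_two_point_hand_expansion(self):
        # n = m = 1, delta = 0.5: each point sits ||u - v||/2 from the center
        u = np.array([[0.0], [0.0]])
        v = np.array([[2.0], [0.0]])
        assert one_center_bound(u, v, 0.5) == pytest.approx(2.0)  # = ||u-v||^2/2

    def test_matches_explicit_sum_oracle(self):
        rng = np.random.default_rng(2)
        Zs, Zt = rng.normal(size=(3, 8)), rng.normal(size=(3, 8))
        delta = 0.3
        mu = delta * Zs.mean(axis=1) + (1 - delta) * Zt.mean(axis=1)
        expect = sum(
            np.sum((Zs[:, i] - mu) ** 2) / 64 for i in range(8)
        ) + sum(np.sum((Zt[:, j] - mu) ** 2) / 64 for j in range(8))
        assert one_center_bound(Zs, Zt, delta) == pytest.approx(expect, abs=1e-12)

    def test_delta_out_of_range_rejected(self):
        Z = np.ones((2, 2))
        with pytest.raises(ValueError):
            one_center_bound(Z, Z, 1.5)


class TestPCDistance:
    def test_zero_weights_give_zero(self):
        Z = np.random.default_rng(0).normal(size=(3, 5))
        assert pc_distance(Z, np.zeros(5), np.zeros(3)) == 0.0

    def test_sqrt_varsigma_weights_recover_one_center_bound(self):
        rng = np.random.default_rng(4)
        Zs, Zt = rng.normal(size=(3, 6)), rng.normal(size=(3, 4))
        mu = 0.5 * Zs.mean(axis=1) + 0.5 * Zt.mean(axis=1)
        lam = np.concatenate([np.full(6, 1 / 6), np.full(4, 1 / 4)])
        assert pc_distance(np.hstack([Zs, Zt]), lam, mu) == pytest.approx(
            one_center_bound(Zs, Zt, 0.5), abs=1e-12
        )

    def test_matches_explicit_loop_oracle(self):
        rng = np.random.default_rng(8)
        Z = rng.normal(size=(4, 9))
        lam = rng.uniform(size=9)
        c = rng.normal(size=4)
        expect = sum(lam[k] ** 2 * np.sum((Z[:, k] - c) ** 2) for k in range(9))
        assert pc_distance(Z, lam, c) == pytest.approx(expect, abs=1e-12)

    def test_weight_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pc_distance(np.ones((2, 2)), np.array([0.5, 1.5]), np.zeros(2))

    def test_monotone_in_each_weight(self):
        rng = np.random.default_rng(9)
        Z = rng.normal(size=(3, 6))
        c = rng.normal(size=3)
        lam = rng.uniform(0.1, 0.8, size=6)
        base = pc_distance(Z, lam, c)
        for k in range(6):
            bumped = lam.copy()
            bumped[k] = min(1.0, bumped[k] + 0.1)
            assert pc_distance(Z, bumped, c) >= base


def test_pc_distance_upper_bounds_mmd_over_stated_weight_range():
    """With memberships above 1/min(n,m), the possibilistic distance to the
    blended center dominates the squared MMD (50 random instances)."""
    rng = np.random.default_rng(123)
    for _ in range(50):
        d = int(rng.choice([2, 5, 20]))
        n, m = int(rng.choice([5, 50])), int(rng.choice([5, 50]))
        Zs, Zt = rng.normal(size=(d, n)), rng.normal(size=(d, m))
        lam = rng.uniform(1.0 / min(n, m), 1.0, size=n + m)
        mu = 0.5 * Zs.mean(axis=1) + 0.5 * Zt.mean(axis=1)
        assert mmd_sq(Zs, Zt) <= pc_distance(np.hstack([Zs, Zt]), lam, mu)


def _random_pair(rng, d=4, C=3, n=12, m=10):
    Xs = rng.normal(size=(d, n))
    labels = np.concatenate([np.arange(1, C + 1), rng.integers(1, C + 1, n - C)])
    Ys = np.zeros((n, C))
    Ys[np.arange(n), labels - 1] = 1.0
    Xt = rng.normal(size=(d, m))
    return DomainPair(Xs=Xs, Ys=Ys, Xt=Xt)


class TestClassCenters:
    def test_delta_one_gives_pure_source_means(self):
        rng = np.random.default_rng(1)
        pair = _random_pair(rng)
        tl = np.concatenate([np.arange(1, 4), rng.integers(1, 4, 7)])
        cc = class_centers(pair, tl, delta=1.0)
        for c in range(1, 4):
            expect = pair.Xs[:, pair.source_labels == c].mean(axis=1)
            np.testing.assert_allclose(cc.mu[:, c], expect, atol=1e-12)

    def test_delta_half_is_midpoint_of_side_means(self):
        rng = np.random.default_rng(2)
        pair = _random_pair(rng)
        tl = np.concatenate([np.arange(1, 4), rng.integers(1, 4, 7)])
        cc = class_centers(pair, tl, delta=0.5)
        a = pair.Xs[:, pair.source_labels == 1].mean(axis=1)
        b = pair.Xt[:, tl == 1].mean(axis=1)
        np.testing.assert_allclose(cc.mu[:, 1], (a + b) / 2, atol=1e-12)

    def test_matches_group_by_mean_oracle(self):
        rng = np.random.default_rng(3)
        pair = _random_pair(rng)
        tl = np.concatenate([np.arange(1, 4), rng.integers(1, 4, 7)])
        delta = 0.6
        cc = class_centers(pair, tl, delta=delta)
        # column 0: blended global means
        expect0 = delta * pair.Xs.mean(axis=1) + (1 - delta) * pair.Xt.mean(axis=1)
        np.testing.assert_allclose(cc.mu[:, 0], expect0, atol=1e-12)
        for c in range(1, 4):
            ms = pair.Xs[:, pair.source_labels == c].mean(axis=1)
            mt = pair.Xt[:, tl == c].mean(axis=1)
            np.testing.assert_allclose(
                cc.mu[:, c], delta * ms + (1 - delta) * mt, atol=1e-12
            )

    def test_empty_target_class_falls_back_to_source_mean(self):
        rng = np.random.default_rng(4)
        pair = _random_pair(rng)
        tl = np.full(10, 1)  # classes 2,3 empty on the target side
        cc = class_centers(pair, tl, delta=0.5)
        for c in (2, 3):
            expect = pair.Xs[:, pair.source_labels == c].mean(axis=1)
            np.testing.assert_allclose(cc.mu[:, c], expect, atol=1e-12)

    def test_invalid_target_label_rejected(self):
        pair = _random_pair(np.random.default_rng(5))
        with pytest.raises(ValueError):
            class_centers(pair, np.full(10, 9))

    def test_membership_weights_exclude_downweighted_samples(self):
        rng = np.random.default_rng(6)
        pair = _random_pair(rng)
        tl = np.concatenate([np.arange(1, 4), rng.integers(1, 4, 7)])
        N = pair.N
        ones = np.ones(N)
        plain = class_centers(pair, tl, delta=0.5)
        same = class_centers(pair, tl, delta=0.5, sample_weights=(ones, ones))
        np.testing.assert_allclose(plain.mu, same.mu, atol=1e-12)
        # zero out one source sample of class 1: its coordinates vanish
        wc = ones.copy()
        first_c1 = int(np.argmax(pair.source_labels == 1))
        wc[first_c1] = 1e-13 * 0 + 0.0  # excluded entirely
        weighted = class_centers(pair, tl, delta=1.0, sample_weights=(ones, wc))
        keep = (pair.source_labels == 1) & (np.arange(pair.n) != first_c1)
        np.testing.assert_allclose(
            weighted.mu[:, 1], pair.Xs[:, keep].mean(axis=1), atol=1e-12
        )


class TestRepulsionMatrix:
    def test_per_class_rows_sum_to_zero(self):
        labels = np.array([1, 1, 2, 3, 3, 3, 2, 1])
        rep = repulsion_matrix(labels)
        for Mc in rep.per_class:
            np.testing.assert_allclose(Mc.sum(axis=1), 0.0, atol=1e-14)
        np.testing.assert_allclose(rep.Mrep, rep.Mrep.T, atol=1e-15)

    def test_two_class_complement_symmetry(self):
        labels = np.array([1, 2, 1, 2, 2])
        rep = repulsion_matrix(labels)
        np.testing.assert_allclose(rep.per_class[0], rep.per_class[1], atol=1e-14)
        np.testing.assert_allclose(rep.Mrep, 2 * rep.per_class[0], atol=1e-14)

    def test_quadratic_form_equals_squared_mean_gap(self):
        rng = np.random.default_rng(12)
        labels = np.concatenate([np.arange(1, 4), rng.integers(1, 4, 12)])
        X = rng.normal(size=(6, 15))
        P, _ = np.linalg.qr(rng.normal(size=(6, 3)))
        rep = repulsion_matrix(labels)
        for c, Mc in enumerate(rep.per_class, start=1):
            got = np.trace(P.T @ X @ Mc @ X.T @ P)
            Z = P.T @ X
            gap = Z[:, labels == c].mean(axis=1) - Z[:, labels != c].mean(axis=1)
            assert got == pytest.approx(float(gap @ gap), abs=1e-10)

    def test_quadratic_form_nonnegative(self):
        rng = np.random.default_rng(13)
        labels = rng.integers(1, 4, 30)
        X = rng.normal(size=(5, 30))
        rep = repulsion_matrix(labels)
        for _ in range(5):
            P, _ = np.linalg.qr(rng.normal(size=(5, 2)))
            assert np.trace(P.T @ X @ rep.Mrep @ X.T @ P) >= -1e-12

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            repulsion_matrix(np.array([1, 1, 3, 3]))  # class 2 missing
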