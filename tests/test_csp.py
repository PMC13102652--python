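"""Covariance estimation, the generalized eigenproblem, fusion, log-variance."""

import numpy as np
import pytest

from mcfanet import (
    EpochSet,
    apply_filterbank,
    class_covariances,
    fit_ovr_csp,
    fuse_virtual_channels,
    logvar_features,
    make_bands,
    solve_csp,
    trial_covariance,
)


def _random_pd(rng, n):
    A = rng.standard_normal((n, n))
    return A @ A.T + n * np.eye(n)


def _band_epochs(rng, n_trials=16, C=6, T=250, labels=None):
    ep = EpochSet(
        data=rng.standard_normal((n_trials, C, T)),
        labels=np.arange(n_trials) % 4 if labels is None else labels,
        fs=250.0,
        class_names=["a", "b", "c", "d"],
    )
    return apply_filterbank(ep, make_bands(8, 32, 4))


class TestTrialCovariance:
    def test_rank_one_hand_computed(self):
        X = np.array([[1.0, -1.0], [1.0, -1.0]])
        C = trial_covariance(X, ridge=0.0)
        np.testing.assert_allclose(C, np.ones((2, 2)), atol=1e-12)

    def test_constant_channel_stays_pd_via_ridge(self):
        X = np.vstack([np.ones(100), np.random.default_rng(0).standard_normal(100)])
        C = trial_covariance(X, ridge=1e-6)
        assert abs(C[0, 1]) < 1e-12
        assert np.all(np.linalg.eigvalsh(C) > 0)

    def test_matches_brute_force_oracle(self, rng):
        X = rng.standard_normal((3, 200))
        C = trial_covariance(X, ridge=0.0)
        Xc = X - X.mean(axis=1, keepdims=True)
        oracle = np.empty((3, 3))
        for i in range(3):
            for j in range(3):
                oracle[i, j] = sum(Xc[i, t] * Xc[j, t] for t in range(200)) / 200
        assert np.abs(C - oracle).max() <= 1e-10

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            trial_covariance(np.array([[np.nan, 1.0], [0.0, 1.0]]))


class TestClassCovariances:
    def test_identical_trials_give_equal_pairs(self, rng):
        be = _band_epochs(rng, n_trials=8)
        be.data[:] = be.data[0]
        pairs = class_covariances(be)
        for (k, f), (Sk, Sr) in pairs.items():
            np.testing.assert_allclose(Sk, Sr, rtol=1e-9)

    def test_rest_pool_is_mean_of_other_class_means(self, rng):
        be = _band_epochs(rng, n_trials=16)  # 4 per class, balanced
        pairs = class_covariances(be)
        means = {}
        for k in range(4):
            mask = be.labels == k
            means[k] = np.mean(
                [trial_covariance(be.data[i, 0]) for i in np.flatnonzero(mask)], axis=0)
        expected_rest0 = np.mean([means[k] for k in (1, 2, 3)], axis=0)
        np.testing.assert_allclose(pairs[(0, 0)][1], expected_rest0, rtol=1e-9)

    def test_trace_normalization_flag(self, rng):
        X = rng.standard_normal((4, 300)) * 5.0
        C = trial_covariance(X, ridge=0.0, trace_normalize=True)
        assert np.trace(C) == pytest.approx(1.0, abs=1e-12)

    def test_rest_pooling_modes_coincide_only_when_balanced(self, rng):
        balanced = _band_epochs(rng, n_trials=16)
        p_tr = class_covariances(balanced, rest_pooling="trials")
        p_cl = class_covariances(balanced, rest_pooling="classes")
        np.testing.assert_allclose(p_tr[(0, 0)][1], p_cl[(0, 0)][1], rtol=1e-9)
        lab = np.array([0, 0, 0, 0, 0, 0, 1, 1, 2, 2, 3, 3, 3, 3, 3, 3])
        skewed = _band_epochs(rng, n_trials=16, labels=lab)
        q_tr = class_covariances(skewed, rest_pooling="trials")
        q_cl = class_covariances(skewed, rest_pooling="classes")
        assert np.abs(q_tr[(1, 0)][1] - q_cl[(1, 0)][1]).max() > 1e-6

    def test_unknown_rest_pooling_rejected(self, rng):
        with pytest.raises(ValueError, match="rest_pooling"):
            class_covariances(_band_epochs(rng, n_trials=8), rest_pooling="mean")

    def test_pair_count_is_k_times_f(self, rng):
        assert len(class_covariances(_band_epochs(rng, n_trials=16))) == 4 * 6

    def test_class_with_one_trial_rejected(self, rng):
        be = _band_epochs(rng, n_trials=5, labels=np.array([0, 0, 1, 1, 2]))
        with pytest.raises(ValueError):
            class_covariances(be)


class TestSolveCsp:
    def test_diagonal_pair_closed_form(self):
        W, lam = solve_csp(np.diag([2.0, 1.0]), np.diag([1.0, 2.0]), m=1)
        np.testing.assert_allclose(lam, [2.0, 0.5], atol=1e-12)
        np.testing.assert_allclose(np.abs(W), np.eye(2), atol=1e-12)
        assert (W[np.argmax(np.abs(W), axis=0), [0, 1]] > 0).all()

    def test_equal_covariances_all_eigenvalues_one(self, rng):
        S = _random_pd(rng, 4)
        with pytest.warns(UserWarning, match="degenerate"):
            _W, lam = solve_csp(S, S, m=2)
        np.testing.assert_allclose(lam, 1.0, rtol=1e-8)

    def test_residual_and_monte_carlo_maximality(self, rng):
        Si, Sj = _random_pd(rng, 6), _random_pd(rng, 6)
        W, lam = solve_csp(Si, Sj, m=2)
        for col in range(4):
            w, l = W[:, col], lam[col]
            assert np.linalg.norm(Si @ w - l * Sj @ w) <= 1e-8 * np.linalg.norm(Si)
        # the top column maximizes the variance ratio over 1e5 random directions
        V = rng.standard_normal((6, 100_000))
        ratios = (V * (Si @ V)).sum(0) / (V * (Sj @ V)).sum(0)
        top = W[:, 0]
        top_ratio = (top @ Si @ top) / (top @ Sj @ top)
        assert top_ratio >= ratios.max()

    def test_too_many_pairs_rejected(self, rng):
        S = _random_pd(rng, 4)
        with pytest.raises(ValueError):
            solve_csp(S, _random_pd(rng, 4), m=3)


class TestOvrCsp:
    def test_channel_constraint_matches_montage(self, rng):
        be = _band_epochs(rng, n_trials=16, C=6)
        with pytest.raises(ValueError, match="channels"):
            fit_ovr_csp(be, m=4)  # 2m = 8 > 6 channels

    def test_shapes_and_layout(self, rng):
        be = _band_epochs(rng, n_trials=16, C=8)
        bank = fit_ovr_csp(be, m=1)
        assert bank.n_classes == 4 and bank.n_bands == 6
        assert all(W.shape == (8, 2) for row in bank.W for W in row)
        assert bank.eigenvalues.shape == (4, 6, 2)
        # layout: largest first, then smallest
        assert (bank.eigenvalues[:, :, 0] >= bank.eigenvalues[:, :, 1]).all()

    def test_deterministic_across_runs(self, rng):
        be = _band_epochs(rng, n_trials=16, C=8)
        b1, b2 = fit_ovr_csp(be, m=2), fit_ovr_csp(be, m=2)
        for r1, r2 in zip(b1.W, b2.W):
            for W1, W2 in zip(r1, r2):
                np.testing.assert_array_equal(W1, W2)

    def test_scale_invariance_of_filters(self, rng):
        be = _band_epochs(rng, n_trials=16, C=6)
        b1 = fit_ovr_csp(be, m=1)
        be.data = be.data * 7.5
        b2 = fit_ovr_csp(be, m=1)
        for r1, r2 in zip(b1.W, b2.W):
            for W1, W2 in zip(r1, r2):
                np.testing.assert_allclose(W1, W2, atol=1e-8)


class TestFusion:
    @pytest.mark.parametrize("m,expected_D", [(1, 48), (3, 144)])
    def test_fused_dimension(self, rng, m, expected_D):
        be = _band_epochs(rng, n_trials=16, C=8)
        vc = fuse_virtual_channels(be, fit_ovr_csp(be, m=m))
        assert vc.D == expected_D == 4 * 6 * 2 * m
        assert vc.data.shape == (16, expected_D, 250)

    def test_index_map_ordering_is_class_major(self, rng):
        be = _band_epochs(rng, n_trials=16, C=8)
        vc = fuse_virtual_channels(be, fit_ovr_csp(be, m=2))
        m2 = 4
        assert all(vc.index_map[d] == (0, 0, d) for d in range(m2))
        assert vc.index_map[m2] == (0, 1, 0)
        assert vc.index_map[6 * m2] == (1, 0, 0)

    def test_projection_values_match_direct_product(self, rng):
        be = _band_epochs(rng, n_trials=8, C=6)
        bank = fit_ovr_csp(be, m=1)
        vc = fuse_virtual_channels(be, bank)
        # virtual channels of trial 2, class 1, band 3
        d0 = 1 * 6 * 2 + 3 * 2
        direct = bank.W[1][3].T @ be.data[2, 3]
        np.testing.assert_allclose(vc.data[2, d0 : d0 + 2], direct, atol=1e-12)

    def test_band_mismatch_rejected(self, rng):
        be = _band_epochs(rng, n_trials=16, C=6)
        bank = fit_ovr_csp(be, m=1)
        be2 = _band_epochs(rng, n_trials=4, C=6)
        be2.data = be2.data[:, :3]
        be2.bands = be2.bands[:3]
        with pytest.raises(ValueError):
            fuse_virtual_channels(be2, bank)


class TestLogVar:
    def test_unit_variance_gives_zero_and_scaling_identity(self, rng):
        be = _band_epochs(rng, n_trials=8, C=6)
        vc = fuse_virtual_channels(be, fit_ovr_csp(be, m=1))
        f1 = logvar_features(vc)
        vc.data *= 3.0
        f2 = logvar_features(vc)
        np.testing.assert_allclose(f2 - f1, 2 * np.log(3.0), atol=1e-9)

    def test_matches_brute_force_variance_loop(self, rng):
        be = _band_epochs(rng, n_trials=8, C=6)
        vc = fuse_virtual_channels(be, fit_ovr_csp(be, m=1))
        feats = logvar_features(vc)
        for n in range(vc.n_trials):
            for d in range(0, vc.D, 17):
                assert abs(feats[n, d] - np.log(vc.data[n, d].var())) <= 1e-10

    def test_zero_variance_channel_floors_with_warning(self, rng):
        be = _band_epochs(rng, n_trials=8, C=6)
        vc = fuse_virtual_channels(be, fit_ovr_csp(be, m=1))
        vc.data[0, 0] = 5.0  # constant
        with pytest.warns(UserWarning, match="zero-variance"):
            feats = logvar_features(vc, eps=1e-12)
        assert feats[0, 0] == pytest.approx(np.log(1e-12))
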