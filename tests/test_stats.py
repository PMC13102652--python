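"""F1, paired statistics, importance maps, Welch features, embeddings."""

import numpy as np
import pytest

from mcfanet import (
    EpochSet,
    NetConfig,
    TrainConfig,
    build_mcfanet,
    export_embeddings,
    gradient_importance,
    macro_f1,
    make_bands,
    paired_stats,
    train_model,
    welch_bandpower_features,
)
from mcfanet.csp import VirtualChannelSet


class TestMacroF1:
    def test_perfect_predictions(self):
        per_class, macro = macro_f1([0, 1, 2, 3], [0, 1, 2, 3])
        assert macro == 1.0 and (per_class == 1.0).all()

    def test_binary_confusion_hand_computed(self):
        # confusion [[3,1],[1,3]]: precision = recall = 0.75 for both classes
        y_true = [0] * 4 + [1] * 4
        y_pred = [0, 0, 0, 1, 1, 1, 1, 0]
        per_class, macro = macro_f1(y_true, y_pred)
        np.testing.assert_allclose(per_class, [0.75, 0.75])
        assert macro == pytest.approx(0.75)

    def test_never_predicted_class_gets_zero(self):
        per_class, _ = macro_f1([0, 0, 1, 1], [0, 0, 0, 0])
        assert per_class[1] == 0.0

    def test_class_missing_from_truth_raises(self):
        with pytest.raises(ValueError, match="undefined"):
            macro_f1([0, 0, 1], [0, 2, 1])

    def test_micro_f1_equals_accuracy(self, rng):
        from sklearn.metrics import f1_score
        y_true = rng.integers(0, 4, 200)
        y_pred = rng.integers(0, 4, 200)
        micro = f1_score(y_true, y_pred, average="micro")
        assert micro == pytest.approx((y_true == y_pred).mean(), abs=1e-12)


class TestPairedStats:
    def test_closed_form_example(self):
        from scipy.stats import t as tdist
        res = paired_stats([2, 3, 4], [1, 1, 1])  # diffs [1, 2, 3]
        assert res.d == pytest.approx(2.0, abs=1e-12)
        assert res.t == pytest.approx(2 * np.sqrt(3), abs=1e-12)
        assert res.p == pytest.approx(2 * tdist.sf(2 * np.sqrt(3), 2), abs=1e-12)
        assert res.p == pytest.approx(0.0742, abs=2e-4)

    def test_antisymmetry(self, rng):
        a, b = rng.random(9), rng.random(9)
        r1, r2 = paired_stats(a, b), paired_stats(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.d == pytest.approx(-r2.d)
        assert r1.p == pytest.approx(r2.p)

    def test_identical_vectors_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            paired_stats([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_matches_scipy_ttest_rel(self, rng):
        from scipy.stats import ttest_rel
        a, b = rng.random(12), rng.random(12)
        res = paired_stats(a, b)
        ref = ttest_rel(a, b)
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_agrees_with_sign_permutation_null(self, rng):
        # on n = 9 subject vectors the t-based p matches a sign-flip
        # permutation p within Monte-Carlo error
        a = rng.normal(0.05, 0.1, 9)
        b = np.zeros(9)
        res = paired_stats(a, b)
        diffs = a - b
        flips = rng.integers(0, 2, size=(20000, 9)) * 2 - 1
        perm_t = (flips * diffs).mean(1) / ((flips * diffs).std(1, ddof=1) / 3)
        perm_p = float((np.abs(perm_t) >= abs(res.t)).mean())
        assert abs(perm_p - res.p) < 0.05


@pytest.fixture(scope="module")
def trained_setup():
    rng = np.random.default_rng(0)
    D, T, K = 24, 128, 4
    # an index map for K=4, F=6, one component per (class, band) -> D = 24
    index_map = [(k, f, 0) for k in range(4) for f in range(6)]
    X = rng.standard_normal((24, D, T)).astype(np.float32)
    y = rng.integers(0, K, 24)
    net = build_mcfanet(D, T, NetConfig(n_classes=K), seed=0)
    train_model(net, X, y, TrainConfig(epochs=2, seed=0))
    vc = VirtualChannelSet(data=X.astype(np.float64), index_map=index_map,
                           labels=y, fs=250.0)
    return net, vc


class TestGradientImportance:
    def test_normalization_and_shapes(self, trained_setup):
        net, vc = trained_setup
        imp = gradient_importance(net, vc)
        assert imp.band_percent.shape == (6,)
        assert imp.class_band_percent.shape == (4, 6)
        assert imp.band_percent.sum() == pytest.approx(100.0, abs=1e-6)
        assert imp.class_band_percent.sum() == pytest.approx(100.0, abs=1e-6)
        assert (imp.channel_scores >= 0).all()

    def test_gradients_match_finite_differences(self, trained_setup):
        net, vc = trained_setup
        X = vc.data.astype(np.float32)
        g = net.input_gradients(X[:1], vc.labels[:1])
        logit = lambda x: net.forward(  # noqa: E731
            x[None, None], training=False)[0, vc.labels[0]]
        rng = np.random.default_rng(5)
        for _ in range(4):
            d, t = rng.integers(X.shape[1]), rng.integers(X.shape[2])
            eps = 1e-2
            xp, xm = X[0].copy(), X[0].copy()
            xp[d, t] += eps
            xm[d, t] -= eps
            fd = (logit(xp) - logit(xm)) / (2 * eps)
            assert g[0, d, t] == pytest.approx(fd, abs=2e-3)

    def test_missing_index_map_rejected(self, trained_setup):
        import copy

        net, vc = trained_setup
        broken = copy.copy(vc)
        broken.index_map = []
        with pytest.raises(ValueError, match="index map"):
            gradient_importance(net, broken)


class TestWelchFeatures:
    def _epochs(self, data, fs=250.0):
        return EpochSet(data=data, labels=np.zeros(data.shape[0], dtype=int),
                        fs=fs, class_names=["x"])

    def test_feature_count_is_channels_times_bands(self, rng):
        ep = self._epochs(rng.standard_normal((3, 22, 1000)))
        feats = welch_bandpower_features(ep, make_bands(8, 32, 4))
        assert feats.shape == (3, 132)

    def test_sinusoid_power_concentrates_in_its_band(self):
        t = np.arange(1000) / 250.0
        x = np.sin(2 * np.pi * 10 * t)[None, None, :]
        feats = welch_bandpower_features(self._epochs(x), make_bands(8, 32, 4))
        assert feats[0, 0] >= 0.9 * feats[0].sum()

    def test_zero_signal_gives_zero_features(self):
        ep = self._epochs(np.zeros((2, 3, 500)))
        feats = welch_bandpower_features(ep, make_bands(8, 32, 4))
        assert np.array_equal(feats, np.zeros((2, 18)))

    def test_band_at_nyquist_rejected(self, rng):
        ep = self._epochs(rng.standard_normal((1, 2, 500)), fs=60.0)
        with pytest.raises(ValueError, match="Nyquist"):
            welch_bandpower_features(ep, make_bands(8, 32, 4))


class TestEmbeddings:
    def test_width_nonnegativity_and_determinism(self, rng):
        D, T = 12, 128
        net = build_mcfanet(D, T, NetConfig(n_classes=4), seed=1)
        X = rng.standard_normal((6, D, T))
        X[3] = X[0]  # duplicated trial
        vc = VirtualChannelSet(
            data=X, index_map=[(0, 0, d) for d in range(D)],
            labels=np.zeros(6, dtype=int), fs=250.0)
        E = export_embeddings(net, vc)
        assert E.shape == (6, 128)
        assert (E >= 0).all()
        np.testing.assert_array_equal(E[0], E[3])

    def test_nonstandard_width_warns_but_works(self, rng):
        net = build_mcfanet(8, 128, NetConfig(n_classes=4, hidden=64), seed=1)
        vc = VirtualChannelSet(
            data=rng.standard_normal((2, 8, 128)),
            index_map=[(0, 0, d) for d in range(8)],
            labels=np.zeros(2, dtype=int), fs=250.0)
        with pytest.warns(UserWarning, match="128"):
            E = export_embeddings(net, vc)
        assert E.shape == (2, 64)
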