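"""Backbone architecture contracts: shapes, attention, loss, determinism.

The fused execution path is additionally checked against the literal
layer-by-layer reference path (same parameters, same data).
"""

import numpy as np
import pytest

from mcfanet import NetConfig, build_mcfanet, count_parameters, cross_entropy_loss
from mcfanet.nn.layers import ChannelAttention
from mcfanet.nn.model import MCFANetBackbone


def _net(D=12, T=128, K=4, dropout=0.5, seed=0, hidden=128):
    return build_mcfanet(D, T, NetConfig(n_classes=K, dropout=dropout,
                                         hidden=hidden), seed=seed)


class TestArchitecture:
    def test_logit_shape_full_size(self, rng):
        net = _net(D=48, T=1000)
        x = rng.standard_normal((2, 1, 48, 1000)).astype(np.float32)
        assert net.forward(x, training=False).shape == (2, 4)

    def test_block1_emits_32_feature_maps(self, rng):
        net = _net(D=12, T=128)
        x = rng.standard_normal((3, 1, 12, 128)).astype(np.float32)
        out = net.block0.forward(x, training=False)
        assert out.shape == (3, 16, 12, 128)  # F1 temporal maps, T preserved
        out = net.layers[1].forward(out, training=False)
        out = net.layers[2].forward(out, training=False)
        assert out.shape == (3, 32, 1, 128)  # depthwise doubles to 2*F1

    def test_flatten_width_follows_floor_division(self):
        assert _net(D=48, T=1000).flat_width == 32 * 31  # 1000 -> 250 -> 31
        assert _net(D=12, T=500).flat_width == 32 * 15

    def test_block2_padding_preserves_pooled_length(self, rng):
        net = _net(D=8, T=256)
        x = rng.standard_normal((2, 1, 8, 256)).astype(np.float32)
        out = net.forward(x, training=False)
        assert out.shape == (2, 4)
        assert net.t_out == (256 // 4) // 8

    def test_too_short_trial_rejected(self):
        with pytest.raises(ValueError, match="temporal kernel"):
            _net(D=8, T=32)

    def test_inconsistent_depth_multiplier_rejected(self):
        with pytest.raises(ValueError):
            NetConfig(F1=16, depth_multiplier=2, F2=48)

    def test_softmax_rows_sum_to_one(self, rng):
        net = _net()
        x = rng.standard_normal((5, 12, 128)).astype(np.float32)
        p = net.predict_proba(x)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_eval_forward_is_deterministic(self, rng):
        net = _net()
        x = rng.standard_normal((4, 1, 12, 128)).astype(np.float32)
        a = net.forward(x, training=False)
        b = net.forward(x, training=False)
        np.testing.assert_array_equal(a, b)


class TestFusedEngineEquivalence:
    def test_training_forward_and_gradients_match_reference(self, rng):
        X = rng.standard_normal((6, 1, 10, 96)).astype(np.float32)
        y = rng.integers(0, 4, 6)
        outs, grads = [], []
        for engine in ("reference", "fused"):
            net = _net(D=10, T=96, dropout=0.0, seed=3)
            net.engine = engine
            aux = net.gather_aux(net.prepare_cache(X), np.arange(6))
            logits = net.forward(X, training=True, aux=aux)
            loss, dl = cross_entropy_loss(logits, y)
            net.zero_grad()
            net.backward(dl)
            outs.append(logits)
            grads.append([p.grad.copy() for p in net.params()])
        np.testing.assert_allclose(outs[0], outs[1], atol=1e-5)
        for ga, gb in zip(*grads):
            scale = max(np.abs(ga).max(), 1e-3)
            np.testing.assert_allclose(ga, gb, atol=2e-3 * scale)

    def test_eval_paths_agree(self, rng):
        net = _net(D=10, T=96, seed=3)
        x = rng.standard_normal((4, 1, 10, 96)).astype(np.float32)
        a = net.forward(x, training=False, engine="fused")
        b = net.forward(x, training=False, engine="reference")
        np.testing.assert_allclose(a, b, atol=1e-5)


class TestChannelAttention:
    def test_gates_strictly_inside_unit_interval(self, rng):
        att = ChannelAttention(32, np.random.default_rng(0))
        x = rng.standard_normal((5, 32, 1, 20)).astype(np.float32)
        att.forward(x, training=False)
        assert (att.gate > 0).all() and (att.gate < 1).all()

    def test_zero_input_gives_uniform_gates_and_zero_output(self):
        att = ChannelAttention(32, np.random.default_rng(0))
        x = np.zeros((2, 32, 1, 20), dtype=np.float32)
        out = att.forward(x, training=False)
        assert np.array_equal(out, np.zeros_like(x))
        # purely bias-driven: every trial sees the identical gate vector
        assert np.allclose(att.gate, att.gate[:1, :])

    def test_amplitude_perturbation_moves_the_gate(self, rng):
        att = ChannelAttention(32, np.random.default_rng(0))
        x = rng.standard_normal((1, 32, 1, 50)).astype(np.float32)
        g0 = att.gates(x, training=False).copy()
        x2 = x.copy()
        x2[:, 7] *= 2.0
        g1 = att.gates(x2, training=False)
        assert abs(g1[0, 7] - g0[0, 7]) > 1e-6  # its own statistics changed

    def test_wrong_channel_count_rejected(self, rng):
        att = ChannelAttention(32, np.random.default_rng(0))
        with pytest.raises(ValueError):
            att.forward(rng.standard_normal((1, 16, 1, 20)).astype(np.float32),
                        training=False)


class TestCrossEntropy:
    def test_uniform_logits_closed_form(self):
        loss, _ = cross_entropy_loss(np.zeros((3, 4)), np.array([0, 1, 2]))
        assert loss == pytest.approx(np.log(4.0), abs=1e-12)

    def test_confident_correct_logit_drives_loss_to_zero(self):
        logits = np.array([[30.0, 0.0, 0.0, 0.0]])
        loss, _ = cross_entropy_loss(logits, np.array([0]))
        assert loss < 1e-8

    def test_matches_hand_rolled_softmax_oracle(self, rng):
        logits = rng.standard_normal((8, 5))
        y = rng.integers(0, 5, 8)
        loss, _ = cross_entropy_loss(logits, y)
        expected = 0.0
        for i in range(8):
            p = np.exp(logits[i]) / np.exp(logits[i]).sum()
            expected -= np.log(p[y[i]]) / 8
        assert loss == pytest.approx(expected, abs=1e-8)

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy_loss(np.zeros((2, 4)), np.array([0, 4]))


class TestParameterCount:
    def test_count_is_deterministic_and_monotone_in_hidden(self):
        n1 = count_parameters(_net(D=48, T=1000))
        n2 = count_parameters(_net(D=48, T=1000))
        assert n1 == n2
        assert count_parameters(_net(D=48, T=1000, hidden=256)) > n1

    def test_count_matches_layerwise_closed_form(self):
        D, T, K, H = 48, 1000, 4, 128
        net = _net(D=D, T=T, K=K, hidden=H)
        t_out = (T // 4) // 8
        expected = (
            2  # input batch norm (scale, shift)
            + 64 * 16  # temporal conv kernels (no bias)
            + 2 * 16  # batch norm after temporal conv
            + 32 * D  # depthwise over virtual channels
            + 2 * 32
            + 32 * 16  # separable depthwise (1, 16)
            + 32 * 32  # pointwise
            + 2 * 32
            + (64 * 32 + 32) + (32 * 16 + 16) + (16 * 32 + 32)  # attention MLP
            + (32 * t_out) * H + H  # dense to hidden
            + 2 * H
            + H * K + K
        )
        assert count_parameters(net) == expected
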