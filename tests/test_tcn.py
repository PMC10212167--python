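"""Network primitives: dilated causal convolution, weight norm, dropout,
residual blocks, receptive field, model assembly."""

import numpy as np
import pytest

from tcncall.errors import (ConfigError, InvalidArgumentError,
                            InvalidStateError)
from tcncall.tcn import (FLOAT_ATOL, TCN, TCNConfig, build_model,
                         causal_dilated_conv, receptive_field, relu,
                         residual_block, softmax, spatial_dropout,
                         weight_norm_apply)


def brute_force_conv(x, f, d):
    """Direct double-loop evaluation: y[t] = sum_i f[i] * x[t - d*i]."""
    n, K = len(x), len(f)
    y = np.zeros(n)
    for t in range(n):
        for i in range(K):
            j = t - d * i
            if j >= 0:
                y[t] += f[i] * x[j]
    return y


class TestCausalDilatedConv:
    def test_worked_examples(self):
        np.testing.assert_allclose(
            causal_dilated_conv([1, 2, 3, 4], [1, 1], 1), [1, 3, 5, 7])
        np.testing.assert_allclose(
            causal_dilated_conv([1, 2, 3, 4], [1, 1], 2), [1, 2, 4, 6])

    def test_single_tap_filter_scales(self):
        x = np.arange(6.0)
        for d in (1, 3, 7):
            np.testing.assert_allclose(causal_dilated_conv(x, [2.5], d), 2.5 * x)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(1, 65))
            K = int(rng.integers(1, 9))
            d = int(rng.integers(1, 9))
            x = rng.normal(size=n)
            f = rng.normal(size=K)
            np.testing.assert_allclose(causal_dilated_conv(x, f, d),
                                       brute_force_conv(x, f, d),
                                       atol=FLOAT_ATOL)

    def test_d1_equals_standard_causal_convolution(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        f = rng.normal(size=5)
        # standard causal convolution = full convolution truncated to n
        std = np.convolve(x, f)[: len(x)]
        np.testing.assert_allclose(causal_dilated_conv(x, f, 1), std,
                                   atol=FLOAT_ATOL)

    def test_no_future_leakage(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        f = rng.normal(size=4)
        y = causal_dilated_conv(x, f, 2)
        x2 = x.copy()
        x2[20:] += 5.0
        y2 = causal_dilated_conv(x2, f, 2)
        np.testing.assert_allclose(y[:20], y2[:20], atol=FLOAT_ATOL)

    def test_invalid_dilation_rejected(self):
        with pytest.raises(InvalidArgumentError):
            causal_dilated_conv([1.0], [1.0], 0)


class TestPointwiseOps:
    def test_relu(self):
        assert relu(-3) == 0 and relu(5) == 5 and relu(0) == 0

    def test_weight_norm_examples(self):
        np.testing.assert_allclose(weight_norm_apply([3, 4], 5), [3, 4])
        np.testing.assert_allclose(weight_norm_apply([1, 0], 2), [2, 0])
        np.testing.assert_allclose(weight_norm_apply([7, -7], 0), [0, 0])

    def test_weight_norm_magnitude_is_g(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            v = rng.normal(size=8)
            g = float(rng.normal())
            assert abs(np.linalg.norm(weight_norm_apply(v, g)) - abs(g)) < 1e-9

    def test_weight_norm_zero_direction_rejected(self):
        with pytest.raises(InvalidArgumentError):
            weight_norm_apply([0, 0], 1.0)


class TestSpatialDropout:
    def test_rate_zero_and_inference_are_identity(self):
        x = np.random.default_rng(4).normal(size=(3, 10))
        y, _ = spatial_dropout(x, 0.0, np.random.default_rng(0), training=True)
        np.testing.assert_array_equal(x, y)
        y, _ = spatial_dropout(x, 0.9, np.random.default_rng(0), training=False)
        np.testing.assert_array_equal(x, y)

    def test_whole_channels_dropped_and_scaled(self):
        x = np.ones((50, 6))
        y, _ = spatial_dropout(x, 0.3, np.random.default_rng(5), training=True)
        # each channel is either all zero or all 1/(1-p), across positions
        for c in range(50):
            vals = set(np.round(y[c], 6))
            assert vals in ({0.0}, {round(1 / 0.7, 6)})

    def test_drop_fraction_matches_rate(self):
        # 10^4 seeded channel draws at rate 0.1
        rng = np.random.default_rng(6)
        x = np.ones((10_000, 3))
        y, _ = spatial_dropout(x, 0.1, rng, training=True)
        dropped = (y[:, 0] == 0).mean()
        assert abs(dropped - 0.1) < 0.01

    def test_invalid_rate_rejected(self):
        with pytest.raises(InvalidArgumentError):
            spatial_dropout(np.ones((2, 2)), 1.0, np.random.default_rng(0))


class TestResidualBlock:
    def test_zero_weights_reduce_to_relu(self):
        from tcncall.tcn import ResidualBlock
        blk = ResidualBlock(4, 4, 3, 2, 2, 0.0, np.random.default_rng(7))
        for conv in blk.convs:
            conv.g[:] = 0.0
            conv.b[:] = 0.0
        x = np.random.default_rng(8).normal(size=(4, 12)).astype(np.float32)
        y = residual_block(x, blk)
        np.testing.assert_allclose(y, np.maximum(0, x), atol=FLOAT_ATOL)

    @pytest.mark.parametrize("d", [1, 2, 4, 8, 16, 32])
    def test_length_preserved(self, d):
        from tcncall.tcn import ResidualBlock
        blk = ResidualBlock(3, 5, 4, d, 2, 0.0, np.random.default_rng(9))
        x = np.random.default_rng(10).normal(size=(3, 64)).astype(np.float32)
        assert residual_block(x, blk).shape == (5, 64)

    def test_matches_hand_composed_primitive_chain(self):
        """A block must equal the explicit composition: twice
        [weight-normalized dilated conv -> ReLU] plus skip and final ReLU
        (dropout off)."""
        from tcncall.tcn import ResidualBlock
        blk = ResidualBlock(3, 3, 4, 2, 2, 0.0, np.random.default_rng(11))
        x = np.random.default_rng(12).normal(size=(3, 20)).astype(np.float32)
        h = x
        for conv in blk.convs:
            w = np.stack([weight_norm_apply(v, g)
                          for v, g in zip(conv.v, conv.g)])
            h = relu(causal_dilated_conv(h, w, 2, bias=conv.b))
        expected = relu(x + h)
        np.testing.assert_allclose(residual_block(x, blk), expected,
                                   atol=1e-4)

    def test_channel_mismatch_without_projection_rejected(self):
        from tcncall.tcn import ResidualBlock
        blk = ResidualBlock(3, 5, 4, 1, 1, 0.0, np.random.default_rng(13))
        blk.skip = None  # sabotage: remove the 1x1 projection
        x = np.zeros((3, 8), dtype=np.float32)
        with pytest.raises((InvalidStateError, ValueError)):
            residual_block(x, blk)


class TestModel:
    def test_softmax_rows_sum_to_one(self, tiny_model):
        X = np.zeros((2, 17, 150), dtype=np.float32)
        X[:, 3, :] = 1.0
        p = tiny_model.predict_proba(X)
        assert p.shape == (2, 4, 150)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=FLOAT_ATOL)

    def test_one_block_per_dilation(self):
        cfg = TCNConfig(dilations=(1, 2, 4, 8, 16, 32), in_dim=17)
        assert len(build_model(cfg).blocks) == 6

    def test_seeded_build_is_reproducible(self):
        cfg = TCNConfig(n_channels=6, kernel_size=3, dilations=(1, 2),
                        in_dim=5, seed=21)
        X = np.random.default_rng(0).random((1, 5, 40)).astype(np.float32)
        np.testing.assert_array_equal(build_model(cfg).predict_proba(X),
                                      build_model(cfg).predict_proba(X))

    def test_model_is_causal(self, tiny_model):
        rng = np.random.default_rng(14)
        X = rng.random((1, 17, 64)).astype(np.float32)
        base = tiny_model.predict_proba(X)
        for t in (10, 40):
            X2 = X.copy()
            X2[:, :, t + 1:] = rng.random(X[:, :, t + 1:].shape)
            pert = tiny_model.predict_proba(X2)
            np.testing.assert_allclose(base[:, :, : t + 1],
                                       pert[:, :, : t + 1], atol=1e-5)

    def test_save_load_round_trip(self, tiny_model, tmp_path):
        X = np.random.default_rng(15).random((1, 17, 30)).astype(np.float32)
        tiny_model.save(tmp_path / "ckpt")
        loaded = TCN.load(tmp_path / "ckpt")
        np.testing.assert_array_equal(tiny_model.predict_proba(X),
                                      loaded.predict_proba(X))

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            build_model(TCNConfig(dilations=()))
        with pytest.raises(ConfigError):
            build_model(TCNConfig(dropout_rate=1.0))

    def test_summary_mentions_blocks(self, tiny_model):
        s = tiny_model.summary()
        assert "block d=1" in s and "receptive field" in s


class TestReceptiveField:
    @pytest.mark.parametrize("K,dilations,cpb,expected", [
        (2, (1,), 2, 3),
        (16, (1, 2, 4, 8, 16, 32), 2, 1891),
        (1, (1, 2, 4), 2, 1),
        (8, (1, 2, 4, 8), 2, 211),
    ])
    def test_formula(self, K, dilations, cpb, expected):
        cfg = TCNConfig(kernel_size=K, dilations=dilations,
                        convs_per_block=cpb, in_dim=5)
        assert receptive_field(cfg) == expected

    def test_formula_matches_empirical_influence_horizon(self):
        """With all-ones filters, a bump exactly receptive_field-1 before t
        changes output t; one position further back it cannot."""
        rng = np.random.default_rng(16)
        for _ in range(5):
            cfg = TCNConfig(
                n_channels=int(rng.integers(2, 5)),
                kernel_size=int(rng.integers(2, 5)),
                dilations=tuple(2 ** j for j in range(int(rng.integers(1, 4)))),
                convs_per_block=int(rng.integers(1, 3)),
                dropout_rate=0.0, in_dim=3, seed=int(rng.integers(1000)))
            model = build_model(cfg)
            # all-ones effective filters, zero biases: signal propagates
            # through ReLU to exactly the receptive field
            for blk in model.blocks:
                for conv in blk.convs:
                    conv.v[...] = 1.0
                    conv.g[...] = np.sqrt(conv.v[0].size)
                    conv.b[...] = 0.0
                if blk.skip is not None:
                    blk.skip.w[...] = 1.0
                    blk.skip.b[...] = 0.0
            for layer in (model.conv1x1, model.head):
                layer.w[...] = 1.0
                layer.b[...] = 0.0
            rf = receptive_field(cfg)
            n = rf + 4
            t = rf  # 0-based probe position
            base = model.forward(np.zeros((1, 3, n), dtype=np.float32))
            for offset, should_change in ((rf - 1, True), (rf, False)):
                X = np.zeros((1, 3, n), dtype=np.float32)
                X[0, 1, t - offset] = 1.0
                out = model.forward(X)
                changed = not np.allclose(out[0, :, t], base[0, :, t],
                                          atol=FLOAT_ATOL)
                assert changed == should_change, (cfg, offset)


def test_softmax_is_stable_for_large_logits():
    z = np.array([[1000.0, 1000.0, -1000.0, 0.0]])
    p = softmax(z, axis=1)
    assert np.isfinite(p).all() and abs(p.sum() - 1) < 1e-9
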