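"""Attention modules against independent loop-based oracles, shape
contracts, ablation toggles and basic learnability."""

import numpy as np
import pytest

from masegnet import nn
from masegnet.nn import Tensor, count_parameters
from masegnet.model import (
    CBAM,
    AttentionGate,
    ChannelAttention,
    EncoderBlock,
    ModelConfig,
    SpatialAttention,
    ThreefoldDecoderBlock,
    build_model,
    load_checkpoint,
    save_checkpoint,
)

RNG = np.random.default_rng(7)
REL_TOL = 1e-5


def _sigmoid(v):
    return 1.0 / (1.0 + np.exp(-v))


def channel_attention_oracle(x, w1, b1, w2, b2):
    """Loop-based evaluation: explicit pooling, two matrix products per
    descriptor with shared weights, elementwise sum, sigmoid."""
    bsz, c = x.shape[0], x.shape[1]
    out = np.zeros((bsz, c, 1, 1))
    for bi in range(bsz):
        avg = np.array([x[bi, ch].mean() for ch in range(c)])
        mx = np.array([x[bi, ch].max() for ch in range(c)])
        def mlp(v):
            h = np.maximum(v @ w1 + b1, 0.0)
            return h @ w2 + b2
        out[bi, :, 0, 0] = _sigmoid(mlp(avg) + mlp(mx))
    return out


def spatial_attention_oracle(x, kernel, bias):
    """Direct 7x7 convolution loop over the channel-pooled maps."""
    bsz, _, h, w = x.shape
    avg = x.mean(axis=1)
    mx = x.max(axis=1)
    stacked = np.stack([avg, mx], axis=1)  # B,2,H,W
    pad = 3
    xp = np.pad(stacked, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out = np.zeros((bsz, 1, h, w))
    for bi in range(bsz):
        for i in range(h):
            for j in range(w):
                out[bi, 0, i, j] = _sigmoid(
                    (xp[bi, :, i:i + 7, j:j + 7] * kernel[0]).sum() + bias[0])
    return out


def attention_gate_oracle(skip, gating, gate: AttentionGate):
    """Hand-coded gate: 1x1 projections, bilinear upsampling of the
    gating signal, ReLU, 1x1 to one channel, sigmoid, scale the skip."""
    def conv1x1(x, w, b):
        return np.einsum("bchw,oc->bohw", x, w[:, :, 0, 0]) + \
            b[None, :, None, None]

    theta = conv1x1(skip, gate.theta.weight.data, gate.theta.bias.data)
    phi = conv1x1(gating, gate.phi.weight.data, gate.phi.bias.data)
    h2, w2 = skip.shape[2], skip.shape[3]
    up = np.zeros(phi.shape[:2] + (h2, w2))
    hs, ws = phi.shape[2], phi.shape[3]
    for i in range(h2):
        for j in range(w2):
            sy = min(max((i + 0.5) * hs / h2 - 0.5, 0.0), hs - 1.0)
            sx = min(max((j + 0.5) * ws / w2 - 0.5, 0.0), ws - 1.0)
            y0, x0 = int(np.floor(sy)), int(np.floor(sx))
            y1, x1 = min(y0 + 1, hs - 1), min(x0 + 1, ws - 1)
            fy, fx = sy - y0, sx - x0
            up[:, :, i, j] = (
                phi[:, :, y0, x0] * (1 - fy) * (1 - fx)
                + phi[:, :, y1, x0] * fy * (1 - fx)
                + phi[:, :, y0, x1] * (1 - fy) * fx
                + phi[:, :, y1, x1] * fy * fx)
    act = np.maximum(theta + up, 0.0)
    alpha = _sigmoid(conv1x1(act, gate.psi.weight.data, gate.psi.bias.data))
    return alpha * skip


class TestChannelAttention:
    def test_matches_loop_oracle(self):
        mod = ChannelAttention(4, 2, np.random.default_rng(0))
        x = RNG.standard_normal((2, 4, 5, 5)).astype(np.float32)
        got = mod(Tensor(x)).data
        want = channel_attention_oracle(
            x, mod.fc1.weight.data, mod.fc1.bias.data,
            mod.fc2.weight.data, mod.fc2.bias.data)
        np.testing.assert_allclose(got, want, rtol=REL_TOL, atol=1e-6)

    def test_zero_weights_give_half(self):
        mod = ChannelAttention(4, 2, np.random.default_rng(0))
        for p in (mod.fc1.weight, mod.fc1.bias, mod.fc2.weight, mod.fc2.bias):
            p.data[...] = 0.0
        out = mod(Tensor(RNG.standard_normal((1, 4, 3, 3)))).data
        np.testing.assert_allclose(out, 0.5)

    def test_constant_channels_double_mlp(self):
        """Spatially constant channels make avg and max pooling agree, so
        M_c = sigmoid(2 * MLP(v))."""
        mod = ChannelAttention(3, 1, np.random.default_rng(1))
        v = np.array([0.3, -1.2, 2.0], dtype=np.float32)
        x = np.broadcast_to(v[None, :, None, None], (1, 3, 4, 4)).copy()
        got = mod(Tensor(x)).data[0, :, 0, 0]
        def mlp(u):
            h = np.maximum(u @ mod.fc1.weight.data + mod.fc1.bias.data, 0.0)
            return h @ mod.fc2.weight.data + mod.fc2.bias.data
        np.testing.assert_allclose(got, _sigmoid(2 * mlp(v)),
                                   rtol=REL_TOL, atol=1e-6)

    def test_values_strictly_in_unit_interval(self):
        mod = ChannelAttention(8, 4, np.random.default_rng(2))
        out = mod(Tensor(RNG.standard_normal((2, 8, 6, 6)))).data
        assert np.all(out > 0) and np.all(out < 1)


class TestSpatialAttention:
    def test_matches_loop_oracle(self):
        mod = SpatialAttention(np.random.default_rng(0))
        x = RNG.standard_normal((2, 3, 9, 9)).astype(np.float32)
        got = mod(Tensor(x)).data
        want = spatial_attention_oracle(x, mod.conv.weight.data,
                                        mod.conv.bias.data)
        np.testing.assert_allclose(got, want, rtol=REL_TOL, atol=1e-6)

    def test_zero_kernel_gives_half(self):
        mod = SpatialAttention(np.random.default_rng(0))
        mod.conv.weight.data[...] = 0.0
        mod.conv.bias.data[...] = 0.0
        out = mod(Tensor(RNG.standard_normal((1, 3, 5, 5)))).data
        np.testing.assert_allclose(out, 0.5)

    def test_single_channel_pools_to_itself(self):
        x = RNG.standard_normal((1, 1, 4, 4))
        avg = nn.mean_axes(Tensor(x), (1,)).data
        mx = nn.max_axes(Tensor(x), (1,)).data
        np.testing.assert_allclose(avg, x)
        np.testing.assert_allclose(mx, x)


class TestCBAM:
    def test_composition_of_oracles(self):
        mod = CBAM(4, 2, np.random.default_rng(3))
        x = RNG.standard_normal((2, 4, 6, 6)).astype(np.float32)
        mc = channel_attention_oracle(
            x, mod.channel.fc1.weight.data, mod.channel.fc1.bias.data,
            mod.channel.fc2.weight.data, mod.channel.fc2.bias.data)
        f1 = mc * x
        ms = spatial_attention_oracle(f1, mod.spatial.conv.weight.data,
                                      mod.spatial.conv.bias.data)
        want = ms * f1
        np.testing.assert_allclose(mod(Tensor(x)).data, want,
                                   rtol=REL_TOL, atol=1e-6)

    def test_contraction_never_amplifies(self):
        mod = CBAM(4, 2, np.random.default_rng(4))
        x = RNG.standard_normal((2, 4, 8, 8)).astype(np.float32)
        out = mod(Tensor(x)).data
        assert np.all(np.abs(out) <= np.abs(x) + 1e-7)


class TestAttentionGate:
    def test_zero_psi_halves_skip(self):
        gate = AttentionGate(2, 4, 2, np.random.default_rng(0))
        gate.psi.weight.data[...] = 0.0
        gate.psi.bias.data[...] = 0.0
        skip = RNG.standard_normal((1, 2, 4, 4)).astype(np.float32)
        gating = RNG.standard_normal((1, 4, 2, 2)).astype(np.float32)
        out = gate(Tensor(skip), Tensor(gating)).data
        np.testing.assert_allclose(out, skip / 2.0, rtol=1e-6)

    def test_matches_hand_coded_gate(self):
        gate = AttentionGate(2, 3, 2, np.random.default_rng(5))
        skip = RNG.standard_normal((2, 2, 4, 4)).astype(np.float32)
        gating = RNG.standard_normal((2, 3, 2, 2)).astype(np.float32)
        got = gate(Tensor(skip), Tensor(gating)).data
        want = attention_gate_oracle(skip, gating, gate)
        np.testing.assert_allclose(got, want, rtol=REL_TOL, atol=1e-6)

    def test_attended_skip_is_contraction(self):
        gate = AttentionGate(3, 6, 2, np.random.default_rng(6))
        skip = RNG.standard_normal((1, 3, 8, 8)).astype(np.float32)
        gating = RNG.standard_normal((1, 6, 4, 4)).astype(np.float32)
        out = gate(Tensor(skip), Tensor(gating)).data
        assert np.all(np.abs(out) <= np.abs(skip) + 1e-7)

    def test_invalid_inter_channels_rejected(self):
        with pytest.raises(ValueError):
            AttentionGate(2, 2, 0, np.random.default_rng(0))


class TestBlocks:
    def test_encoder_shapes(self, tiny_model_config):
        enc = EncoderBlock(3, 32, ModelConfig(in_channels=3),
                           np.random.default_rng(0))
        x = Tensor(RNG.standard_normal((1, 3, 64, 64)).astype(np.float32))
        features, pooled = enc(x)
        assert features.shape == (1, 32, 64, 64)
        assert pooled.shape == (1, 32, 32, 32)

    def test_encoder_without_cbam_is_plain_double_conv(self):
        cfg = ModelConfig(use_cbam=False)
        enc = EncoderBlock(1, 8, cfg, np.random.default_rng(1))
        assert enc.cbam is None
        x = Tensor(RNG.standard_normal((1, 1, 8, 8)).astype(np.float32))
        features, _ = enc(x)
        np.testing.assert_array_equal(features.data, enc.block(x).data)

    def test_decoder_shape_contract(self):
        cfg = ModelConfig()
        dec = ThreefoldDecoderBlock(64, 32, 32, cfg, np.random.default_rng(2))
        out = dec(Tensor(RNG.standard_normal((1, 64, 8, 8)).astype(np.float32)),
                  Tensor(RNG.standard_normal((1, 32, 16, 16)).astype(np.float32)))
        assert out.shape == (1, 32, 16, 16)

    def test_decoder_spatial_mismatch_names_shapes(self):
        dec = ThreefoldDecoderBlock(64, 32, 32, ModelConfig(),
                                    np.random.default_rng(3))
        with pytest.raises(ValueError, match="half the spatial"):
            dec(Tensor(np.zeros((1, 64, 8, 8), np.float32)),
                Tensor(np.zeros((1, 32, 20, 20), np.float32)))


class TestFullModel:
    def test_default_config_has_512_bottleneck(self):
        model = build_model(ModelConfig())
        assert model.bottleneck.conv2.weight.shape[0] == 512

    def test_forward_shape_and_range(self, tiny_model):
        x = RNG.uniform(0, 1, (2, 1, 64, 64)).astype(np.float32)
        out = tiny_model.predict_proba(x)
        assert out.shape == (2, 1, 64, 64)
        assert np.all(out > 0) and np.all(out < 1)

    def test_bottleneck_256_variant_builds_and_runs(self):
        model = build_model(ModelConfig(base_filters=16,
                                        bottleneck_filters=256))
        out = model.predict_proba(np.zeros((1, 1, 64, 64), np.float32))
        assert out.shape == (1, 1, 64, 64)

    def test_inconsistent_bottleneck_rejected(self):
        with pytest.raises(ValueError, match="bottleneck_filters"):
            ModelConfig(base_filters=32, depth=4, bottleneck_filters=256)

    def test_indivisible_input_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="divisible"):
            tiny_model.predict_proba(np.zeros((1, 1, 30, 30), np.float32))

    def test_ag_adds_parameters(self, tiny_model_config):
        import dataclasses
        with_ag = count_parameters(build_model(tiny_model_config))
        without = count_parameters(build_model(
            dataclasses.replace(tiny_model_config, use_ag=False)))
        assert without < with_ag

    def test_plain_unet_parameter_count_formula(self):
        """With CBAM and AG off, the parameter count equals the vanilla
        U-Net arithmetic computed independently from the widths."""
        import dataclasses
        cfg = ModelConfig(base_filters=8, depth=2, bottleneck_filters=32,
                          use_cbam=False, use_ag=False)
        model = build_model(cfg)

        def conv_params(cin, cout, k):
            return cout * cin * k * k + cout

        widths = [8, 16]
        expected = 0
        cin = cfg.in_channels
        for f in widths:  # encoder double convs
            expected += conv_params(cin, f, 3) + conv_params(f, f, 3)
            cin = f
        expected += conv_params(16, 32, 3) + conv_params(32, 32, 3)  # bottleneck
        dec_in = 32
        for f in reversed(widths):  # up conv + double conv
            expected += dec_in * f * 2 * 2 + f
            expected += conv_params(2 * f, f, 3) + conv_params(f, f, 3)
            dec_in = f
        expected += conv_params(8, 1, 1)  # head
        assert count_parameters(model) == expected

    def test_loss_decreases_after_one_step(self, tiny_model):
        from masegnet.train import bce_loss

        x = RNG.uniform(0, 1, (2, 1, 32, 32)).astype(np.float32)
        y = (RNG.uniform(0, 1, (2, 1, 32, 32)) < 0.05).astype(np.float32)
        opt = nn.Adam(tiny_model.parameters(), lr=1e-3)
        opt.zero_grad()
        pred = tiny_model(Tensor(x))
        loss0 = bce_loss(pred, y)
        loss0.backward()
        opt.step()
        loss1 = bce_loss(Tensor(tiny_model.predict_proba(x)), y)
        assert loss1.item() < loss0.item()

    def test_checkpoint_roundtrip(self, tiny_model, tmp_path):
        x = RNG.uniform(0, 1, (1, 1, 32, 32)).astype(np.float32)
        before = tiny_model.predict_proba(x)
        save_checkpoint(tiny_model, tmp_path / "m.npz")
        restored = load_checkpoint(tmp_path / "m.npz")
        np.testing.assert_array_equal(restored.predict_proba(x), before)
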