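"""Low-level branch: gate bounds, saturation limits, elementwise oracles."""

import numpy as np
import pytest

import oracles as orc
from duoseg import ConfigurationError, ShapeError
from duoseg.guided_branch import (
    CBAM,
    AggregateHighLevels,
    AttentionGate,
    ChannelAttention,
    GuidedLowLevelBranch,
    SpatialAttention,
)
from duoseg.nn import Tensor


def T(a):
    return Tensor(np.asarray(a, dtype=np.float32))


class TestAggregateHighLevels:
    def test_stride4_output(self, rng):
        agg = AggregateHighLevels(64, 128, rng, out_ch=32).eval()
        h = agg(T(rng.normal(size=(1, 64, 4, 4))), T(rng.normal(size=(1, 128, 2, 2))))
        assert h.shape == (1, 32, 16, 16)

    def test_zero_weights_constant_channels(self, rng):
        agg = AggregateHighLevels(2, 3, rng, out_ch=4).eval()
        agg.proj.weight.data = np.zeros_like(agg.proj.weight.data)
        bias = np.array([1.0, -2.0, 0.5, 3.0], dtype=np.float32)
        agg.proj.bias.data = bias
        h = agg(T(rng.normal(size=(1, 2, 4, 4))), T(rng.normal(size=(1, 3, 2, 2)))).data
        for k in range(4):
            np.testing.assert_allclose(h[0, k], bias[k], rtol=1e-6)


class TestAttentionGate:
    def test_gate_bound_output_never_exceeds_input(self, rng):
        gate = AttentionGate(3, 4, rng).eval()
        orc.randomize_bn_stats(gate, rng)
        h = T(rng.normal(size=(2, 3, 5, 5)))
        l = T(rng.normal(size=(2, 4, 5, 5)))
        out = gate(h, l).data
        assert (np.abs(out) <= np.abs(l.data) + 1e-7).all()
        g = gate.gate_map(h, l).data
        assert (g > 0).all() and (g < 1).all()

    def test_saturated_gate_passes_input_through(self, rng):
        gate = AttentionGate(2, 3, rng).eval()
        gate.conv_g.weight.data = np.zeros_like(gate.conv_g.weight.data)
        gate.conv_g.bias.data = np.full_like(gate.conv_g.bias.data, 50.0)
        gate.bn_g.set_identity()
        l = T(rng.normal(size=(1, 3, 4, 4)))
        out = gate(T(rng.normal(size=(1, 2, 4, 4))), l).data
        np.testing.assert_allclose(out, l.data, rtol=1e-5)

    def test_spatial_mismatch_raises(self, rng):
        gate = AttentionGate(2, 3, rng).eval()
        with pytest.raises(ShapeError):
            gate(T(np.zeros((1, 2, 4, 4))), T(np.zeros((1, 3, 8, 8))))

    def test_matches_hand_composition(self, rng):
        gate = AttentionGate(2, 3, rng, inter_ch=2).eval()
        orc.randomize_bn_stats(gate, rng)
        h = rng.normal(size=(1, 2, 4, 4)).astype(np.float32)
        l = rng.normal(size=(1, 3, 4, 4)).astype(np.float32)
        q = orc.np_sigmoid(
            orc.np_bn_eval(
                orc.np_plain_conv(gate.conv_h, h)
                + orc.np_bn_eval(orc.np_plain_conv(gate.conv_l, l), gate.bn_l),
                gate.bn_q,
            )
        )
        gmap = orc.np_sigmoid(orc.np_bn_eval(orc.np_plain_conv(gate.conv_g, q), gate.bn_g))
        np.testing.assert_allclose(gate(T(h), T(l)).data, l * gmap, rtol=1e-4, atol=1e-6)


class TestChannelAttention:
    def test_identical_channel_maps_give_uniform_scaling(self, rng):
        ca = ChannelAttention(4, rng, reduction=2).eval()
        base = rng.normal(size=(1, 1, 3, 3)).astype(np.float32)
        f = np.repeat(base, 4, axis=1)
        out = ca(T(f)).data
        s = out / f
        assert np.ptp(s) < 1e-5  # one scalar s for every channel and pixel
        assert 0 < s.flat[0] < 1

    def test_bound(self, rng):
        ca = ChannelAttention(4, rng, reduction=2).eval()
        f = rng.normal(size=(2, 4, 3, 3)).astype(np.float32)
        assert (np.abs(ca(T(f)).data) <= np.abs(f)).all()

    def test_reduction_larger_than_channels_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            ChannelAttention(4, rng, reduction=8)

    def test_non_restoring_projection_refuses_product(self, rng):
        ca = ChannelAttention(4, rng, reduction=2, out_channels=3).eval()
        with pytest.raises(ShapeError):
            ca(T(np.zeros((1, 4, 3, 3))))

    def test_matches_hand_evaluation(self, rng):
        ca = ChannelAttention(4, rng, reduction=2).eval()
        f = rng.normal(size=(1, 4, 2, 2)).astype(np.float32)
        pa = f.max(axis=(2, 3), keepdims=True)
        pm = f.mean(axis=(2, 3), keepdims=True)

        def proj(v):
            z = orc.np_plain_conv(ca.conv1, v)
            return orc.np_plain_conv(ca.conv2, orc.np_relu(z))

        ref = f * orc.np_sigmoid(proj(pa) + proj(pm))
        np.testing.assert_allclose(ca(T(f)).data, ref, rtol=1e-5, atol=1e-7)


class TestSpatialAttention:
    def test_single_channel_degenerate_case(self, rng):
        sa = SpatialAttention(rng).eval()
        f = rng.normal(size=(1, 1, 5, 5)).astype(np.float32)
        # with one channel, max map == mean map == f, so the gate is
        # sigmoid(conv(2 f))
        gate = orc.np_sigmoid(orc.np_plain_conv(sa.conv, 2 * f))
        np.testing.assert_allclose(sa(T(f)).data, f * gate, rtol=1e-5, atol=1e-7)

    def test_bound(self, rng):
        sa = SpatialAttention(rng).eval()
        f = rng.normal(size=(2, 3, 5, 5)).astype(np.float32)
        assert (np.abs(sa(T(f)).data) <= np.abs(f)).all()

    def test_matches_hand_evaluation(self, rng):
        sa = SpatialAttention(rng).eval()
        f = rng.normal(size=(1, 3, 5, 5)).astype(np.float32)
        cm = f.max(axis=1, keepdims=True)
        cavg = f.mean(axis=1, keepdims=True)
        ref = f * orc.np_sigmoid(orc.np_plain_conv(sa.conv, cm + cavg))
        np.testing.assert_allclose(sa(T(f)).data, ref, rtol=1e-5, atol=1e-7)


class TestCBAM:
    def test_shape_preserved(self, rng):
        cbam = CBAM(8, rng, reduction=2).eval()
        f = T(rng.normal(size=(1, 8, 6, 6)))
        assert cbam(f).shape == (1, 8, 6, 6)

    def test_matches_sequential_oracles(self, rng):
        cbam = CBAM(2, rng, reduction=2).eval()
        orc.randomize_bn_stats(cbam, rng)
        f = rng.normal(size=(1, 2, 4, 4)).astype(np.float32)
        pa = f.max(axis=(2, 3), keepdims=True)
        pm = f.mean(axis=(2, 3), keepdims=True)

        def proj(v):
            return orc.np_plain_conv(
                cbam.ca.conv2, orc.np_relu(orc.np_plain_conv(cbam.ca.conv1, v))
            )

        after_ca = f * orc.np_sigmoid(proj(pa) + proj(pm))
        cm = after_ca.max(axis=1, keepdims=True)
        cavg = after_ca.mean(axis=1, keepdims=True)
        after_sa = after_ca * orc.np_sigmoid(orc.np_plain_conv(cbam.sa.conv, cm + cavg))
        ref = orc.np_convbnrelu(cbam.conv_block, after_sa)
        np.testing.assert_allclose(cbam(T(f)).data, ref, rtol=1e-4, atol=1e-6)


class TestGuidedBranchHead:
    def _inputs(self, rng, size=64):
        return (
            T(rng.normal(size=(1, 16, size // 4, size // 4))),
            T(rng.normal(size=(1, 64, size // 16, size // 16))),
            T(rng.normal(size=(1, 128, size // 32, size // 32))),
        )

    def test_tiny_shapes(self, rng):
        branch = GuidedLowLevelBranch((16, 32, 64, 128), 7, rng, reduction=4).eval()
        x1, e3, e4 = self._inputs(rng)
        assert branch(x1, e3, e4).shape == (1, 7, 64, 64)

    def test_too_few_classes_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            GuidedLowLevelBranch((16, 32, 64, 128), 1, rng)

    def test_zero_final_conv_gives_constant_maps(self, rng):
        branch = GuidedLowLevelBranch((16, 32, 64, 128), 3, rng, reduction=4).eval()
        orc.randomize_bn_stats(branch, rng)
        branch.head.weight.data = np.zeros_like(branch.head.weight.data)
        branch.head.bias.data = np.array([0.1, -0.2, 0.3], dtype=np.float32)
        out = branch(*self._inputs(rng)).data
        for k in range(3):
            np.testing.assert_allclose(out[0, k], branch.head.bias.data[k], rtol=1e-5)

    def test_finite_under_extreme_input_scaling(self, rng):
        branch = GuidedLowLevelBranch((16, 32, 64, 128), 3, rng, reduction=4).eval()
        orc.randomize_bn_stats(branch, rng)
        x1, e3, e4 = self._inputs(rng)
        out = branch(Tensor(x1.data * 100.0), e3, e4).data
        assert np.isfinite(out).all()
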