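"""High-level branch: block contracts, closed forms and composition oracles."""

import numpy as np
import pytest

import oracles as orc
from duoseg import ConfigurationError, ShapeError
from duoseg.context_branch import (
    CascadedFusion,
    ContextBranch,
    ContextIntegration,
    DownconvBlock,
    FuseHighLevels,
    ResidualUContextExtractor,
    UpconvBlock,
)
from duoseg.encoder import build_encoder, encode
from duoseg.nn import Tensor, concat


def T(a):
    return Tensor(np.asarray(a, dtype=np.float32))


class TestUpconvBlock:
    def test_shape_contract(self, rng):
        blk = UpconvBlock(8, 4, rng, kernel=3, scale=2).eval()
        assert blk(T(rng.normal(size=(1, 8, 16, 16)))).shape == (1, 4, 32, 32)

    def test_nonpositive_scale_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            UpconvBlock(4, 4, rng, scale=0)

    def test_zero_input_nonnegative_everywhere(self, rng):
        blk = UpconvBlock(3, 5, rng).eval()
        out = blk(T(np.zeros((1, 3, 4, 4)))).data
        assert (out >= 0).all()

    def test_matches_hand_composition(self, rng):
        blk = UpconvBlock(2, 3, rng, kernel=3, scale=2).eval()
        orc.randomize_bn_stats(blk, rng)
        x = rng.normal(size=(1, 2, 4, 4)).astype(np.float32)
        ref = orc.np_convbnrelu(blk.block, orc.np_upsample_bilinear(x, 2))
        np.testing.assert_allclose(blk(T(x)).data, ref, rtol=1e-5, atol=1e-6)


class TestDownconvBlock:
    @pytest.mark.parametrize("stride,out_ch", [(2, 320), (4, 512)])
    def test_shape_contract(self, rng, stride, out_ch):
        blk = DownconvBlock(8, out_ch, rng, pool_stride=stride).eval()
        out = blk(T(rng.normal(size=(1, 8, 32, 32))))
        assert out.shape == (1, out_ch, 32 // stride, 32 // stride)

    def test_indivisible_size_raises(self, rng):
        blk = DownconvBlock(2, 4, rng, pool_stride=4).eval()
        with pytest.raises(ShapeError):
            blk(T(np.zeros((1, 2, 6, 6))))

    def test_constant_input_closed_form(self, rng):
        """Max-pool is the identity on constants, so the output is the
        BN/ReLU of the 1x1 conv response to that constant."""
        blk = DownconvBlock(1, 1, rng, pool_stride=2).eval()
        orc.randomize_bn_stats(blk, rng)
        c = 0.7
        out = blk(T(np.full((1, 1, 4, 4), c))).data
        w = blk.block.conv.weight.data.item()
        bn = blk.block.bn
        expected = max(
            (w * c - bn.running_mean.item()) / np.sqrt(bn.running_var.item() + bn.eps)
            * bn.weight.data.item() + bn.bias.data.item(),
            0.0,
        )
        np.testing.assert_allclose(out, expected, rtol=1e-5)


class TestFuseHighLevels:
    @pytest.mark.parametrize("c2,c3,c4,size", [(32, 64, 128, 64)])
    def test_output_at_stride8(self, rng, c2, c3, c4, size):
        fuse = FuseHighLevels(c2, c3, c4, rng).eval()
        y = fuse(
            T(rng.normal(size=(1, c2, size // 8, size // 8))),
            T(rng.normal(size=(1, c3, size // 16, size // 16))),
            T(rng.normal(size=(1, c4, size // 32, size // 32))),
        )
        assert y.shape == (1, c2, size // 8, size // 8)

    def test_concat_order_permutation_equivalence(self, rng):
        """Permuting the concatenation order together with the matching
        input-channel blocks of the 1x1 projection leaves y unchanged."""
        c2 = 3
        fuse = FuseHighLevels(c2, 4, 5, rng).eval()
        orc.randomize_bn_stats(fuse, rng)
        x2 = T(rng.normal(size=(1, c2, 8, 8)))
        x3 = T(rng.normal(size=(1, 4, 4, 4)))
        x4 = T(rng.normal(size=(1, 5, 2, 2)))
        y_ref = fuse(x2, x3, x4).data

        p2 = fuse.conv_x2(x2)
        p3 = fuse.up_x3(x3)
        p4 = fuse.up_x4_b(fuse.up_x4_a(x4))
        cat_perm = concat([p3, p4, p2], axis=1)  # order rotated
        w = fuse.proj.weight.data
        blocks = [w[:, :c2], w[:, c2 : 2 * c2], w[:, 2 * c2 :]]
        w_perm = np.concatenate([blocks[1], blocks[2], blocks[0]], axis=1)
        y_perm = orc.np_conv2d(cat_perm.data, w_perm, fuse.proj.bias.data)
        np.testing.assert_allclose(y_perm, y_ref, rtol=1e-4, atol=1e-5)


class TestResidualUContextExtractor:
    def test_shape_contract(self, rng):
        ruce = ResidualUContextExtractor(128, 128, rng, mid_ch=64).eval()
        out = ruce(T(rng.normal(size=(1, 128, 32, 32))))
        assert out.shape == (1, 128, 32, 32)

    def test_too_small_input_raises(self, rng):
        ruce = ResidualUContextExtractor(4, 4, rng).eval()
        with pytest.raises(ShapeError):
            ruce(T(np.zeros((1, 4, 2, 2))))

    def test_residual_identity_when_inner_paths_zeroed(self, rng):
        ruce = ResidualUContextExtractor(3, 4, rng, mid_ch=2).eval()
        for name in ("enc1", "enc2", "enc3", "bridge", "dec2", "dec1", "conv_out"):
            blk = getattr(ruce, name)
            blk.conv.weight.data = np.zeros_like(blk.conv.weight.data)
            blk.bn.set_identity()
        x = T(rng.normal(size=(1, 3, 8, 8)))
        f_in = ruce.conv_in(x).data
        np.testing.assert_allclose(ruce(x).data, f_in, rtol=1e-6)

    def test_matches_hand_wired_composition(self, rng):
        """The whole U-block (11 layers) against an independent composition
        of the same weights: conv-in, 3 pooled encoder convs, dilated
        bridge, 2 skip-merging decoder convs with upsampling, output conv,
        residual add."""
        ruce = ResidualUContextExtractor(4, 6, rng, mid_ch=3).eval()
        orc.randomize_bn_stats(ruce, rng)
        x = rng.normal(size=(1, 4, 8, 8)).astype(np.float32)
        f_in = orc.np_convbnrelu(ruce.conv_in, x)
        e1 = orc.np_convbnrelu(ruce.enc1, f_in)
        e2 = orc.np_convbnrelu(ruce.enc2, orc.np_maxpool(e1, 2))
        e3 = orc.np_convbnrelu(ruce.enc3, orc.np_maxpool(e2, 2))
        b = orc.np_convbnrelu(ruce.bridge, e3)
        d2 = orc.np_upsample_bilinear(
            orc.np_convbnrelu(ruce.dec2, np.concatenate([b, e3], axis=1)), 2
        )
        d1 = orc.np_upsample_bilinear(
            orc.np_convbnrelu(ruce.dec1, np.concatenate([d2, e2], axis=1)), 2
        )
        f_dec = orc.np_convbnrelu(ruce.conv_out, np.concatenate([d1, e1], axis=1))
        np.testing.assert_allclose(
            ruce(T(x)).data, f_in + f_dec, rtol=1e-4, atol=1e-5
        )

    def test_batch_size_invariance_in_eval(self, rng):
        ruce = ResidualUContextExtractor(3, 4, rng, mid_ch=2).eval()
        orc.randomize_bn_stats(ruce, rng)
        x = rng.normal(size=(3, 3, 8, 8)).astype(np.float32)
        full = ruce(T(x)).data
        single = np.concatenate([ruce(T(x[i : i + 1])).data for i in range(3)])
        np.testing.assert_allclose(full, single, rtol=1e-5, atol=1e-6)


class TestContextIntegration:
    def _pyramid(self, rng, c2=2, c3=3, c4=4):
        return (
            T(rng.normal(size=(1, c2, 8, 8))),
            T(rng.normal(size=(1, c3, 4, 4))),
            T(rng.normal(size=(1, c4, 2, 2))),
        )

    def test_uniform_softmax_closed_form(self, rng):
        """Zero gate convolutions (BN identity) give uniform channel softmax,
        hence x'_i = (1 + 1/C_i) * x_i exactly."""
        integ = ContextIntegration(3, 2, 3, 4, rng).eval()
        integ.gate2.weight.data = np.zeros_like(integ.gate2.weight.data)
        integ.gate2.bias.data = np.zeros_like(integ.gate2.bias.data)
        for gate in (integ.gate3, integ.gate4):
            gate.block.conv.weight.data = np.zeros_like(gate.block.conv.weight.data)
            gate.block.bn.set_identity()
        x2, x3, x4 = self._pyramid(rng)
        context = T(rng.normal(size=(1, 3, 8, 8)))
        enh = integ(context, x2, x3, x4)
        for x, e, c in ((x2, enh.x2, 2), (x3, enh.x3, 3), (x4, enh.x4, 4)):
            np.testing.assert_allclose(e.data, (1 + 1 / c) * x.data, rtol=1e-5)

    def test_gate_softmax_sums_to_one_and_residual_form(self, rng):
        integ = ContextIntegration(3, 2, 3, 4, rng).eval()
        orc.randomize_bn_stats(integ, rng)
        x2, x3, x4 = self._pyramid(rng)
        context = T(rng.normal(size=(1, 3, 8, 8)))
        enh = integ(context, x2, x3, x4)
        gate2 = integ.gate2(context).softmax(axis=1).data
        np.testing.assert_allclose(gate2.sum(axis=1), 1.0, atol=1e-5)
        assert (gate2 > 0).all() and (gate2 < 1).all()
        # residual form: x'_2 - x_2 = x_2 * gate
        np.testing.assert_allclose(
            enh.x2.data - x2.data, x2.data * gate2, rtol=1e-4, atol=1e-6
        )

    def test_x2_branch_matches_elementwise_formula(self, rng):
        integ = ContextIntegration(3, 2, 3, 4, rng).eval()
        orc.randomize_bn_stats(integ, rng)
        x2, x3, x4 = self._pyramid(rng)
        context = rng.normal(size=(1, 3, 8, 8)).astype(np.float32)
        enh = integ(T(context), x2, x3, x4)
        gate = orc.np_softmax_channels(orc.np_plain_conv(integ.gate2, context))
        ref = x2.data * gate + x2.data
        np.testing.assert_allclose(enh.x2.data, ref, rtol=1e-4, atol=1e-6)

    def test_channel_mismatch_raises(self, rng):
        integ = ContextIntegration(3, 2, 3, 4, rng).eval()
        x2 = T(np.zeros((1, 5, 8, 8)))  # wrong channel count
        with pytest.raises(ShapeError):
            integ(T(np.zeros((1, 3, 8, 8))), x2, T(np.zeros((1, 3, 4, 4))),
                  T(np.zeros((1, 4, 2, 2))))


class TestCascadedFusion:
    def test_shapes_from_tiny_pyramid(self, rng):
        from duoseg.context_branch import EnhancedPyramid

        fusion = CascadedFusion(32, 64, 128, 7, rng, width=16).eval()
        enh = EnhancedPyramid(
            T(rng.normal(size=(1, 32, 8, 8))),
            T(rng.normal(size=(1, 64, 4, 4))),
            T(rng.normal(size=(1, 128, 2, 2))),
        )
        assert fusion(enh).shape == (1, 7, 64, 64)

    def test_too_few_classes_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            CascadedFusion(32, 64, 128, 1, rng)

    def test_zero_head_gives_constant_bias_logits(self, rng):
        from duoseg.context_branch import EnhancedPyramid

        fusion = CascadedFusion(4, 5, 6, 3, rng, width=4).eval()
        fusion.head.weight.data = np.zeros_like(fusion.head.weight.data)
        bias = np.array([0.3, -1.2, 2.0], dtype=np.float32)
        fusion.head.bias.data = bias
        enh = EnhancedPyramid(
            T(rng.normal(size=(1, 4, 8, 8))),
            T(rng.normal(size=(1, 5, 4, 4))),
            T(rng.normal(size=(1, 6, 2, 2))),
        )
        out = fusion(enh).data
        for k in range(3):
            np.testing.assert_allclose(out[0, k], bias[k], rtol=1e-6)


def test_full_branch_composition_oracle_tiny(rng):
    """End-to-end high-level branch vs an independent hand composition of
    every layer on shared weights (tiny encoder at 64x64)."""
    enc = build_encoder("tiny", seed=0)
    branch = ContextBranch((16, 32, 64, 128), 4, rng, fusion_width=8).eval()
    orc.randomize_bn_stats(branch, rng)
    img = rng.random((1, 64, 64), dtype=np.float32)
    pyr = encode(img, enc)
    logits, enhanced = branch(pyr.x2, pyr.x3, pyr.x4)

    x2, x3, x4 = pyr.x2.data, pyr.x3.data, pyr.x4.data
    fuse = branch.fuse
    p2 = orc.np_plain_conv(fuse.conv_x2, x2)
    p3 = orc.np_convbnrelu(fuse.up_x3.block, orc.np_upsample_bilinear(x3, 2))
    p4a = orc.np_convbnrelu(fuse.up_x4_a.block, orc.np_upsample_bilinear(x4, 2))
    p4 = orc.np_convbnrelu(fuse.up_x4_b.block, orc.np_upsample_bilinear(p4a, 2))
    y = orc.np_plain_conv(fuse.proj, np.concatenate([p2, p3, p4], axis=1))

    ruce = branch.extractor
    f_in = orc.np_convbnrelu(ruce.conv_in, y)
    e1 = orc.np_convbnrelu(ruce.enc1, f_in)
    e2 = orc.np_convbnrelu(ruce.enc2, orc.np_maxpool(e1, 2))
    e3 = orc.np_convbnrelu(ruce.enc3, orc.np_maxpool(e2, 2))
    b = orc.np_convbnrelu(ruce.bridge, e3)
    d2 = orc.np_upsample_bilinear(
        orc.np_convbnrelu(ruce.dec2, np.concatenate([b, e3], axis=1)), 2)
    d1 = orc.np_upsample_bilinear(
        orc.np_convbnrelu(ruce.dec1, np.concatenate([d2, e2], axis=1)), 2)
    context = f_in + orc.np_convbnrelu(ruce.conv_out, np.concatenate([d1, e1], axis=1))

    integ = branch.integrate
    g2 = orc.np_softmax_channels(orc.np_plain_conv(integ.gate2, context))
    g3 = orc.np_softmax_channels(
        orc.np_convbnrelu(integ.gate3.block, orc.np_maxpool(context, 2)))
    g4 = orc.np_softmax_channels(
        orc.np_convbnrelu(integ.gate4.block, orc.np_maxpool(context, 4)))
    e_x2, e_x3, e_x4 = x2 * g2 + x2, x3 * g3 + x3, x4 * g4 + x4

    fus = branch.fusion
    f2 = orc.np_plain_conv(fus.proj2, e_x2)
    f3 = orc.np_convbnrelu(fus.up3.block, orc.np_upsample_bilinear(e_x3, 2))
    f4 = orc.np_convbnrelu(fus.up4.block, orc.np_upsample_bilinear(e_x4, 4))
    ref = orc.np_plain_conv(
        fus.head, orc.np_upsample_bilinear(np.concatenate([f2, f3, f4], axis=1), 8))

    np.testing.assert_allclose(enhanced.x2.data, e_x2, rtol=1e-4, atol=1e-5)
    np.testing.assert_allclose(logits.data, ref, rtol=1e-3, atol=1e-4)
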