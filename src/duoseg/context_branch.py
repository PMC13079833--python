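"""High-level decoder branch: contextual enhancement of the deep features.

The branch fuses the three deep pyramid levels ``x2..x4`` to a common
stride-8 map ``y``, extracts multi-receptive-field context ``C`` from it with
a single residual U-shaped extractor, gates each deep feature with a
per-pixel channel softmax of (a projection of) ``C`` in residual form

    x'_i = x_i * softmax_channels(proj_i(C)) + x_i ,

and finally fuses the enhanced pyramid through progressive upsampling into
the branch's class-logit map ``P`` at full image resolution.

The softmax is taken over the channel axis at each spatial location, so every
gate is a convex channel reweighting: ``x'_i - x_i = x_i * g_i`` with
``g_i in (0,1)`` and the gate channels summing to 1 per pixel.  A spatial
softmax would scale the residual term like 1/(H*W) and extinguish it.

Channel plan (configurable): the fused input and context keep ``C_y = C_r =
C2`` channels; the extractor's internal convolutions run at ``M = C_r // 2``
channels; the fusion paths are reduced to ``F_f`` (default 64) channels each.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from . import nn
from .errors import ConfigurationError, ShapeError
from .nn import Tensor, concat, maxpool2d, upsample_bilinear

__all__ = [
    "UpconvBlock",
    "DownconvBlock",
    "FuseHighLevels",
    "ResidualUContextExtractor",
    "ContextIntegration",
    "CascadedFusion",
    "ContextBranch",
    "EnhancedPyramid",
]


class EnhancedPyramid(NamedTuple):
    """Context-gated deep features, shape-identical to x2..x4."""

    x2: Tensor
    x3: Tensor
    x4: Tensor


class UpconvBlock(nn.Module):
    """Bilinear upsample by *scale* then Conv-BN-ReLU (kernel 3 or 1)."""

    def __init__(self, in_ch: int, out_ch: int, rng, kernel: int = 3, scale: int = 2):
        super().__init__()
        if scale <= 0:
            raise ConfigurationError(f"upsample scale must be positive, got {scale}")
        self.scale = scale
        self.block = nn.ConvBNReLU(in_ch, out_ch, kernel, rng)

    def forward(self, x):
        return self.block(upsample_bilinear(x, self.scale))


class DownconvBlock(nn.Module):
    """Max-pool by *pool_stride* then 1x1 Conv-BN-ReLU."""

    def __init__(self, in_ch: int, out_ch: int, rng, pool_stride: int = 2):
        super().__init__()
        if pool_stride <= 0:
            raise ConfigurationError(f"pool stride must be positive, got {pool_stride}")
        self.pool_stride = pool_stride
        self.block = nn.ConvBNReLU(in_ch, out_ch, 1, rng)

    def forward(self, x):
        H, W = x.shape[2], x.shape[3]
        if H % self.pool_stride or W % self.pool_stride:
            raise ShapeError(
                f"spatial size ({H},{W}) not divisible by pool stride {self.pool_stride}"
            )
        return self.block(maxpool2d(x, self.pool_stride))


class FuseHighLevels(nn.Module):
    """Fuse x2..x4 at stride 8: y = Conv1x1([Conv3x3(x2), Up(x3), Up(Up(x4))]).

    x3 is upsampled x2 and x4 x4 (as two chained x2 upconv blocks); every
    path is brought to C2 channels before the 1x1 projection to ``out_ch``.
    """

    def __init__(self, c2: int, c3: int, c4: int, rng, out_ch: int | None = None):
        super().__init__()
        out_ch = c2 if out_ch is None else out_ch
        self.conv_x2 = nn.Conv2d(c2, c2, 3, rng, padding=1)
        self.up_x3 = UpconvBlock(c3, c2, rng, kernel=3, scale=2)
        self.up_x4_a = UpconvBlock(c4, c2, rng, kernel=3, scale=2)
        self.up_x4_b = UpconvBlock(c2, c2, rng, kernel=3, scale=2)
        self.proj = nn.Conv2d(3 * c2, out_ch, 1, rng)

    def forward(self, x2, x3, x4):
        p2 = self.conv_x2(x2)
        p3 = self.up_x3(x3)
        p4 = self.up_x4_b(self.up_x4_a(x4))
        for name, p in (("x3", p3), ("x4", p4)):
            if p.shape[2:] != p2.shape[2:]:
                raise ShapeError(
                    f"{name} path spatial size {p.shape[2:]} does not match x2 "
                    f"{p2.shape[2:]} after upsampling"
                )
        return self.proj(concat([p2, p3, p4], axis=1))


class ResidualUContextExtractor(nn.Module):
    """Single residual U-block: a small encoder–decoder with a dilated bridge.

    The input is first projected by a 3x3 Conv-BN-ReLU (``F_in``); a
    two-level max-pooling encoder and a dilation-2 bridge diversify the
    receptive field; the decoder restores resolution with skip connections;
    the output is the residual sum ``C = F_in + F_dec``.
    """

    def __init__(self, in_ch: int, out_ch: int, rng, mid_ch: int | None = None):
        super().__init__()
        mid = out_ch // 2 if mid_ch is None else mid_ch
        self.conv_in = nn.ConvBNReLU(in_ch, out_ch, 3, rng)
        self.enc1 = nn.ConvBNReLU(out_ch, mid, 3, rng)
        self.enc2 = nn.ConvBNReLU(mid, mid, 3, rng)
        self.enc3 = nn.ConvBNReLU(mid, mid, 3, rng)
        self.bridge = nn.ConvBNReLU(mid, mid, 3, rng, dilation=2, padding=2)
        self.dec2 = nn.ConvBNReLU(2 * mid, mid, 3, rng)
        self.dec1 = nn.ConvBNReLU(2 * mid, mid, 3, rng)
        self.conv_out = nn.ConvBNReLU(2 * mid, out_ch, 3, rng)

    def forward(self, y):
        H, W = y.shape[2], y.shape[3]
        if H < 4 or W < 4 or H % 4 or W % 4:
            raise ShapeError(
                f"context extractor needs spatial size divisible by 4 and >= 4, got ({H},{W})"
            )
        f_in = self.conv_in(y)
        e1 = self.enc1(f_in)
        e2 = self.enc2(maxpool2d(e1, 2))
        e3 = self.enc3(maxpool2d(e2, 2))
        b = self.bridge(e3)
        d2 = upsample_bilinear(self.dec2(concat([b, e3], axis=1)), 2)
        d1 = upsample_bilinear(self.dec1(concat([d2, e2], axis=1)), 2)
        f_dec = self.conv_out(concat([d1, e1], axis=1))
        return f_in + f_dec


class ContextIntegration(nn.Module):
    """Gate each deep feature with a channel softmax of the context map.

    The x2 gate is a stride-preserving 1x1 conv of C; the x3/x4 gates pass C
    through pool-2 / pool-4 down-convolution blocks first.  Softmax is over
    channels per pixel, the gated product is added back to the untouched
    encoder feature (residual form).
    """

    def __init__(self, c_r: int, c2: int, c3: int, c4: int, rng):
        super().__init__()
        self.gate2 = nn.Conv2d(c_r, c2, 1, rng)
        self.gate3 = DownconvBlock(c_r, c3, rng, pool_stride=2)
        self.gate4 = DownconvBlock(c_r, c4, rng, pool_stride=4)

    def forward(self, context, x2, x3, x4) -> EnhancedPyramid:
        out = []
        for gate_mod, x in ((self.gate2, x2), (self.gate3, x3), (self.gate4, x4)):
            g = gate_mod(context)
            if g.shape != x.shape:
                raise ShapeError(
                    f"gate shape {g.shape} does not match feature shape {x.shape}"
                )
            out.append(x * g.softmax(axis=1) + x)
        return EnhancedPyramid(*out)


class CascadedFusion(nn.Module):
    """Fuse the enhanced pyramid into full-resolution class logits P.

    x'_2 is reduced by a 1x1 conv; x'_3 and x'_4 are brought to stride 8 by
    1x1 upconv blocks; the concatenation is upsampled x8 and mapped to K
    logits by a plain 1x1 conv (no BN/ReLU on the logit layer, which must be
    free to go negative).
    """

    def __init__(self, c2: int, c3: int, c4: int, num_classes: int, rng, width: int = 64):
        super().__init__()
        if num_classes < 2:
            raise ConfigurationError(f"need at least 2 classes, got {num_classes}")
        self.proj2 = nn.Conv2d(c2, width, 1, rng)
        self.up3 = UpconvBlock(c3, width, rng, kernel=1, scale=2)
        self.up4 = UpconvBlock(c4, width, rng, kernel=1, scale=4)
        self.head = nn.Conv2d(3 * width, num_classes, 1, rng)

    def forward(self, enhanced: EnhancedPyramid):
        f = concat(
            [self.proj2(enhanced.x2), self.up3(enhanced.x3), self.up4(enhanced.x4)],
            axis=1,
        )
        return self.head(upsample_bilinear(f, 8))


class ContextBranch(nn.Module):
    """The full high-level branch: fuse -> extract context -> gate -> logits."""

    def __init__(
        self,
        channels: tuple[int, int, int, int],
        num_classes: int,
        rng: np.random.Generator,
        fusion_width: int = 64,
    ):
        super().__init__()
        _, c2, c3, c4 = channels
        c_y = c_r = c2
        self.fuse = FuseHighLevels(c2, c3, c4, rng, out_ch=c_y)
        self.extractor = ResidualUContextExtractor(c_y, c_r, rng)
        self.integrate = ContextIntegration(c_r, c2, c3, c4, rng)
        self.fusion = CascadedFusion(c2, c3, c4, num_classes, rng, width=fusion_width)

    def forward(self, x2, x3, x4):
        y = self.fuse(x2, x3, x4)
        context = self.extractor(y)
        enhanced = self.integrate(context, x2, x3, x4)
        logits = self.fusion(enhanced)
        return logits, enhanced
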