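"""Low-level decoder branch: global-context-guided refinement of x1.

The stride-4 encoder feature ``x1`` carries edge and texture detail but
little semantics, so it is gated by an aggregate ``h`` of the enhanced deep
features: an additive attention gate produces a single-channel sigmoid map
that suppresses irrelevant regions of ``x1``; the gated feature is merged
with ``h`` and refined by a CBAM block (channel attention, then spatial
attention, then a 3x3 conv block) before the branch's own logit head.

All gate maps here are sigmoid-valued, hence strictly inside (0,1): the
gated output never exceeds the input elementwise.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .errors import ConfigurationError, ShapeError
from .nn import Tensor, concat, upsample_bilinear

__all__ = [
    "AggregateHighLevels",
    "AttentionGate",
    "ChannelAttention",
    "SpatialAttention",
    "CBAM",
    "GuidedLowLevelBranch",
]


class AggregateHighLevels(nn.Module):
    """Bring x'_3 (x4) and x'_4 (x8) to stride 4, concatenate, 1x1-project."""

    def __init__(self, c3: int, c4: int, rng, out_ch: int = 64):
        super().__init__()
        self.proj = nn.Conv2d(c3 + c4, out_ch, 1, rng)

    def forward(self, e3, e4):
        u3 = upsample_bilinear(e3, 4)
        u4 = upsample_bilinear(e4, 8)
        if u3.shape[2:] != u4.shape[2:]:
            raise ShapeError(
                f"aggregated features disagree spatially: {u3.shape[2:]} vs {u4.shape[2:]}"
            )
        return self.proj(concat([u3, u4], axis=1))


class AttentionGate(nn.Module):
    """Additive attention gate: the guide *h* decides where *l* may pass.

        q = sigmoid(BN(Conv_h(h) + BN_l(Conv_l(l))))
        out = l * sigmoid(BN_g(Conv_g(q)))        (single-channel gate)

    Both nonlinearities are sigmoids; the final 1x1 conv reduces to one
    channel which is broadcast across the channels of *l*.
    """

    def __init__(self, c_h: int, c_l: int, rng, inter_ch: int | None = None):
        super().__init__()
        inter = max(c_h // 2, 1) if inter_ch is None else inter_ch
        self.conv_h = nn.Conv2d(c_h, inter, 1, rng)
        self.conv_l = nn.Conv2d(c_l, inter, 1, rng)
        self.bn_l = nn.BatchNorm2d(inter)
        self.bn_q = nn.BatchNorm2d(inter)
        self.conv_g = nn.Conv2d(inter, 1, 1, rng)
        self.bn_g = nn.BatchNorm2d(1)

    def gate_map(self, h, l) -> Tensor:
        if h.shape[2:] != l.shape[2:]:
            raise ShapeError(
                f"guide and low-level feature disagree spatially: "
                f"{h.shape[2:]} vs {l.shape[2:]}"
            )
        q = self.bn_q(self.conv_h(h) + self.bn_l(self.conv_l(l))).sigmoid()
        return self.bn_g(self.conv_g(q)).sigmoid()

    def forward(self, h, l):
        return l * self.gate_map(h, l)


class ChannelAttention(nn.Module):
    """Squeeze-and-excite style channel reweighting from global max+avg pools.

    Two shared 1x1 projections form a bottleneck of ``channels // reduction``;
    the second projection restores the input channel count, which is what
    makes the elementwise product with the input well-defined.
    ``out_channels`` can override the restored width for auditing the
    alternative (dimensionally inconsistent) reading, in which case the
    forward pass refuses the product.
    """

    def __init__(
        self,
        channels: int,
        rng,
        reduction: int = 16,
        out_channels: int | None = None,
    ):
        super().__init__()
        if channels < reduction:
            raise ConfigurationError(
                f"channel count {channels} smaller than reduction factor {reduction}"
            )
        out_ch = channels if out_channels is None else out_channels
        self.conv1 = nn.Conv2d(channels, channels // reduction, 1, rng)
        self.conv2 = nn.Conv2d(channels // reduction, out_ch, 1, rng)
        self.out_channels = out_ch
        self.in_channels = channels

    def weights(self, f) -> Tensor:
        pa = f.amax(axis=(2, 3), keepdims=True)
        pm = f.mean(axis=(2, 3), keepdims=True)
        z = self.conv2(self.conv1(pa).relu()) + self.conv2(self.conv1(pm).relu())
        return z.sigmoid()

    def forward(self, f):
        if self.out_channels != self.in_channels:
            raise ShapeError(
                "channel attention with a non-restoring second projection "
                f"({self.in_channels} -> {self.out_channels}) cannot be multiplied "
                "with its input"
            )
        return f * self.weights(f)


class SpatialAttention(nn.Module):
    """Per-pixel gate from the channel-wise max and mean maps.

    The two 1xHxW maps are summed and passed through a 7x7 conv (padding 3)
    and a sigmoid; the result reweights every channel of the input.
    """

    def __init__(self, rng, kernel: int = 7):
        super().__init__()
        self.conv = nn.Conv2d(1, 1, kernel, rng, padding=kernel // 2)

    def weights(self, f) -> Tensor:
        cm = f.amax(axis=1, keepdims=True)
        ca = f.mean(axis=1, keepdims=True)
        return self.conv(cm + ca).sigmoid()

    def forward(self, f):
        return f * self.weights(f)


class CBAM(nn.Module):
    """Channel attention, spatial attention, then a 3x3 conv block."""

    def __init__(self, channels: int, rng, reduction: int = 16):
        super().__init__()
        self.ca = ChannelAttention(channels, rng, reduction=reduction)
        self.sa = SpatialAttention(rng)
        self.conv_block = nn.ConvBNReLU(channels, channels, 3, rng)

    def forward(self, f):
        return self.conv_block(self.sa(self.ca(f)))


class GuidedLowLevelBranch(nn.Module):
    """The full low-level branch: aggregate -> gate -> merge -> CBAM -> logits.

    The gated low-level feature and the aggregate guide are combined by
    channel concatenation and a 1x1 projection (keeping both signals), then
    refined and upsampled x4 to full resolution for the plain 1x1 logit head.
    """

    def __init__(
        self,
        channels: tuple[int, int, int, int],
        num_classes: int,
        rng: np.random.Generator,
        guide_width: int = 64,
        reduction: int = 16,
    ):
        super().__init__()
        if num_classes < 2:
            raise ConfigurationError(f"need at least 2 classes, got {num_classes}")
        c1, _, c3, c4 = channels
        self.aggregate = AggregateHighLevels(c3, c4, rng, out_ch=guide_width)
        self.gate = AttentionGate(guide_width, c1, rng)
        self.merge = nn.Conv2d(c1 + guide_width, guide_width, 1, rng)
        self.cbam = CBAM(guide_width, rng, reduction=reduction)
        self.head = nn.Conv2d(guide_width, num_classes, 1, rng)

    def forward(self, x1, e3, e4):
        h = self.aggregate(e3, e4)
        g = self.gate(h, x1)
        m = self.merge(concat([g, h], axis=1))
        refined = self.cbam(m)
        return self.head(upsample_bilinear(refined, 4))
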