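"""Hierarchical vision-transformer encoder producing a 4-level feature pyramid.

The encoder follows the PVTv2 design: four stages of overlapping
convolutional patch embedding followed by transformer blocks with
spatial-reduction attention (keys/values computed on a strided-conv-reduced
token grid) and a convolutional feed-forward network (a depthwise 3x3
convolution between the two linear layers).  Stage *i* emits a feature map at
stride ``4 * 2**(i-1)`` of the input, with strictly increasing channel
counts, so a ``(3, H, W)`` image becomes the pyramid

    x1: (C1, H/4,  W/4)    x2: (C2, H/8,  W/8)
    x3: (C3, H/16, W/16)   x4: (C4, H/32, W/32)

Grayscale medical images are replicated to 3 channels before entering the
stem so that externally supplied 3-channel pretrained weights remain usable;
by default weights are randomly initialised (truncated normal for linear
layers, fan-out normal for convolutions) from the generator passed to
:func:`build_encoder`.

The ``"b2"`` variant is the published mid-size configuration; ``"tiny"`` is a
desk-scale variant added so that the full network trains in seconds on one
CPU core.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from . import nn
from .errors import ConfigurationError, ShapeError
from .nn import Tensor

__all__ = ["EncoderConfig", "FeaturePyramid", "PyramidEncoder", "build_encoder", "encode"]


class FeaturePyramid(NamedTuple):
    """Encoder stage outputs x1..x4 at strides 4/8/16/32 (NCHW tensors)."""

    x1: Tensor
    x2: Tensor
    x3: Tensor
    x4: Tensor


_VARIANTS: dict[str, dict] = {
    "b2": dict(
        channels=(64, 128, 320, 512),
        depths=(3, 4, 6, 3),
        heads=(1, 2, 5, 8),
        sr_ratios=(8, 4, 2, 1),
        mlp_ratios=(8, 8, 4, 4),
    ),
    "tiny": dict(
        channels=(16, 32, 64, 128),
        depths=(1, 1, 1, 1),
        heads=(1, 2, 4, 8),
        sr_ratios=(8, 4, 2, 1),
        mlp_ratios=(2, 2, 2, 2),
    ),
}


@dataclass(frozen=True)
class EncoderConfig:
    """Stage-wise layout of the pyramid encoder.

    ``strides`` are the patch-embedding strides per stage; their running
    product gives the stride schedule 4/8/16/32.
    """

    variant: str = "b2"
    channels: tuple[int, int, int, int] = (64, 128, 320, 512)
    depths: tuple[int, int, int, int] = (3, 4, 6, 3)
    heads: tuple[int, int, int, int] = (1, 2, 5, 8)
    sr_ratios: tuple[int, int, int, int] = (8, 4, 2, 1)
    mlp_ratios: tuple[int, int, int, int] = (8, 8, 4, 4)
    strides: tuple[int, int, int, int] = (4, 2, 2, 2)
    in_channels: int = 3
    qkv_bias: bool = True

    @staticmethod
    def from_variant(variant: str) -> "EncoderConfig":
        if variant not in _VARIANTS:
            raise ConfigurationError(
                f"unknown encoder variant {variant!r}; available: {sorted(_VARIANTS)}"
            )
        return EncoderConfig(variant=variant, **_VARIANTS[variant])

    def __post_init__(self):
        for name in ("channels", "depths", "heads", "sr_ratios", "mlp_ratios", "strides"):
            if len(getattr(self, name)) != 4:
                raise ConfigurationError(f"encoder needs exactly 4 stages; {name} has "
                                         f"{len(getattr(self, name))}")
        if self.in_channels != 3:
            raise ConfigurationError("the stem expects 3 input channels "
                                     "(grayscale inputs are replicated)")
        if list(self.channels) != sorted(set(self.channels)):
            raise ConfigurationError("stage channel counts must be strictly increasing")
        if any(s <= 0 for s in self.strides):
            raise ConfigurationError("stage strides must be positive")
        for c, h in zip(self.channels, self.heads):
            if c % h:
                raise ConfigurationError(f"channels {c} not divisible by heads {h}")


class _PatchEmbed(nn.Module):
    """Overlapping patch embedding: strided conv + layer norm over tokens."""

    def __init__(self, in_ch: int, dim: int, patch: int, stride: int, rng):
        super().__init__()
        self.proj = nn.Conv2d(in_ch, dim, patch, rng, stride=stride, padding=patch // 2)
        self.norm = nn.LayerNorm(dim)

    def forward(self, x):
        x = self.proj(x)
        B, C, H, W = x.shape
        tokens = x.reshape(B, C, H * W).transpose(0, 2, 1)
        return self.norm(tokens), H, W


class _Attention(nn.Module):
    """Multi-head self-attention with spatial reduction of keys/values."""

    def __init__(self, dim: int, heads: int, sr_ratio: int, rng, qkv_bias: bool):
        super().__init__()
        self.heads = heads
        self.head_dim = dim // heads
        self.scale = self.head_dim**-0.5
        self.q = nn.Linear(dim, dim, rng, bias=qkv_bias)
        self.k = nn.Linear(dim, dim, rng, bias=qkv_bias)
        self.v = nn.Linear(dim, dim, rng, bias=qkv_bias)
        self.proj = nn.Linear(dim, dim, rng)
        self.sr_ratio = sr_ratio
        if sr_ratio > 1:
            self.sr = nn.Conv2d(dim, dim, sr_ratio, rng, stride=sr_ratio)
            self.sr_norm = nn.LayerNorm(dim)

    def forward(self, x, H: int, W: int):
        B, N, C = x.shape
        h, d = self.heads, self.head_dim
        q = self.q(x).reshape(B, N, h, d).transpose(0, 2, 1, 3)
        if self.sr_ratio > 1:
            xs = x.transpose(0, 2, 1).reshape(B, C, H, W)
            xs = self.sr(xs)
            xs = xs.reshape(B, C, -1).transpose(0, 2, 1)
            xs = self.sr_norm(xs)
        else:
            xs = x
        M = xs.shape[1]
        k = self.k(xs).reshape(B, M, h, d).transpose(0, 2, 3, 1)
        v = self.v(xs).reshape(B, M, h, d).transpose(0, 2, 1, 3)
        attn = (q @ k * self.scale).softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, N, C)
        return self.proj(out)


class _ConvMLP(nn.Module):
    """fc -> depthwise 3x3 conv -> GELU -> fc (the convolutional FFN)."""

    def __init__(self, dim: int, hidden: int, rng):
        super().__init__()
        self.fc1 = nn.Linear(dim, hidden, rng)
        self.dwconv = nn.Conv2d(hidden, hidden, 3, rng, padding=1, groups=hidden)
        self.fc2 = nn.Linear(hidden, dim, rng)

    def forward(self, x, H: int, W: int):
        x = self.fc1(x)
        B, N, Ch = x.shape
        xm = x.transpose(0, 2, 1).reshape(B, Ch, H, W)
        xm = self.dwconv(xm)
        x = xm.reshape(B, Ch, N).transpose(0, 2, 1)
        return self.fc2(x.gelu())


class _Block(nn.Module):
    def __init__(self, dim, heads, sr_ratio, mlp_ratio, rng, qkv_bias):
        super().__init__()
        self.norm1 = nn.LayerNorm(dim)
        self.attn = _Attention(dim, heads, sr_ratio, rng, qkv_bias)
        self.norm2 = nn.LayerNorm(dim)
        self.mlp = _ConvMLP(dim, dim * mlp_ratio, rng)

    def forward(self, x, H, W):
        x = x + self.attn(self.norm1(x), H, W)
        x = x + self.mlp(self.norm2(x), H, W)
        return x


class _Stage(nn.Module):
    def __init__(self, in_ch, dim, patch, stride, depth, heads, sr, mlp_ratio, rng, qkv_bias):
        super().__init__()
        self.embed = _PatchEmbed(in_ch, dim, patch, stride, rng)
        self.blocks = [
            _Block(dim, heads, sr, mlp_ratio, rng, qkv_bias) for _ in range(depth)
        ]
        self.norm = nn.LayerNorm(dim)

    def forward(self, x):
        tokens, H, W = self.embed(x)
        for blk in self.blocks:
            tokens = blk(tokens, H, W)
        tokens = self.norm(tokens)
        B, N, C = tokens.shape
        return tokens.transpose(0, 2, 1).reshape(B, C, H, W)


class PyramidEncoder(nn.Module):
    """Four-stage pyramid encoder; ``forward`` returns a :class:`FeaturePyramid`."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        in_ch = config.in_channels
        self.stages = []
        for i in range(4):
            patch = 7 if i == 0 else 3
            self.stages.append(
                _Stage(
                    in_ch,
                    config.channels[i],
                    patch,
                    config.strides[i],
                    config.depths[i],
                    config.heads[i],
                    config.sr_ratios[i],
                    config.mlp_ratios[i],
                    rng,
                    config.qkv_bias,
                )
            )
            in_ch = config.channels[i]

    def forward(self, x: Tensor) -> FeaturePyramid:
        feats = []
        for stage in self.stages:
            x = stage(x)
            feats.append(x)
        return FeaturePyramid(*feats)

    def load_weights(self, path: str) -> None:
        """Load an encoder checkpoint from a local ``.npz`` state dict."""
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})


def build_encoder(config: EncoderConfig | str, seed: int = 0,
                  weights_path: str | None = None) -> PyramidEncoder:
    """Construct a pyramid encoder from a config or a variant name.

    Initialisation is deterministic in *seed*.  ``weights_path`` optionally
    loads a locally stored checkpoint (nothing is ever downloaded).
    """
    if isinstance(config, str):
        config = EncoderConfig.from_variant(config)
    enc = PyramidEncoder(config, np.random.default_rng(seed))
    if weights_path is not None:
        enc.load_weights(weights_path)
    return enc


def _check_divisible(H: int, W: int) -> None:
    for name, v in (("height", H), ("width", W)):
        if v % 32:
            raise ShapeError(f"image {name} {v} is not divisible by 32")


def prepare_image_batch(images: np.ndarray) -> Tensor:
    """Validate and promote an image batch to the (N, 3, H, W) tensor the
    encoder consumes.  Accepts (H, W), (N, H, W), (N, 1, H, W) or (N, 3, H, W);
    grayscale is replicated across 3 channels."""
    arr = np.asarray(images, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 3:
        arr = arr[:, None]
    if arr.ndim != 4:
        raise ShapeError(f"expected 2-D images, got array of ndim {arr.ndim}")
    if arr.shape[1] == 1:
        arr = np.repeat(arr, 3, axis=1)
    if arr.shape[1] != 3:
        raise ShapeError(f"expected 1 or 3 channels, got {arr.shape[1]}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image batch contains non-finite values")
    _check_divisible(arr.shape[2], arr.shape[3])
    return Tensor(arr)


def encode(images: np.ndarray, encoder: PyramidEncoder) -> FeaturePyramid:
    """Run the encoder on a batch of images (grayscale replicated to RGB)."""
    return encoder(prepare_image_batch(images))
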