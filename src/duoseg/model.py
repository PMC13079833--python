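"""Full dual-decoder segmentation network.

The network wires the pyramid encoder into two decoder branches: the
high-level context branch (producing logits ``P1`` from enhanced deep
features) and the low-level guided branch (producing logits ``P2`` from the
stride-4 feature gated by the enhanced deep features).  Either branch can be
ablated; the guided branch then falls back to gating with the *raw* deep
features, and the remaining branch's logits become the sole output.

At inference the two branch probability maps are summed,

    S = sigmoid(P1) + sigmoid(P2),

and the predicted label is the channel argmax of S.  Summing probabilities
(rather than logits) keeps S in [0, 2] with a monotone per-class ordering;
no post-processing is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from . import nn
from .context_branch import ContextBranch
from .encoder import EncoderConfig, PyramidEncoder, prepare_image_batch
from .errors import ConfigurationError
from .guided_branch import GuidedLowLevelBranch
from .nn import Tensor, no_grad

__all__ = ["ModelConfig", "BranchOutputs", "DualDecoderNet", "build_model",
           "predict_probs", "predict_labels"]


class BranchOutputs(NamedTuple):
    """Per-branch class-logit maps at full image resolution (either may be
    ``None`` when the corresponding branch is ablated)."""

    p1: Tensor | None
    p2: Tensor | None


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters of the full network."""

    encoder_variant: str = "b2"
    num_classes: int = 7
    use_context_branch: bool = True
    use_guided_branch: bool = True
    fusion_width: int = 64  # per-path channels in the cascaded fusion
    guide_width: int = 64  # channels of the aggregated guide h
    attention_reduction: int = 16  # channel-attention bottleneck factor
    encoder_weights: str | None = None  # optional local checkpoint path

    def __post_init__(self):
        if self.num_classes < 2:
            raise ConfigurationError(
                f"need at least 2 classes (background + 1), got {self.num_classes}"
            )
        if not (self.use_context_branch or self.use_guided_branch):
            raise ConfigurationError("at least one decoder branch must be enabled")


class DualDecoderNet(nn.Module):
    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        enc_cfg = EncoderConfig.from_variant(config.encoder_variant)
        self.encoder = PyramidEncoder(enc_cfg, rng)
        if config.encoder_weights:
            self.encoder.load_weights(config.encoder_weights)
        channels = enc_cfg.channels
        self.context_branch = (
            ContextBranch(channels, config.num_classes, rng,
                          fusion_width=config.fusion_width)
            if config.use_context_branch
            else None
        )
        self.guided_branch = (
            GuidedLowLevelBranch(channels, config.num_classes, rng,
                                 guide_width=config.guide_width,
                                 reduction=config.attention_reduction)
            if config.use_guided_branch
            else None
        )

    def forward(self, images) -> BranchOutputs:
        x = images if isinstance(images, Tensor) else prepare_image_batch(images)
        pyramid = self.encoder(x)
        p1 = None
        deep = (pyramid.x3, pyramid.x4)
        if self.context_branch is not None:
            p1, enhanced = self.context_branch(pyramid.x2, pyramid.x3, pyramid.x4)
            deep = (enhanced.x3, enhanced.x4)
        p2 = None
        if self.guided_branch is not None:
            p2 = self.guided_branch(pyramid.x1, *deep)
        return BranchOutputs(p1=p1, p2=p2)


def build_model(config: ModelConfig | None = None, seed: int = 0, **kwargs) -> DualDecoderNet:
    """Build the network with weights deterministically initialised by *seed*.

    Keyword arguments override :class:`ModelConfig` fields when no explicit
    config is given.
    """
    if config is None:
        config = ModelConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a config or keyword overrides, not both")
    return DualDecoderNet(config, np.random.default_rng(seed))


def predict_probs(model: DualDecoderNet, images) -> np.ndarray:
    """Combined per-class score map S (sum of branch sigmoids), (N,K,H,W)."""
    model.eval()
    with no_grad():
        out = model(images)
    score = None
    for logits in (out.p1, out.p2):
        if logits is None:
            continue
        s = logits.sigmoid().data
        score = s if score is None else score + s
    return score


def predict_labels(model: DualDecoderNet, images) -> np.ndarray:
    """Predicted integer label maps, (N, H, W): channel argmax of S."""
    return predict_probs(model, images).argmax(axis=1)
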