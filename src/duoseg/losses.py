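"""Training objectives: per-branch BCE+Dice and the joint dual-branch loss.

Supervision is channel-wise binary: every class (including an explicit
background channel) gets a sigmoid probability map compared against its
one-hot target with binary cross-entropy plus soft Dice, weighted 1:1.

The joint objective supervises both branch outputs *and* their elementwise
product:

    loss = L(sigmoid(P1), T) + L(sigmoid(P2), T) + L(sigmoid(P1) * sigmoid(P2), T)

The product of probabilities is itself a valid probability map (it is high
only where both branches agree), which is what makes the multiplicative term
meaningful; the ablation flag drops it, leaving the plain two-branch sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = ["LossTerms", "bce_dice_loss", "joint_loss"]

_EPS = 1e-7
_SMOOTH = 1.0


@dataclass
class LossTerms:
    """The three scalar terms of the joint objective (autodiff tensors)."""

    loss_p1: Tensor
    loss_p2: Tensor
    loss_mul: Tensor
    total: Tensor

    def as_floats(self) -> dict[str, float]:
        return {
            "loss_p1": float(self.loss_p1.data),
            "loss_p2": float(self.loss_p2.data),
            "loss_mul": float(self.loss_mul.data),
            "total": float(self.total.data),
        }


def _check_pair(prob: Tensor, target: np.ndarray) -> None:
    if prob.shape != target.shape:
        raise ValueError(f"probability shape {prob.shape} != target shape {target.shape}")
    pv = prob.data
    if pv.min() < -1e-5 or pv.max() > 1 + 1e-5:
        raise ValueError("probabilities must lie in [0, 1]")
    tv = np.asarray(target)
    if not np.isin(tv, (0, 1)).all():
        raise ValueError("targets must be one-hot (0/1) maps")


def bce_dice_loss(prob, target, smooth: float = _SMOOTH) -> Tensor:
    """Mean binary cross-entropy plus soft Dice loss, equal weights.

    ``prob`` is a (K, H, W) or (N, K, H, W) per-class probability map (values
    in [0, 1], clamped to [eps, 1-eps] inside the BCE); ``target`` the
    matching one-hot map.  The Dice term averages the per-(sample, class)
    soft Dice with additive smoothing ``smooth`` in both numerator and
    denominator.
    """
    prob = Tensor.as_tensor(prob)
    target = np.asarray(target, dtype=prob.data.dtype)
    _check_pair(prob, target)
    p = prob.clip(_EPS, 1.0 - _EPS)
    t = Tensor(target)
    bce = -(t * p.log() + (1.0 - t) * (1.0 - p).log()).mean()
    spatial = tuple(range(prob.ndim - 2, prob.ndim))  # (H, W) axes
    inter = (prob * t).sum(axis=spatial)
    denom = prob.sum(axis=spatial) + t.sum(axis=spatial)
    dice = ((inter * 2.0 + smooth) / (denom + smooth)).mean()
    return bce + (1.0 - dice)


def joint_loss(
    p1_logits,
    p2_logits,
    target,
    use_multiplicative: bool = True,
    smooth: float = _SMOOTH,
) -> LossTerms:
    """Joint dual-branch objective on raw logits.

    Both logit maps are passed through a sigmoid; each branch and (unless
    ablated) their product are scored with :func:`bce_dice_loss` against the
    same one-hot target.  ``total`` is the exact sum of the enabled terms.
    """
    p1_logits = Tensor.as_tensor(p1_logits)
    p2_logits = Tensor.as_tensor(p2_logits)
    if p1_logits.shape != p2_logits.shape:
        raise ValueError(
            f"branch logit shapes differ: {p1_logits.shape} vs {p2_logits.shape}"
        )
    p1 = p1_logits.sigmoid()
    p2 = p2_logits.sigmoid()
    loss_p1 = bce_dice_loss(p1, target, smooth=smooth)
    loss_p2 = bce_dice_loss(p2, target, smooth=smooth)
    if use_multiplicative:
        loss_mul = bce_dice_loss(p1 * p2, target, smooth=smooth)
        total = loss_p1 + loss_p2 + loss_mul
    else:
        loss_mul = Tensor(np.zeros((), dtype=p1.data.dtype))
        total = loss_p1 + loss_p2
    return LossTerms(loss_p1=loss_p1, loss_p2=loss_p2, loss_mul=loss_mul, total=total)
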