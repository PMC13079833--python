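"""Optimisation: AdamW with decoupled weight decay, plus seed derivation.

A single master seed drives every source of randomness in a training run
(weight init, shuffling, noise injection).  Sub-seeds are derived with a
splitmix64 mixer so that changing the master seed decorrelates all streams,
and each derived seed is reduced below 2**31 for portability.
"""

from __future__ import annotations

import numpy as np

from .modules import Parameter

__all__ = ["AdamW", "derive_seed"]

_GOLDEN = 0x9E3779B97F4A7C15
_MASK = (1 << 64) - 1


def _splitmix64(z: int) -> int:
    z = (z + _GOLDEN) & _MASK
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK
    return (z ^ (z >> 31)) & _MASK

_STREAMS = ("init", "shuffle", "noise", "phantom", "jitter")


def derive_seed(master: int, stream: str, index: int = 0) -> int:
    """Deterministic sub-seed (< 2**31) for a named randomness stream."""
    h = _splitmix64(master & _MASK)
    for token in (stream, str(index)):
        for ch in token:
            h = _splitmix64(h ^ ord(ch))
    return h % (2**31)


class AdamW:
    """Adam with decoupled weight decay (the optimiser used for training).

    Defaults mirror the training recipe: lr 3e-4, weight decay 1e-5,
    betas (0.9, 0.999).
    """

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 3e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-5,
    ):
        if lr < 0 or weight_decay < 0:
            raise ValueError("lr and weight_decay must be non-negative")
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            # decoupled decay: applied to the weights, not the gradient
            p.data = p.data * (1.0 - self.lr * self.weight_decay)
            p.data = p.data - self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
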