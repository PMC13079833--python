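"""Model capacity reporting: parameter counts and analytic forward cost.

Parameters are the number of trainable scalars.  The forward cost is
accumulated analytically inside the compute primitives during a single
profiling forward pass: a convolution contributes
``k^2 * C_in/groups * C_out * H_out * W_out`` multiply–accumulates, a matrix
product the product of its output shape with the contracted dimension
(linear layers and the attention score/value products).  One fused
multiply–add counts as one operation; the doubled (2 ops per MAC) figure is
also reported for comparison against conventions that count it as two.
Normalisations, activations and interpolation are not counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ShapeError
from .model import DualDecoderNet
from .nn import Tensor, mac_counter, no_grad

__all__ = ["ModelSummary", "model_summary"]


@dataclass
class ModelSummary:
    """Capacity of a model at a stated input size."""

    input_size: int
    param_total: int
    param_breakdown: dict[str, int]
    mac_total: int
    mac_by_layer_type: dict[str, int]

    @property
    def params_millions(self) -> float:
        return self.param_total / 1e6

    @property
    def macs_g(self) -> float:
        """Forward cost in G, one fused multiply–add = one operation."""
        return self.mac_total / 1e9

    @property
    def flops_g_double(self) -> float:
        """Forward cost in G counting multiply and add separately."""
        return 2 * self.mac_total / 1e9

    def __str__(self) -> str:
        lines = [
            f"input size          : {self.input_size} x {self.input_size}",
            f"trainable parameters: {self.param_total:,} ({self.params_millions:.2f} M)",
            f"forward MACs        : {self.mac_total:,} ({self.macs_g:.2f} G; "
            f"{self.flops_g_double:.2f} G at 2 ops/MAC)",
            "parameter breakdown :",
        ]
        for name, n in sorted(self.param_breakdown.items(), key=lambda kv: -kv[1]):
            lines.append(f"  {name:<16s} {n:>12,} ({n / 1e6:.2f} M)")
        return "\n".join(lines)


def model_summary(model: DualDecoderNet, input_size: int = 256) -> ModelSummary:
    """Count trainable parameters and analytic MACs of one forward pass."""
    if input_size % 32:
        raise ShapeError(f"input size {input_size} not divisible by 32")
    breakdown: dict[str, int] = {}
    for name in ("encoder", "context_branch", "guided_branch"):
        comp = getattr(model, name, None)
        if comp is not None:
            breakdown[name] = comp.num_parameters()
    total = model.num_parameters()
    assert total == sum(breakdown.values())
    model.eval()
    counter: dict[str, int] = {}
    x = Tensor(np.zeros((1, 3, input_size, input_size), dtype=np.float32))
    with no_grad(), mac_counter(counter):
        model(x)
    mac_total = counter.pop("total", 0)
    return ModelSummary(
        input_size=input_size,
        param_total=total,
        param_breakdown=breakdown,
        mac_total=mac_total,
        mac_by_layer_type=dict(counter),
    )
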