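"""Layer building blocks on top of the autodiff tensor.

Layers follow the familiar module pattern: a :class:`Module` owns parameters
and sub-modules, exposes ``parameters()`` / ``named_parameters()``, and has a
training flag toggled by ``train()`` / ``eval()``.  Every layer that owns
weights takes a ``numpy.random.Generator`` at construction, so model
initialisation is fully determined by the seed that created the generator.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import Tensor, conv2d, mac_scope, maxpool2d

__all__ = [
    "Module",
    "Parameter",
    "Sequential",
    "Conv2d",
    "Linear",
    "BatchNorm2d",
    "LayerNorm",
    "MaxPool2d",
    "ReLU",
    "GELU",
    "Identity",
    "ConvBNReLU",
    "trunc_normal_",
]


class Parameter(Tensor):
    """A tensor registered as a trainable weight of a module."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


def trunc_normal_(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) samples truncated to ±2·std by resampling."""
    out = rng.normal(0.0, std, size=shape)
    bad = np.abs(out) > 2 * std
    while bad.any():
        out[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(out) > 2 * std
    return out


class Module:
    def __init__(self):
        self.training = True

    # -- registry -------------------------------------------------------------
    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix, self
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield from val.named_modules(f"{prefix}.{name}" if prefix else name)
            elif isinstance(val, (list, tuple)):
                for i, v in enumerate(val):
                    if isinstance(v, Module):
                        sub = f"{prefix}.{name}.{i}" if prefix else f"{name}.{i}"
                        yield from v.named_modules(sub)

    def named_parameters(self) -> Iterator[tuple[str, Parameter]]:
        for mod_name, mod in self.named_modules():
            for name, val in vars(mod).items():
                if isinstance(val, Parameter):
                    yield (f"{mod_name}.{name}" if mod_name else name), val

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True) -> "Module":
        for _, m in self.named_modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- state ----------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters()}
        for mod_name, mod in self.named_modules():
            for name, val in vars(mod).items():
                if name.startswith("running_") and isinstance(val, np.ndarray):
                    state[f"{mod_name}.{name}" if mod_name else name] = val
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_dict()
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing keys in state dict: {sorted(missing)[:5]} ...")
        for mod_name, mod in self.named_modules():
            for name, val in vars(mod).items():
                key = f"{mod_name}.{name}" if mod_name else name
                if isinstance(val, Parameter):
                    if state[key].shape != val.data.shape:
                        raise ValueError(f"shape mismatch for {key}")
                    val.data = np.asarray(state[key], dtype=val.data.dtype)
                elif name.startswith("running_") and isinstance(val, np.ndarray):
                    setattr(mod, name, np.asarray(state[key], dtype=val.dtype))

    def __call__(self, *args, **kwargs):
        with mac_scope(type(self).__name__):
            return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class GELU(Module):
    def forward(self, x):
        return x.gelu()


class MaxPool2d(Module):
    def __init__(self, kernel: int):
        super().__init__()
        self.kernel = kernel

    def forward(self, x):
        return maxpool2d(x, self.kernel)


class Conv2d(Module):
    """2-D convolution with kaiming fan-out initialisation."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
        dilation: int = 1,
        groups: int = 1,
        bias: bool = True,
    ):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        self.stride, self.padding, self.dilation, self.groups = (
            stride,
            padding,
            dilation,
            groups,
        )
        fan_out = kernel_size * kernel_size * out_channels // groups
        std = float(np.sqrt(2.0 / fan_out))
        self.weight = Parameter(
            rng.normal(0.0, std, (out_channels, in_channels // groups, kernel_size, kernel_size))
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        return conv2d(
            x,
            self.weight,
            self.bias,
            stride=self.stride,
            padding=self.padding,
            dilation=self.dilation,
            groups=self.groups,
        )


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator,
        bias: bool = True,
    ):
        super().__init__()
        self.weight = Parameter(trunc_normal_(rng, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x):
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x):
        C = x.shape[1]
        if self.training:
            m = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - m
            v = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbias = n / max(n - 1, 1)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean
                + self.momentum * m.data.reshape(C)
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var
                + self.momentum * unbias * v.data.reshape(C)
            ).astype(np.float32)
            xhat = xc / (v + self.eps).sqrt()
        else:
            m = self.running_mean.reshape(1, C, 1, 1)
            v = self.running_var.reshape(1, C, 1, 1)
            xhat = (x - m) * (1.0 / np.sqrt(v + self.eps))
        return xhat * self.weight.reshape(1, C, 1, 1) + self.bias.reshape(1, C, 1, 1)

    def set_identity(self) -> None:
        """Force an exact identity map in eval mode (used by analytic tests)."""
        self.eps = 0.0
        self.weight.data = np.ones_like(self.weight.data)
        self.bias.data = np.zeros_like(self.bias.data)
        self.running_mean = np.zeros_like(self.running_mean)
        self.running_var = np.ones_like(self.running_var)


class LayerNorm(Module):
    """Normalisation over the last axis (token channel dimension)."""

    def __init__(self, num_features: int, eps: float = 1e-6):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))

    def forward(self, x):
        m = x.mean(axis=-1, keepdims=True)
        xc = x - m
        v = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (v + self.eps).sqrt() * self.weight + self.bias


class ConvBNReLU(Module):
    """Conv → BatchNorm → ReLU, the workhorse block of both decoder branches."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int | None = None,
        dilation: int = 1,
    ):
        super().__init__()
        if padding is None:
            padding = dilation * (kernel_size - 1) // 2
        self.conv = Conv2d(
            in_channels,
            out_channels,
            kernel_size,
            rng,
            stride=stride,
            padding=padding,
            dilation=dilation,
            bias=False,
        )
        self.bn = BatchNorm2d(out_channels)

    def forward(self, x):
        return self.bn(self.conv(x)).relu()
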