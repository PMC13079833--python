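"""Reverse-mode automatic differentiation on numpy arrays.

The engine is deliberately small: a :class:`Tensor` wraps an ``ndarray``,
records the operations applied to it, and :meth:`Tensor.backward` walks the
recorded graph in reverse topological order accumulating gradients.  Only the
primitives the segmentation network needs are provided (broadcast
arithmetic, matmul, 2-D convolution, pooling, bilinear upsampling, the usual
activations and reductions).  Everything is deterministic: there are no
stochastic layers and no implicit global RNG.

Multiply–accumulate accounting
------------------------------
``conv2d`` and ``matmul`` are the only primitives that perform dense
multiply–accumulate work; when a :func:`mac_counter` context is active they
report their analytic MAC counts (one fused multiply–add counted once) into
it.  This is what the model-summary machinery uses, so the reported forward
cost is exact layer arithmetic, not a timing estimate.
"""

from __future__ import annotations

import contextlib
from typing import Sequence

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor",
    "no_grad",
    "mac_counter",
    "concat",
    "conv2d",
    "maxpool2d",
    "upsample_bilinear",
]

_grad_enabled = True
_active_mac_counters: list[dict] = []


@contextlib.contextmanager
def no_grad():
    """Disable graph recording inside the context (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


@contextlib.contextmanager
def mac_counter(counter: dict):
    """Accumulate multiply–accumulate counts of conv/matmul ops into *counter*.

    ``counter`` is a dict; counts are added under ``"total"`` and under the
    label currently pushed by the layer executing (see ``modules.Module``).
    """
    counter.setdefault("total", 0)
    _active_mac_counters.append(counter)
    try:
        yield counter
    finally:
        _active_mac_counters.remove(counter)


_current_scope: list[str] = []


@contextlib.contextmanager
def mac_scope(label: str):
    _current_scope.append(label)
    try:
        yield
    finally:
        _current_scope.pop()


def _record_macs(n: int) -> None:
    if not _active_mac_counters:
        return
    label = _current_scope[-1] if _current_scope else "<unscoped>"
    for c in _active_mac_counters:
        c["total"] = c.get("total", 0) + int(n)
        c[label] = c.get(label, 0) + int(n)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum *grad* down to *shape* (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    # -- basic properties -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff -------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep graphs overflow recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free graph-interior gradients lazily is unnecessary at our sizes
        return None

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy() if g.base is not None or not g.flags.owndata else g
        else:
            self.grad = self.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        if isinstance(other, (int, float)):  # scalar fast path, keeps dtype
            out_data = self.data + other

            def backward_s(g):
                if self.requires_grad:
                    self._accum(g)

            return Tensor._make(out_data, (self,), backward_s)
        other = Tensor.as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            out_data = self.data * other

            def backward_s(g):
                if self.requires_grad:
                    self._accum(g * other)

            return Tensor._make(out_data, (self,), backward_s)
        other = Tensor.as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = Tensor.as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
                )

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), backward)

    # -- elementwise functions ------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(out_data, (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp; the gradient passes through strictly inside the interval."""
        out_data = np.clip(self.data, lo, hi)
        mask = (self.data > lo) & (self.data < hi)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        x = self.data
        out_data = np.empty_like(x)
        pos = x >= 0
        out_data[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out_data[~pos] = ex / (1.0 + ex)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def gelu(self):
        # exact (erf) form; scalar constants stay python floats to keep dtype
        x = self.data
        cdf = 0.5 * (1.0 + erf(x * 0.7071067811865476))
        out_data = x * cdf

        def backward(g):
            if self.requires_grad:
                pdf = np.exp(-0.5 * x * x) * 0.3989422804014327
                self._accum(g * (cdf + x * pdf))

        return Tensor._make(out_data, (self,), backward)

    def softmax(self, axis: int):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                self._accum(out_data * (g - dot))

        return Tensor._make(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).astype(self.dtype))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).astype(self.dtype))

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def amax(self, axis, keepdims: bool = False):
        """Max reduction; gradient split evenly between tied maxima."""
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == out_data).astype(self.dtype)
        mask /= mask.sum(axis=axis, keepdims=True)
        res = out_data if keepdims else np.squeeze(out_data, axis=axis)

        def backward(g):
            if self.requires_grad:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(mask * gg)

        return Tensor._make(res, (self,), backward)

    # -- shape manipulation ---------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[idx] = g
                self._accum(full)

        return Tensor._make(out_data, (self,), backward)

    # -- matmul ---------------------------------------------------------------
    def matmul(self, other: "Tensor"):
        other = Tensor.as_tensor(other)
        out_data = self.data @ other.data
        # MACs: product over output shape times the contracted dimension
        _record_macs(out_data.size * self.data.shape[-1])

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    def __matmul__(self, other):
        return self.matmul(other)


# -- multi-input / structural ops ---------------------------------------------


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tensors, backward)


def _conv_slices(k: int, dil: int, stride: int, n_out: int):
    """Slice of the padded input matching kernel tap *a* for every output pos."""
    return [slice(a * dil, a * dil + (n_out - 1) * stride + 1, stride) for a in range(k)]


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    dilation: int = 1,
    groups: int = 1,
) -> Tensor:
    """2-D cross-correlation, NCHW layout, square kernel/stride/padding.

    Implemented by gathering kernel-tap slices into a column tensor and
    contracting with BLAS; the backward pass scatters through the same
    (strided, hence fast) slices.
    """
    x = Tensor.as_tensor(x)
    N, Cin, H, W = x.data.shape
    Cout, Cin_g, kh, kw = weight.data.shape
    if Cin_g * groups != Cin:
        raise ValueError(
            f"conv2d channel mismatch: input has {Cin} channels, "
            f"weight expects {Cin_g * groups}"
        )
    Ho = (H + 2 * padding - dilation * (kh - 1) - 1) // stride + 1
    Wo = (W + 2 * padding - dilation * (kw - 1) - 1) // stride + 1
    if Ho <= 0 or Wo <= 0:
        raise ValueError("conv2d: non-positive output size")
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        if padding
        else x.data
    )
    hs = _conv_slices(kh, dilation, stride, Ho)
    ws = _conv_slices(kw, dilation, stride, Wo)
    cols = np.empty((N, Cin, kh, kw, Ho, Wo), dtype=x.data.dtype)
    for a in range(kh):
        for b in range(kw):
            cols[:, :, a, b] = xp[:, :, hs[a], ws[b]]
    # (N, g, Cin_g*kh*kw, Ho*Wo)
    cols_m = cols.reshape(N, groups, Cin_g * kh * kw, Ho * Wo)
    w_m = weight.data.reshape(groups, Cout // groups, Cin_g * kh * kw)
    out = np.matmul(w_m, cols_m)  # (N, g, Cout_g, L)
    out = out.reshape(N, Cout, Ho, Wo)
    if bias is not None:
        out = out + bias.data.reshape(1, Cout, 1, 1)
    _record_macs(N * Cout * Ho * Wo * Cin_g * kh * kw)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        g_m = g.reshape(N, groups, Cout // groups, Ho * Wo)
        if weight.requires_grad:
            gw = np.matmul(g_m, cols_m.swapaxes(-1, -2)).sum(axis=0)
            weight._accum(gw.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = np.matmul(np.swapaxes(w_m, -1, -2), g_m)  # (N,g,K,L)
            gcols = gcols.reshape(N, Cin, kh, kw, Ho, Wo)
            gxp = np.zeros_like(xp)
            for a in range(kh):
                for b in range(kw):
                    gxp[:, :, hs[a], ws[b]] += gcols[:, :, a, b]
            if padding:
                gxp = gxp[:, :, padding : padding + H, padding : padding + W]
            x._accum(gxp)

    return Tensor._make(out, parents, backward)


def maxpool2d(x: Tensor, kernel: int) -> Tensor:
    """Non-overlapping max pooling (window == stride == *kernel*)."""
    x = Tensor.as_tensor(x)
    N, C, H, W = x.data.shape
    if H % kernel or W % kernel:
        raise ValueError(
            f"maxpool2d: spatial size ({H},{W}) not divisible by window {kernel}"
        )
    Ho, Wo = H // kernel, W // kernel
    xr = x.data.reshape(N, C, Ho, kernel, Wo, kernel)
    out = xr.max(axis=(3, 5))
    mask = xr == out[:, :, :, None, :, None]
    # split gradient between ties so that constant inputs stay well-behaved
    cnt = mask.sum(axis=(3, 5), keepdims=True)
    maskf = mask / cnt

    def backward(g):
        if x.requires_grad:
            gr = maskf * g[:, :, :, None, :, None]
            x._accum(gr.reshape(N, C, H, W).astype(x.dtype))

    return Tensor._make(out, (x,), backward)


_interp_cache: dict[tuple, np.ndarray] = {}


def _interp_matrix(n_in: int, scale: int, dtype) -> np.ndarray:
    """(n_in*scale, n_in) bilinear interpolation matrix, half-pixel centres."""
    key = (n_in, scale, np.dtype(dtype).name)
    m = _interp_cache.get(key)
    if m is not None:
        return m
    n_out = n_in * scale
    src = (np.arange(n_out) + 0.5) / scale - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = src - i0
    m = np.zeros((n_out, n_in), dtype=dtype)
    m[np.arange(n_out), i0] += 1.0 - w1
    m[np.arange(n_out), i1] += w1
    _interp_cache[key] = m
    return m


def upsample_bilinear(x: Tensor, scale: int) -> Tensor:
    """Bilinear upsampling by an integer factor (half-pixel alignment)."""
    x = Tensor.as_tensor(x)
    if scale < 1:
        raise ValueError("upsample scale must be a positive integer")
    if scale == 1:
        return x
    N, C, H, W = x.data.shape
    A = _interp_matrix(H, scale, x.data.dtype)
    B = _interp_matrix(W, scale, x.data.dtype)
    out = A @ x.data @ B.T  # broadcast over (N, C)

    def backward(g):
        if x.requires_grad:
            x._accum(A.T @ g @ B)

    return Tensor._make(out, (x,), backward)
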