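"""Independent brute-force re-implementations of the network's primitives.

These helpers share *weights* with the modules under test but none of the
implementation: convolution goes through scipy's correlate2d on explicitly
dilated kernels, pooling and bilinear interpolation are per-pixel loops.
Used to hand-compose reference outputs for the attention/gating blocks.
"""

import numpy as np
from scipy.signal import correlate2d


def np_conv2d(x, weight, bias=None, stride=1, padding=0, dilation=1, groups=1):
    """(N,C,H,W) cross-correlation via scipy, one (out, in) channel pair at a time."""
    x = np.asarray(x, dtype=np.float64)
    w = np.asarray(weight, dtype=np.float64)
    N, Cin, H, W = x.shape
    Cout, Cin_g, k, _ = w.shape
    if dilation > 1:  # insert zeros between kernel taps
        kd = dilation * (k - 1) + 1
        wd = np.zeros((Cout, Cin_g, kd, kd))
        wd[:, :, ::dilation, ::dilation] = w
        w, k = wd, kd
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Ho = (H + 2 * padding - k) // stride + 1
    Wo = (W + 2 * padding - k) // stride + 1
    out = np.zeros((N, Cout, Ho, Wo))
    cpg_in, cpg_out = Cin // groups, Cout // groups
    for n in range(N):
        for co in range(Cout):
            g = co // cpg_out
            acc = np.zeros((xp.shape[2] - k + 1, xp.shape[3] - k + 1))
            for ci_local in range(Cin_g):
                ci = g * cpg_in + ci_local
                acc += correlate2d(xp[n, ci], w[co, ci_local], mode="valid")
            out[n, co] = acc[::stride, ::stride][:Ho, :Wo]
    if bias is not None:
        out += np.asarray(bias, dtype=np.float64).reshape(1, Cout, 1, 1)
    return out


def np_bn_eval(x, bn):
    """Evaluation-mode batch norm from a BatchNorm2d module's state."""
    C = x.shape[1]
    m = bn.running_mean.reshape(1, C, 1, 1)
    v = bn.running_var.reshape(1, C, 1, 1)
    g = bn.weight.data.reshape(1, C, 1, 1)
    b = bn.bias.data.reshape(1, C, 1, 1)
    return (np.asarray(x, dtype=np.float64) - m) / np.sqrt(v + bn.eps) * g + b


def np_relu(x):
    return np.maximum(x, 0.0)


def np_sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


def np_softmax_channels(x):
    z = np.asarray(x, dtype=np.float64)
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def np_maxpool(x, k):
    N, C, H, W = x.shape
    out = np.zeros((N, C, H // k, W // k))
    for i in range(H // k):
        for j in range(W // k):
            out[:, :, i, j] = x[:, :, i * k : (i + 1) * k, j * k : (j + 1) * k].max(
                axis=(2, 3)
            )
    return out


def np_upsample_bilinear(x, scale):
    """Per-pixel bilinear interpolation with half-pixel centre alignment."""
    x = np.asarray(x, dtype=np.float64)
    N, C, H, W = x.shape
    Ho, Wo = H * scale, W * scale
    out = np.zeros((N, C, Ho, Wo))
    for io in range(Ho):
        sy = min(max((io + 0.5) / scale - 0.5, 0.0), H - 1.0)
        y0 = int(np.floor(sy))
        y1 = min(y0 + 1, H - 1)
        wy = sy - y0
        for jo in range(Wo):
            sx = min(max((jo + 0.5) / scale - 0.5, 0.0), W - 1.0)
            x0 = int(np.floor(sx))
            x1 = min(x0 + 1, W - 1)
            wx = sx - x0
            out[:, :, io, jo] = (
                (1 - wy) * (1 - wx) * x[:, :, y0, x0]
                + (1 - wy) * wx * x[:, :, y0, x1]
                + wy * (1 - wx) * x[:, :, y1, x0]
                + wy * wx * x[:, :, y1, x1]
            )
    return out


def np_convbnrelu(block, x, stride=None):
    """Reference evaluation of a ConvBNReLU module (eval mode)."""
    conv = block.conv
    y = np_conv2d(
        x,
        conv.weight.data,
        None if conv.bias is None else conv.bias.data,
        stride=conv.stride,
        padding=conv.padding,
        dilation=conv.dilation,
        groups=conv.groups,
    )
    return np_relu(np_bn_eval(y, block.bn))


def np_plain_conv(conv, x):
    return np_conv2d(
        x,
        conv.weight.data,
        None if conv.bias is None else conv.bias.data,
        stride=conv.stride,
        padding=conv.padding,
        dilation=conv.dilation,
        groups=conv.groups,
    )


def randomize_bn_stats(module, rng):
    """Give every BatchNorm2d in *module* non-trivial eval-mode statistics so
    composition oracles exercise the affine part of the normalisation."""
    for _, m in module.named_modules():
        if hasattr(m, "running_mean"):
            C = m.running_mean.shape[0]
            m.running_mean = rng.normal(0.0, 0.3, C).astype(np.float32)
            m.running_var = rng.uniform(0.5, 1.5, C).astype(np.float32)
            m.weight.data = rng.uniform(0.7, 1.3, C).astype(np.float32)
            m.bias.data = rng.normal(0.0, 0.2, C).astype(np.float32)
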