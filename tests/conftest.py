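import numpy as np
import pytest

from duoseg.nn import Module, Parameter, Tensor


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def to_float64(module: Module) -> Module:
    """Cast a module's parameters (and running stats) to float64 in place —
    used by numerical gradient checks, which need small finite-difference
    error."""
    for _, p in module.named_parameters():
        p.data = p.data.astype(np.float64)
    for _, m in module.named_modules():
        for name, val in vars(m).items():
            if name.startswith("running_") and isinstance(val, np.ndarray):
                setattr(m, name, val.astype(np.float64))
    return module


def numerical_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar-valued f at x (float64)."""
    x = x.astype(np.float64)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp = x.copy()
        xp[i] += eps
        xm = x.copy()
        xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
    return g


def assert_grad_matches(f, x: np.ndarray, rtol: float = 1e-5, atol: float = 1e-7):
    """Check the autodiff gradient of scalar f against finite differences."""
    xt = Tensor(x.astype(np.float64), requires_grad=True)
    out = f(xt)
    out.backward()
    num = numerical_grad(lambda a: float(f(Tensor(a)).data), x)
    np.testing.assert_allclose(xt.grad, num, rtol=rtol, atol=atol)
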