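import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def finite_diff_params(layer, loss_fn, n_checks=15, eps=1e-5, tol=1e-4):
    """Central finite-difference check of a layer's accumulated parameter
    gradients against ``loss_fn`` (which re-runs the forward pass)."""
    worst = 0.0
    for name, p in layer.params.items():
        it = np.nditer(p, flags=["multi_index"])
        for _ in range(min(p.size, n_checks)):
            mi = it.multi_index
            old = p[mi]
            p[mi] = old + eps
            lp = loss_fn()
            p[mi] = old - eps
            lm = loss_fn()
            p[mi] = old
            num = (lp - lm) / (2 * eps)
            rel = abs(num - layer.grads[name][mi]) / max(1e-6, abs(num))
            worst = max(worst, rel)
            it.iternext()
    assert worst <= tol, f"parameter gradient mismatch: rel err {worst:.2e}"
    return worst


def finite_diff_input(x, grad, loss_fn, n_checks=20, eps=1e-5, tol=1e-4):
    """Same check for the gradient w.r.t. an input array (modified in place)."""
    worst = 0.0
    it = np.nditer(x, flags=["multi_index"])
    for _ in range(min(x.size, n_checks)):
        mi = it.multi_index
        old = x[mi]
        x[mi] = old + eps
        lp = loss_fn()
        x[mi] = old - eps
        lm = loss_fn()
        x[mi] = old
        num = (lp - lm) / (2 * eps)
        rel = abs(num - grad[mi]) / max(1e-6, abs(num))
        worst = max(worst, rel)
        it.iternext()
    assert worst <= tol, f"input gradient mismatch: rel err {worst:.2e}"
    return worst
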