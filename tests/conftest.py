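"""Shared fixtures and independent numerical oracles for the test suite."""

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def numeric_grad(f, arr, eps=1e-6):
    """Central finite-difference gradient of scalar ``f`` w.r.t. ``arr``."""
    g = np.zeros_like(arr, dtype=np.float64)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = arr[idx]
        arr[idx] = orig + eps
        fp = f()
        arr[idx] = orig - eps
        fm = f()
        arr[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
    return g


def rel_err(a, b, atol=1e-8):
    # relative error with an absolute floor: exactly-zero gradients (e.g.
    # biases under batch-norm, where any shift is normalized away) are
    # dominated by finite-difference noise, not by relative disagreement
    diff = max(np.abs(a - b).max() - atol, 0.0)
    return diff / max(np.abs(b).max(), atol)


def naive_conv2d_same(x, W, b):
    """Six-nested-loop same-padded stride-1 cross-correlation oracle."""
    B, Cin, H, Wd = x.shape
    Cout, _, kh, kw = W.shape
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    out = np.zeros((B, Cout, H, Wd))
    for bi in range(B):
        for co in range(Cout):
            for r in range(H):
                for c in range(Wd):
                    acc = b[co]
                    for ci in range(Cin):
                        for dr in range(kh):
                            for dc in range(kw):
                                acc += W[co, ci, dr, dc] * xp[bi, ci, r + dr, c + dc]
                    out[bi, co, r, c] = acc
    return out
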