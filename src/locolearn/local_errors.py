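"""Layer-local error generation and weight updates.

Each hidden layer ``i`` carries a local classifier with a fixed random
matrix ``M_i`` (C x N) mapping the layer's flattened activity ``y`` to
class scores ``s = M_i y`` (no bias).  The score error
``e_s = dE/ds`` is projected back through a feedback matrix ``K_i``
(N x C) and masked by the activation derivative:

    e_y = (K_i e_s) * y'

which yields the weight and bias updates ``dW = -eta e_y x^T`` and
``db = -eta e_y``.  Four feedback modes:

``SYM``
    ``K = M^T`` — the update is exact gradient descent on the local loss.
``SCFB``
    ``sign(K) = sign(M^T)`` with independent fixed magnitudes.
``INDEP``
    ``K`` fixed, random, and independent of ``M`` (a failure mode: the
    fixed classifier cannot align with it, so learning collapses to
    chance).
``TLC``
    ``K = M^T`` and ``M`` itself trained by gradient descent on the local
    loss.

Batch-norm scale/shift parameters, when present, are trained with exact
local gradients of the same loss.  Mini-batch updates average the
per-sample gradients.  Dropped units (mask = 0) receive exactly zero
updates on all incoming and outgoing weights for that iteration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.special import log_softmax, softmax

from .net_core import (
    LayerGrads,
    LayerSpec,
    LayerState,
    LayerTrace,
    backward_through_layer,
)

__all__ = [
    "MODES",
    "LocalLoop",
    "scores",
    "loss_and_escore",
    "backproject",
    "layer_update",
    "tlc_update",
    "bn_scale_update",
    "local_gradients",
]

MODES = ("SYM", "SCFB", "INDEP", "TLC")


@dataclass
class LocalLoop:
    """One layer's local error loop: classifier ``M``, feedback ``K``
    (None when it is implicitly ``M^T``), feedback mode, and loss."""

    M: np.ndarray
    K: Optional[np.ndarray] = None
    mode: str = "SYM"
    loss_kind: str = "cross_entropy"

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode in ("SYM", "TLC"):
            if self.K is not None:
                raise ValueError(f"{self.mode} mode never materializes K separately")
        elif self.K is None:
            raise ValueError(f"{self.mode} mode requires an explicit K")
        if self.K is not None and self.K.shape != self.M.T.shape:
            raise ValueError(
                f"K shape {self.K.shape} must equal M.T shape {self.M.T.shape}"
            )

    @property
    def K_effective(self) -> np.ndarray:
        return self.M.T if self.K is None else self.K

    @property
    def trainable(self) -> bool:
        return self.mode == "TLC"


def scores(M: np.ndarray, y_flat: np.ndarray) -> np.ndarray:
    """Class scores ``s = M y`` per sample (no bias term)."""
    y_flat = np.atleast_2d(y_flat)
    if y_flat.shape[1] != M.shape[1]:
        raise ValueError(f"activity width {y_flat.shape[1]} != M columns {M.shape[1]}")
    return y_flat @ M.T


def loss_and_escore(s: np.ndarray, t: np.ndarray, loss_kind: str = "cross_entropy"
                    ) -> Tuple[np.ndarray, np.ndarray]:
    """Per-sample loss ``E`` and its score derivative ``e_s = dE/ds``.

    ``cross_entropy``: ``E = -log softmax(s)_t``, ``e_s = softmax(s) -
    onehot(t)``.  ``square_hinge``: ``E = sum_{c != t} max(0, 1 - s_t +
    s_c)^2`` with its exact derivative.
    """
    s = np.atleast_2d(s)
    if not np.all(np.isfinite(s)):
        raise FloatingPointError("non-finite class scores")
    t = np.asarray(t, dtype=np.intp).ravel()
    B, C = s.shape
    if t.min() < 0 or t.max() >= C:
        raise ValueError("labels out of range")
    rows = np.arange(B)
    if loss_kind == "cross_entropy":
        E = -log_softmax(s, axis=1)[rows, t]
        e_s = softmax(s, axis=1)
        e_s[rows, t] -= 1.0
    elif loss_kind == "square_hinge":
        margin = np.maximum(0.0, 1.0 - s[rows, t][:, None] + s)
        margin[rows, t] = 0.0
        E = (margin ** 2).sum(axis=1)
        e_s = 2.0 * margin
        e_s[rows, t] = -e_s.sum(axis=1)
    else:
        raise ValueError(f"unknown loss {loss_kind!r}")
    return E, e_s


def backproject(loop: LocalLoop, e_s: np.ndarray, yprime_masked: np.ndarray
                ) -> np.ndarray:
    """Layer error ``e_y = (K_eff e_s) * y'`` with the feedback matrix of
    the loop's mode (``M^T`` for SYM/TLC, the stored ``K`` otherwise).
    ``yprime_masked`` is the ReLU derivative mask with the (scaled)
    dropout mask already applied."""
    return (np.atleast_2d(e_s) @ loop.K_effective.T) * yprime_masked


def layer_update(e_y: np.ndarray, x: np.ndarray, lr: float
                 ) -> Tuple[np.ndarray, np.ndarray]:
    """Dense update ``dW = -eta * mean_batch outer(e_y, x)``,
    ``db = -eta * mean_batch e_y``."""
    e_y = np.atleast_2d(e_y)
    x = np.atleast_2d(x)
    B = e_y.shape[0]
    return -lr * (e_y.T @ x) / B, -lr * e_y.mean(axis=0)


def tlc_update(loop: LocalLoop, e_s: np.ndarray, y_flat: np.ndarray, lr: float
               ) -> np.ndarray:
    """Trainable-classifier update ``dM = -eta * mean_batch outer(e_s, y)``
    — the exact gradient step on the local loss w.r.t. ``M``."""
    if not loop.trainable:
        raise ValueError("tlc_update is only valid in TLC mode")
    e_s = np.atleast_2d(e_s)
    y_flat = np.atleast_2d(y_flat)
    return -lr * (e_s.T @ y_flat) / e_s.shape[0]


def bn_scale_update(tr: LayerTrace, state: LayerState, e_y: np.ndarray
                    ) -> Tuple[np.ndarray, np.ndarray]:
    """Exact batch-mean-loss gradients for the batch-norm scale and shift,
    given the per-sample error ``e_y`` at the batch-norm output (i.e. the
    backprojected error already masked by the ReLU derivative)."""
    if state.bn_scale is None:
        raise ValueError("layer has no batch-norm parameters")
    B = e_y.shape[0]
    axes = (0,) if e_y.ndim == 2 else (0, 2, 3)
    d_scale = (e_y * tr.bn_xhat).sum(axis=axes) / B
    d_shift = e_y.sum(axis=axes) / B
    return d_scale, d_shift


def local_gradients(
    layer: LayerSpec,
    state: LayerState,
    tr: LayerTrace,
    loop: LocalLoop,
    t: np.ndarray,
) -> Tuple[LayerGrads, Optional[np.ndarray], np.ndarray, np.ndarray]:
    """Gradients of the batch-mean local loss for one layer.

    Runs the full local loop: scores from the flattened post-dropout
    activity, loss derivative, backprojection through ``K_eff``, and the
    exact backward chain (dropout, pool winners, ReLU mask, batch-norm)
    down to the layer's weights.  In SYM/TLC mode the result is the exact
    gradient of the local loss; in SCFB/INDEP the same chain is driven by
    the mode's fixed feedback direction.

    Returns ``(grads, dM, E, e_s)`` where ``dM`` is the classifier
    gradient in TLC mode (else None) and ``E`` the per-sample losses.
    """
    y_flat = tr.classifier_input
    s = scores(loop.M, y_flat)
    E, e_s = loss_and_escore(s, t, loop.loss_kind)
    B = s.shape[0]
    g_flat = (e_s / B) @ loop.K_effective.T  # grad at classifier input
    grads = backward_through_layer(layer, state, tr, g_flat)
    dM = (e_s.T @ y_flat) / B if loop.trainable else None
    return grads, dM, E, e_s
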