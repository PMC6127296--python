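"""Backpropagation and feedback-alignment baselines.

Both baselines share the forward stack (and its recorded dropout masks
and pool winners) with the local-error path.  The network ends in a
trainable dense classifier (C units, with bias) on the last layer's
flattened post-dropout activity.  Backpropagation applies the exact chain
rule; feedback alignment replaces every transposed-weight multiplication
in the backward pass with a fixed random matrix (dense layers, top
classifier) or fixed random filters (convolutional layers), while
activation-derivative masks, winner-only pool routing, reused dropout
masks, and exact batch-norm calculus are kept identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import fixed_streams as fs
from .net_core import (
    ForwardTrace,
    LayerGrads,
    LayerState,
    NetworkSpec,
    backward_through_layer,
)
from .local_errors import loss_and_escore

__all__ = [
    "FeedbackSet",
    "make_top_classifier",
    "make_feedback_set",
    "top_forward",
    "bp_backward",
    "fa_backward",
]


@dataclass
class FeedbackSet:
    """Fixed random feedback arrays for feedback alignment: one per layer
    (shaped like that layer's weights) plus one for the top classifier.
    Never updated; regenerable from the seed ledger."""

    per_layer: List[np.ndarray]
    top: np.ndarray


def make_top_classifier(spec: NetworkSpec, seed: int,
                        distribution: str = "uniform",
                        dtype=np.float64) -> LayerState:
    """Trainable top classifier (C x N_L dense layer with bias), fan-scaled."""
    n = spec.classifier_input_size(spec.n_layers - 1)
    C = spec.num_classes
    W = fs.draw_fixed(fs.StreamSpec(seed, (C, n), distribution, n_in=n, n_out=C))
    return LayerState(W=W.astype(dtype), b=np.zeros(C, dtype=dtype))


def make_feedback_set(spec: NetworkSpec, master_seed: int,
                      distribution: str = "uniform",
                      dtype=np.float64) -> FeedbackSet:
    """Draw the fixed feedback arrays for every layer from the seed-mixing
    scheme (role ``FA``), scaled like the corresponding forward weights."""
    per_layer = []
    for li, layer in enumerate(spec.layers):
        seed = fs.derive_seed(master_seed, li, "FA")
        if layer.kind == "dense":
            shape = (layer.out_size, layer.in_size)
            n_in, n_out = layer.in_size, layer.out_size
        else:
            kh, kw = layer.kernel
            shape = (layer.out_channels, layer.in_channels, kh, kw)
            n_in, n_out = layer.in_channels * kh * kw, layer.out_channels * kh * kw
        per_layer.append(
            fs.draw_fixed(fs.StreamSpec(seed, shape, distribution, n_in, n_out)).astype(dtype)
        )
    n = spec.classifier_input_size(spec.n_layers - 1)
    C = spec.num_classes
    top_seed = fs.derive_seed(master_seed, spec.n_layers, "FA")
    top = fs.draw_fixed(
        fs.StreamSpec(top_seed, (C, n), distribution, n_in=n, n_out=C)
    ).astype(dtype)
    return FeedbackSet(per_layer=per_layer, top=top)


def top_forward(top: LayerState, trace: ForwardTrace) -> np.ndarray:
    """Scores of the trainable top classifier on the last layer's
    flattened post-dropout activity."""
    return trace[len(trace) - 1].classifier_input @ top.W.T + top.b


def _chain_backward(
    spec: NetworkSpec,
    states: Sequence[LayerState],
    top: LayerState,
    trace: ForwardTrace,
    t: np.ndarray,
    feedback: Optional[FeedbackSet],
    loss_kind: str = "cross_entropy",
) -> Tuple[List[LayerGrads], LayerGrads, np.ndarray]:
    s = top_forward(top, trace)
    E, e_s = loss_and_escore(s, t, loss_kind)
    B = s.shape[0]
    g = e_s / B  # gradients of the batch-mean loss from here on
    yL = trace[len(trace) - 1].classifier_input
    top_grads = LayerGrads(dW=g.T @ yL, db=g.sum(axis=0))
    back_top = top.W if feedback is None else feedback.top
    g = g @ back_top
    per_layer: List[Optional[LayerGrads]] = [None] * spec.n_layers
    for li in range(spec.n_layers - 1, -1, -1):
        bw = None if feedback is None else feedback.per_layer[li]
        if feedback is not None and bw is None:
            raise ValueError(f"missing feedback array for layer {li}")
        grads = backward_through_layer(
            spec.layers[li], states[li], trace[li], g,
            backprop_weight=bw, need_input_grad=(li > 0),
        )
        per_layer[li] = grads
        if li > 0:
            g = grads.g_input.reshape(trace[li - 1].classifier_input.shape)
    return per_layer, top_grads, E


def bp_backward(spec, states, top, trace, t, loss_kind="cross_entropy"):
    """Exact chain-rule gradients of the top classification loss for every
    layer and the top classifier.  Returns ``(per_layer, top_grads, E)``."""
    return _chain_backward(spec, states, top, trace, t, feedback=None,
                           loss_kind=loss_kind)


def fa_backward(spec, states, top, feedback: FeedbackSet, trace, t,
                loss_kind="cross_entropy"):
    """Feedback-alignment gradients: identical to :func:`bp_backward`
    except every transposed-weight multiplication uses the fixed random
    feedback array.  With ``feedback`` equal to the forward weights this
    reduces exactly to backpropagation."""
    return _chain_backward(spec, states, top, trace, t, feedback=feedback,
                           loss_kind=loss_kind)
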