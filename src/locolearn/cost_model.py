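"""Analytic memory-traffic and MAC-count model for training hardware.

For a compute device with at least ``max_i(|P_i| + N_b |A_i|)`` words of
on-board memory (one 32-bit word per weight or activation), training for
``N_e`` epochs over ``N_b`` mini-batches costs:

=======================  =========================  =========================  ==============================
scheme                   memory reads (words)       memory writes (words)      MAC operations
=======================  =========================  =========================  ==============================
backpropagation (bp)     N_e N_b sum(2|P_i|+|A_i|)  N_e N_b sum(|P_i|+|A_i|)   N_e N_b sum_i 3 R_i |A_i|
local errors (lel)       N_e sum|P_i|               N_e sum|P_i|               N_e N_b sum_i (2R_i+2C)|A_i|
=======================  =========================  =========================  ==============================

where ``|P_i|`` counts a layer's weight words (biases and batch-norm
parameters excluded; fixed local-classifier matrices cost nothing because
they live in a PRNG seed), ``|A_i|`` counts the layer's post-pool
mini-batch activations, and ``R_i`` is the fanout: the number of
layer-(i+1) neurons one layer-i neuron projects to (the top layer fans
out to the C classifier units).  Border effects in convolutional fanout
are ignored.  Local-error training reads parameters once per epoch
because weights are updated in place during the forward sweep and
activations never leave the device; its MAC count wins over
backpropagation exactly when ``L*C < 0.5 * sum_i R_i``.

The per-layer closed forms index each layer's feed-forward and
weight-update cost by the *source* layer's fanout (``R_i |A_i|`` pays for
computing layer i+1 from layer i, for updating layer i+1's weights, and —
under backpropagation — for projecting errors from layer i+1 back to
layer i).  The input layer's own terms (computing layer 1 from the data
and updating layer 1's weights) are left out of the sums, as is the cost
of evaluating the top-layer loss.  :mod:`locolearn.counting` provides an
instrumented naive-loop implementation whose per-operation tallies verify
these formulas term by term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import pandas as pd

from .net_core import NetworkSpec


__all__ = [
    "ArchAccounting",
    "RunShape",
    "CostReport",
    "account",
    "traffic",
    "macs",
    "mac_advantage",
    "cost_table",
]


@dataclass(frozen=True)
class RunShape:
    """Training run geometry: ``n_epochs`` (N_e), ``n_batches`` mini-batches
    per epoch (N_b), and the mini-batch size."""

    n_epochs: int
    n_batches: int
    batch_size: int

    def __post_init__(self):
        if min(self.n_epochs, self.n_batches, self.batch_size) < 1:
            raise ValueError("run shape entries must be positive")


@dataclass(frozen=True)
class ArchAccounting:
    """Per-layer words and fanout of an architecture.

    ``params[i]`` = |P_i| (weight words only), ``activations[i]`` = |A_i|
    (post-pool activation words for one mini-batch), ``fanout[i]`` = R_i.
    """

    params: tuple
    activations: tuple
    fanout: tuple
    n_layers: int
    num_classes: int
    batch_size: int

    @property
    def total_params(self) -> int:
        return sum(self.params)

    @property
    def total_activations(self) -> int:
        return sum(self.activations)


@dataclass(frozen=True)
class CostReport:
    scheme: str
    reads: int
    writes: int
    macs: int
    run: RunShape


def _layer_param_count(layer) -> int:
    # weights only: biases and batch-norm parameters are excluded from the
    # accounting, and fixed classifier matrices are stored as seeds
    if layer.kind == "dense":
        return layer.out_size * layer.in_size
    kh, kw = layer.kernel
    return layer.out_channels * layer.in_channels * kh * kw


def account(spec: NetworkSpec, batch_size: int = 100) -> ArchAccounting:
    """Count |P_i|, |A_i| and R_i for every layer of ``spec``.

    Activations are counted after pooling (those are the words a scheme
    would have to move); the fanout of the last layer is the class count
    C, since its activity feeds a C-way classifier in every scheme.
    """
    params: List[int] = []
    acts: List[int] = []
    fanout: List[int] = []
    L = spec.n_layers
    for li, layer in enumerate(spec.layers):
        params.append(_layer_param_count(layer))
        acts.append(spec.classifier_input_size(li) * batch_size)
        if li + 1 < L:
            nxt = spec.layers[li + 1]
            if nxt.kind == "dense":
                fanout.append(nxt.out_size)
            else:
                kh, kw = nxt.kernel
                fanout.append(nxt.out_channels * kh * kw)
        else:
            fanout.append(spec.num_classes)
    return ArchAccounting(
        params=tuple(params),
        activations=tuple(acts),
        fanout=tuple(fanout),
        n_layers=L,
        num_classes=spec.num_classes,
        batch_size=batch_size,
    )


def traffic(acct: ArchAccounting, scheme: str, run: RunShape) -> CostReport:
    """External-memory words moved by a full training run."""
    P = acct.params
    A = acct.activations
    if scheme == "bp":
        reads = run.n_epochs * run.n_batches * sum(2 * p + a for p, a in zip(P, A))
        writes = run.n_epochs * run.n_batches * sum(p + a for p, a in zip(P, A))
    elif scheme == "lel":
        reads = writes = run.n_epochs * sum(P)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return CostReport(scheme=scheme, reads=reads, writes=writes,
                      macs=macs(acct, scheme, run), run=run)


def macs(acct: ArchAccounting, scheme: str, run: RunShape) -> int:
    """Multiply-accumulate count of a full training run."""
    R = acct.fanout
    A = acct.activations
    C = acct.num_classes
    if scheme == "bp":
        per_batch = sum(3 * r * a for r, a in zip(R, A))
    elif scheme == "lel":
        per_batch = sum((2 * r + 2 * C) * a for r, a in zip(R, A))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return run.n_epochs * run.n_batches * per_batch


def mac_advantage(acct: ArchAccounting) -> bool:
    """True iff local-error training needs fewer MACs than
    backpropagation: ``L * C < 0.5 * sum_i R_i``."""
    return acct.n_layers * acct.num_classes < 0.5 * sum(acct.fanout)


def cost_table(spec: NetworkSpec, run: RunShape) -> pd.DataFrame:
    """Per-layer accounting plus both schemes' totals as a DataFrame."""
    acct = account(spec, run.batch_size)
    rows = [
        {"layer": i + 1, "P_words": p, "A_words": a, "fanout": r}
        for i, (p, a, r) in enumerate(zip(acct.params, acct.activations, acct.fanout))
    ]
    df = pd.DataFrame(rows)
    for scheme in ("bp", "lel"):
        rep = traffic(acct, scheme, run)
        df.attrs[scheme] = {"reads": rep.reads, "writes": rep.writes, "macs": rep.macs}
    df.attrs["mac_advantage"] = mac_advantage(acct)
    return df
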