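"""Training harness: SGD with Nesterov momentum, the stepped learning-rate
schedule, per-layer evaluation, and early-exit inference.

The three training methods share one forward stack:

``lel``
    Local-error learning.  During the forward sweep each layer computes
    its own error from its fixed random classifier and updates its
    weights immediately — there is no backward pass, and no layer ever
    waits for (or reads) state from a higher layer.
``bp``
    Standard backpropagation of a top cross-entropy loss through a
    trainable top classifier.
``fa``
    Feedback alignment: the same top loss backpropagated through fixed
    random feedback arrays.

Every source of randomness — weight init, the fixed classifier and
feedback draws, dropout, epoch shuffling — derives from one master seed
through :func:`locolearn.fixed_streams.derive_seed`, so a run is
bit-reproducible and each fixed matrix is reconstructible from the seed
ledger alone.
"""

from __future__ import annotations


from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from . import fixed_streams as fs
from .baselines import FeedbackSet, bp_backward, fa_backward, make_feedback_set, \
    make_top_classifier, top_forward
from .local_errors import LocalLoop, local_gradients, loss_and_escore, scores
from .net_core import (
    LayerState,
    NetworkSpec,
    forward_layer,
    init_layer_state,
    network_forward,
)

__all__ = [
    "TrainConfig",
    "TrainingDiverged",
    "lr_at",
    "nag_step",
    "build_loops",
    "train",
    "TrainResult",
    "evaluate_layers",
    "evaluate_top",
    "early_exit_predict",
    "early_exit_mac_count",
]


class TrainingDiverged(RuntimeError):
    """Loss became non-finite for several consecutive mini-batches."""


@dataclass
class TrainConfig:
    """Optimization settings.

    Defaults follow the reference protocol: Nesterov momentum 0.9, initial
    learning rate 0.1 dropped by a factor of 5 every 25 epochs, 100-sample
    mini-batches, 100 epochs.
    """

    lr0: float = 0.1
    momentum: float = 0.9
    epochs: int = 100
    lr_drop_factor: float = 5.0
    lr_drop_every: int = 25
    batch_size: int = 100
    master_seed: int = 0
    method: str = "lel"  # lel | fa | bp
    mode: str = "SYM"  # SYM | SCFB | INDEP | TLC (lel only)
    loss_kind: str = "cross_entropy"
    distribution: str = "uniform"  # fixed-weight and init distribution
    dtype: str = "float32"
    divergence_patience: int = 3

    def __post_init__(self):
        if self.method not in ("lel", "fa", "bp"):
            raise ValueError(f"method must be lel/fa/bp, got {self.method!r}")


def lr_at(epoch: int, cfg: TrainConfig) -> float:
    """Piecewise-constant schedule: ``lr0 / factor**(epoch // every)``."""
    if epoch < 0:
        raise ValueError("epoch must be nonnegative")
    return cfg.lr0 / cfg.lr_drop_factor ** (epoch // cfg.lr_drop_every)


def nag_step(param: np.ndarray, grad: np.ndarray, velocity: np.ndarray,
             lr: float, momentum: float) -> Tuple[np.ndarray, np.ndarray]:
    """Nesterov-accelerated SGD step.

    ``v' = mu v + g``; ``p' = p - lr (g + mu v')``.  With ``mu = 0`` this
    reduces to plain SGD; with ``g = 0`` the velocity decays geometrically.
    """
    v = momentum * velocity + grad
    return param - lr * (grad + momentum * v), v


def build_loops(spec: NetworkSpec, master_seed: int, mode: str = "SYM",
                loss_kind: str = "cross_entropy", distribution: str = "uniform",
                dtype=np.float64) -> List[LocalLoop]:
    """Draw each layer's fixed classifier (and, per mode, feedback matrix)
    from the seed-mixing scheme."""
    loops = []
    C = spec.num_classes
    for li in range(spec.n_layers):
        N = spec.classifier_input_size(li)
        seed_M = fs.derive_seed(master_seed, li, "M")
        if mode == "SCFB":
            seed_K = fs.derive_seed(master_seed, li, "K_mag")
            M, K = fs.sign_concordant_pair(seed_M, seed_K, (C, N),
                                           distribution, n_in=N, n_out=C)
            loops.append(LocalLoop(M.astype(dtype), K.astype(dtype), mode, loss_kind))
        elif mode == "INDEP":
            M = fs.draw_fixed(fs.StreamSpec(seed_M, (C, N), distribution, N, C))
            seed_K = fs.derive_seed(master_seed, li, "K_mag")
            K = fs.draw_fixed(fs.StreamSpec(seed_K, (N, C), distribution, N, C))
            loops.append(LocalLoop(M.astype(dtype), K.astype(dtype), mode, loss_kind))
        else:  # SYM / TLC: K is implicitly M^T
            M = fs.draw_fixed(fs.StreamSpec(seed_M, (C, N), distribution, N, C))
            loops.append(LocalLoop(M.astype(dtype), None, mode, loss_kind))
    return loops


def seed_ledger_entries(spec: NetworkSpec, cfg: TrainConfig):
    """The (layer, role, seed) triples from which every fixed matrix and
    random stream of a run can be regenerated."""
    entries = []
    for li in range(spec.n_layers):
        entries.append((li, "init", fs.derive_seed(cfg.master_seed, li, "init")))
        if cfg.method == "lel":
            entries.append((li, "M", fs.derive_seed(cfg.master_seed, li, "M")))
            if cfg.mode in ("SCFB", "INDEP"):
                entries.append((li, "K_mag", fs.derive_seed(cfg.master_seed, li, "K_mag")))
        if cfg.method == "fa":
            entries.append((li, "FA", fs.derive_seed(cfg.master_seed, li, "FA")))
    if cfg.method == "fa":
        entries.append((spec.n_layers, "FA",
                        fs.derive_seed(cfg.master_seed, spec.n_layers, "FA")))
    entries.append((0, "dropout", fs.derive_seed(cfg.master_seed, 0, "dropout")))
    entries.append((0, "shuffle", fs.derive_seed(cfg.master_seed, 0, "shuffle")))
    return entries


@dataclass
class _Velocity:
    W: np.ndarray
    b: np.ndarray
    scale: Optional[np.ndarray] = None
    shift: Optional[np.ndarray] = None
    M: Optional[np.ndarray] = None


@dataclass
class TrainResult:
    states: List[LayerState]
    loops: Optional[List[LocalLoop]]
    top: Optional[LayerState]
    feedback: Optional[FeedbackSet]
    metrics: pd.DataFrame
    seed_entries: list


def _zero_velocity(state: LayerState, loop: Optional[LocalLoop]) -> _Velocity:
    v = _Velocity(W=np.zeros_like(state.W), b=np.zeros_like(state.b))
    if state.bn_scale is not None:
        v.scale = np.zeros_like(state.bn_scale)
        v.shift = np.zeros_like(state.bn_shift)
    if loop is not None and loop.trainable:
        v.M = np.zeros_like(loop.M)
    return v


def _apply_updates(state: LayerState, grads, vel: _Velocity, lr, mu,
                   loop: Optional[LocalLoop] = None, dM=None):
    state.W, vel.W = nag_step(state.W, grads.dW, vel.W, lr, mu)
    state.b, vel.b = nag_step(state.b, grads.db, vel.b, lr, mu)
    if grads.d_scale is not None:
        state.bn_scale, vel.scale = nag_step(state.bn_scale, grads.d_scale,
                                             vel.scale, lr, mu)
        state.bn_shift, vel.shift = nag_step(state.bn_shift, grads.d_shift,
                                             vel.shift, lr, mu)
    if dM is not None:
        loop.M, vel.M = nag_step(loop.M, dM, vel.M, lr, mu)


def train(spec: NetworkSpec, data, cfg: TrainConfig) -> TrainResult:
    """Train ``spec`` on ``data`` (an object with ``X_train``/``y_train``/
    ``X_test``/``y_test``) with the configured method.

    Local-error training updates each layer during the forward sweep; the
    activations a layer hands upward were computed with its pre-update
    weights.  Metrics are recorded per epoch and per layer (local
    classifier accuracy/loss for ``lel``; top-classifier numbers, keyed as
    layer ``top``, for ``bp``/``fa``).
    """
    dtype = np.dtype(cfg.dtype)
    X_train = np.asarray(data.X_train, dtype=dtype)
    y_train = np.asarray(data.y_train, dtype=np.int64)
    X_test = np.asarray(data.X_test, dtype=dtype)
    y_test = np.asarray(data.y_test, dtype=np.int64)
    n = len(X_train)

    states = [
        init_layer_state(
            layer,
            np.random.Generator(np.random.PCG64(fs.derive_seed(cfg.master_seed, li, "init"))),
            cfg.distribution,
            dtype,
        )
        for li, layer in enumerate(spec.layers)
    ]
    loops = top = feedback = None
    if cfg.method == "lel":
        loops = build_loops(spec, cfg.master_seed, cfg.mode, cfg.loss_kind,
                            cfg.distribution, dtype)
        velocities = [_zero_velocity(s, l) for s, l in zip(states, loops)]
    else:
        top = make_top_classifier(
            spec, fs.derive_seed(cfg.master_seed, spec.n_layers, "init"),
            cfg.distribution, dtype)
        velocities = [_zero_velocity(s, None) for s in states]
        vel_top = _Velocity(W=np.zeros_like(top.W), b=np.zeros_like(top.b))
        if cfg.method == "fa":
            feedback = make_feedback_set(spec, cfg.master_seed, cfg.distribution, dtype)

    dropout_rng = np.random.Generator(
        np.random.PCG64(fs.derive_seed(cfg.master_seed, 0, "dropout")))
    shuffle_rng = np.random.Generator(
        np.random.PCG64(fs.derive_seed(cfg.master_seed, 0, "shuffle")))

    records = []
    bad_batches = 0
    for epoch in range(cfg.epochs):
        lr = lr_at(epoch, cfg)
        order = shuffle_rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, tb = X_train[idx], y_train[idx]
            try:
                if cfg.method == "lel":
                    h = xb
                    for li, layer in enumerate(spec.layers):
                        tr, h_next = forward_layer(layer, states[li], h,
                                                   training=True,
                                                   dropout_rng=dropout_rng)
                        grads, dM, E, _ = local_gradients(layer, states[li], tr,
                                                          loops[li], tb)
                        if not np.isfinite(E).all():
                            raise FloatingPointError("non-finite local loss")
                        _apply_updates(states[li], grads, velocities[li], lr,
                                       cfg.momentum, loops[li], dM)
                        h = h_next
                else:
                    trace = network_forward(spec, states, xb, mode="train",
                                            dropout_rng=dropout_rng)
                    if cfg.method == "bp":
                        per_layer, top_grads, E = bp_backward(
                            spec, states, top, trace, tb, cfg.loss_kind)
                    else:
                        per_layer, top_grads, E = fa_backward(
                            spec, states, top, feedback, trace, tb, cfg.loss_kind)
                    if not np.isfinite(E).all():
                        raise FloatingPointError("non-finite top loss")
                    for li in range(spec.n_layers):
                        _apply_updates(states[li], per_layer[li], velocities[li],
                                       lr, cfg.momentum)
                    top.W, vel_top.W = nag_step(top.W, top_grads.dW, vel_top.W,
                                                lr, cfg.momentum)
                    top.b, vel_top.b = nag_step(top.b, top_grads.db, vel_top.b,
                                                lr, cfg.momentum)
                bad_batches = 0
            except FloatingPointError as err:
                bad_batches += 1
                if bad_batches >= cfg.divergence_patience:
                    raise TrainingDiverged(
                        f"non-finite loss for {bad_batches} consecutive "
                        f"mini-batches at epoch {epoch} (method={cfg.method}): {err}"
                    ) from err

        # per-epoch metrics, eval mode
        for split, X, y in (("train", X_train, y_train), ("test", X_test, y_test)):
            if cfg.method == "lel":
                accs, losses = evaluate_layers(spec, states, loops, X, y)
                for li in range(spec.n_layers):
                    records.append({"epoch": epoch, "layer": li + 1, "split": split,
                                    "accuracy": accs[li], "loss": losses[li]})
            else:
                acc, loss = evaluate_top(spec, states, top, X, y, cfg.loss_kind)
                records.append({"epoch": epoch, "layer": "top", "split": split,
                                "accuracy": acc, "loss": loss})

    metrics = pd.DataFrame.from_records(
        records, columns=["epoch", "layer", "split", "accuracy", "loss"])
    return TrainResult(states=states, loops=loops, top=top, feedback=feedback,
                       metrics=metrics,
                       seed_entries=seed_ledger_entries(spec, cfg))


def evaluate_layers(spec, states, loops, X, y, batch_size: int = 1000):
    """Per-layer local-classifier accuracy (%) and mean local loss on
    ``(X, y)``, eval-mode forward."""
    L = spec.n_layers
    correct = np.zeros(L)
    loss_sum = np.zeros(L)
    n = len(X)
    for start in range(0, n, batch_size):
        xb = X[start:start + batch_size]
        tb = y[start:start + batch_size]
        trace = network_forward(spec, states, xb, mode="eval")
        for li in range(L):
            s = scores(loops[li].M, trace[li].classifier_input)
            E, _ = loss_and_escore(s, tb, loops[li].loss_kind)
            correct[li] += (s.argmax(axis=1) == tb).sum()
            loss_sum[li] += E.sum()
    return 100.0 * correct / n, loss_sum / n


def evaluate_top(spec, states, top, X, y, loss_kind="cross_entropy",
                 batch_size: int = 1000):
    """Top-classifier accuracy (%) and mean loss, eval-mode forward."""
    correct = 0.0
    loss_sum = 0.0
    n = len(X)
    for start in range(0, n, batch_size):
        xb = X[start:start + batch_size]
        tb = y[start:start + batch_size]
        trace = network_forward(spec, states, xb, mode="eval")
        s = top_forward(top, trace)
        E, _ = loss_and_escore(s, tb, loss_kind)
        correct += (s.argmax(axis=1) == tb).sum()
        loss_sum += E.sum()
    return 100.0 * correct / n, loss_sum / n


def early_exit_predict(spec, states, loops, X, stop_layer: int) -> np.ndarray:
    """Classify from layer ``stop_layer``'s local classifier, evaluating
    layers ``1..stop_layer`` only — higher layers are never touched, which
    is what makes dynamic network truncation free."""
    if not (1 <= stop_layer <= spec.n_layers):
        raise ValueError(f"stop_layer must be in [1, {spec.n_layers}]")
    trace = network_forward(spec, states, X, mode="eval", stop_layer=stop_layer)
    s = scores(loops[stop_layer - 1].M, trace[stop_layer - 1].classifier_input)
    return s.argmax(axis=1)


def early_exit_mac_count(spec: NetworkSpec, stop_layer: int, batch_size: int = 1
                         ) -> int:
    """Forward MACs for an early exit at ``stop_layer``: the cost of
    evaluating layers 1..stop_layer plus the exit layer's local-classifier
    score.  Strictly increasing in ``stop_layer``."""
    if not (1 <= stop_layer <= spec.n_layers):
        raise ValueError(f"stop_layer must be in [1, {spec.n_layers}]")
    total = 0
    in_shape = spec.input_shape
    for li in range(stop_layer):
        layer = spec.layers[li]
        if layer.kind == "dense":
            total += layer.in_size * layer.out_size
        else:
            c, h, w = in_shape
            kh, kw = layer.kernel
            total += layer.out_channels * h * w * layer.in_channels * kh * kw
        in_shape = spec.output_shape(li)
    total += spec.num_classes * spec.classifier_input_size(stop_layer - 1)
    return total * batch_size
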