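"""Network description, parameter state, and the forward computation.

The networks trained here are plain feed-forward stacks of dense and
convolutional ReLU layers with optional per-layer batch normalization
(applied to the pre-activation), max pooling (convolutional layers only),
and dropout.  A forward pass records everything the learning rules need —
activations, ReLU derivative masks, pool winners, dropout masks, and the
flattened per-layer classifier inputs — in a :class:`ForwardTrace`.

Conventions
-----------
* Convolutions are stride-1 cross-correlations with "same" (size
  preserving) zero padding; kernels must have odd side lengths.
* Max-pool ties are broken by the first (row-major lowest) index inside
  the window.
* Dropout is inverted dropout: surviving units are scaled by
  ``1/(1-rate)`` at train time so that evaluation needs no rescaling.
* Flattening a feature-map tensor for a local classifier is channel-major
  then row-major, i.e. plain C-order ``reshape(batch, -1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "PoolSpec",
    "DenseSpec",
    "ConvSpec",
    "LayerSpec",
    "NetworkSpec",
    "LayerState",
    "LayerTrace",
    "ForwardTrace",
    "LayerGrads",
    "init_layer_state",
    "init_states",
    "forward_dense",
    "forward_conv",
    "maxpool",
    "unpool_scatter",
    "apply_dropout",
    "forward_layer",
    "network_forward",
    "flatten_for_classifier",
    "unflatten_from_classifier",
    "backward_through_layer",
    "dale_decompose",
    "dale_pairs",
    "dale_forward",
]

BN_EPS = 1e-5
BN_MOMENTUM = 0.1


class ShapeError(ValueError):
    """Raised when tensors do not compose with the declared architecture."""


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PoolSpec:
    """Max-pooling geometry: ``window`` x ``window``, given stride/padding."""

    window: int = 2
    stride: int = 2
    padding: int = 0

    def out_size(self, n: int) -> int:
        out = (n + 2 * self.padding - self.window) // self.stride + 1
        if out < 1:
            raise ShapeError(f"pool window {self.window} larger than padded input {n}")
        return out


@dataclass(frozen=True)
class DenseSpec:
    in_size: int
    out_size: int
    use_batchnorm: bool = False
    dropout_rate: float = 0.0

    kind = "dense"

    def __post_init__(self):
        if self.in_size < 1 or self.out_size < 1:
            raise ValueError("dense layer sizes must be positive")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError(f"dropout_rate must be in [0,1), got {self.dropout_rate}")


@dataclass(frozen=True)
class ConvSpec:
    in_channels: int
    out_channels: int
    kernel: Tuple[int, int] = (3, 3)
    pool: Optional[PoolSpec] = None
    use_batchnorm: bool = False
    dropout_rate: float = 0.0

    kind = "conv"

    def __post_init__(self):
        kh, kw = self.kernel
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("same-padded convolution requires odd kernel sides")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError(f"dropout_rate must be in [0,1), got {self.dropout_rate}")


LayerSpec = Union[DenseSpec, ConvSpec]


@dataclass(frozen=True)
class NetworkSpec:
    """Ordered layer stack plus class count — the single source of truth
    for every shape and for the cost-model accounting."""

    layers: Tuple[LayerSpec, ...]
    num_classes: int
    input_shape: Union[int, Tuple[int, int, int]]

    def __post_init__(self):
        object.__setattr__(self, "layers", tuple(self.layers))
        if len(self.layers) < 1:
            raise ValueError("need at least one layer")
        if self.num_classes < 2:
            raise ValueError("need at least two classes")
        # walk shapes once to validate composition
        self._shape_walk()

    # -- shape propagation -------------------------------------------------
    def _shape_walk(self) -> List[Union[int, Tuple[int, int, int]]]:
        """Per-layer *output* shape after pooling (what the next layer sees)."""
        shapes: List[Union[int, Tuple[int, int, int]]] = []
        cur: Union[int, Tuple[int, int, int]] = self.input_shape
        for li, layer in enumerate(self.layers):
            if layer.kind == "dense":
                cur_flat = cur if isinstance(cur, int) else int(np.prod(cur))
                if cur_flat != layer.in_size:
                    raise ShapeError(
                        f"layer {li}: dense in_size {layer.in_size} != incoming {cur_flat}"
                    )
                cur = layer.out_size
            else:
                if isinstance(cur, int):
                    raise ShapeError(f"layer {li}: conv layer needs a (C,H,W) input")
                c, h, w = cur
                if c != layer.in_channels:
                    raise ShapeError(
                        f"layer {li}: conv in_channels {layer.in_channels} != incoming {c}"
                    )
                if layer.pool is not None:
                    h = layer.pool.out_size(h)
                    w = layer.pool.out_size(w)
                cur = (layer.out_channels, h, w)
            shapes.append(cur)
        return shapes

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def output_shape(self, i: int) -> Union[int, Tuple[int, int, int]]:
        """Shape of layer ``i``'s output after pooling."""
        return self._shape_walk()[i]

    def classifier_input_size(self, i: int) -> int:
        """Flattened size of the post-pool, post-dropout activity feeding
        layer ``i``'s local classifier."""
        s = self.output_shape(i)
        return s if isinstance(s, int) else int(np.prod(s))


# ---------------------------------------------------------------------------
# State
# ---------------------------------------------------------------------------


@dataclass
class LayerState:
    """Trainable parameters of one layer.

    ``W`` is ``(out, in)`` for dense layers, ``(out_ch, in_ch, kh, kw)``
    for convolutional layers.  Batch-norm arrays are present iff the spec
    enables batch normalization (one entry per unit for dense layers, per
    feature map for convolutional layers).
    """

    W: np.ndarray
    b: np.ndarray
    bn_scale: Optional[np.ndarray] = None
    bn_shift: Optional[np.ndarray] = None
    bn_running_mean: Optional[np.ndarray] = None
    bn_running_var: Optional[np.ndarray] = None

    def copy(self) -> "LayerState":
        return LayerState(
            self.W.copy(),
            self.b.copy(),
            None if self.bn_scale is None else self.bn_scale.copy(),
            None if self.bn_shift is None else self.bn_shift.copy(),
            None if self.bn_running_mean is None else self.bn_running_mean.copy(),
            None if self.bn_running_var is None else self.bn_running_var.copy(),
        )


def _glorot_std(n_in: int, n_out: int) -> float:
    return float(np.sqrt(2.0 / (n_in + n_out)))


def init_layer_state(
    layer: LayerSpec,
    rng: np.random.Generator,
    distribution: str = "uniform",
    dtype=np.float64,
) -> LayerState:
    """Initialize one layer's parameters with fan-scaled random weights.

    The weight std is ``sqrt(2/(n_in+n_out))``; ``uniform`` draws on
    ``[-sqrt(3)*std, +sqrt(3)*std]`` so the std matches the Gaussian case.
    """
    if layer.kind == "dense":
        shape = (layer.out_size, layer.in_size)
        n_in, n_out = layer.in_size, layer.out_size
        n_units = layer.out_size
    else:
        kh, kw = layer.kernel
        shape = (layer.out_channels, layer.in_channels, kh, kw)
        n_in = layer.in_channels * kh * kw
        n_out = layer.out_channels * kh * kw
        n_units = layer.out_channels
    std = _glorot_std(n_in, n_out)
    if distribution == "gaussian":
        W = rng.normal(0.0, std, size=shape)
    elif distribution == "uniform":
        lim = np.sqrt(3.0) * std
        W = rng.uniform(-lim, lim, size=shape)
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    state = LayerState(W=W.astype(dtype), b=np.zeros(n_units, dtype=dtype))
    if layer.use_batchnorm:
        state.bn_scale = np.ones(n_units, dtype=dtype)
        state.bn_shift = np.zeros(n_units, dtype=dtype)
        state.bn_running_mean = np.zeros(n_units, dtype=dtype)
        state.bn_running_var = np.ones(n_units, dtype=dtype)
    return state


def init_states(
    spec: NetworkSpec,
    rng: np.random.Generator,
    distribution: str = "uniform",
    dtype=np.float64,
) -> List[LayerState]:
    return [init_layer_state(l, rng, distribution, dtype) for l in spec.layers]


# ---------------------------------------------------------------------------
# Trace
# ---------------------------------------------------------------------------


@dataclass
class LayerTrace:
    """Everything one layer's forward pass recorded for learning.

    ``x`` is the layer's input exactly as received, ``deriv`` the ReLU
    derivative mask at the (batch-normed) pre-activation, computed before
    dropout, ``pooled`` the post-pool maps (conv only), and
    ``classifier_input`` the flattened post-pool, post-dropout activity
    feeding the local classifier.
    """

    x: np.ndarray
    post_act: np.ndarray
    deriv: np.ndarray
    bn_xhat: Optional[np.ndarray] = None
    bn_var: Optional[np.ndarray] = None
    pooled: Optional[np.ndarray] = None
    pool_winners: Optional[np.ndarray] = None
    dropout_mask: Optional[np.ndarray] = None
    dropout_rate: float = 0.0
    classifier_input: Optional[np.ndarray] = None


@dataclass
class ForwardTrace:
    layers: List[LayerTrace] = field(default_factory=list)
    mode: str = "train"

    def __getitem__(self, i: int) -> LayerTrace:
        return self.layers[i]

    def __len__(self) -> int:
        return len(self.layers)


@dataclass
class LayerGrads:
    """Gradients of a (batch-mean) loss w.r.t. one layer's parameters and input."""

    dW: np.ndarray
    db: np.ndarray
    d_scale: Optional[np.ndarray] = None
    d_shift: Optional[np.ndarray] = None
    g_input: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# Primitive forward ops
# ---------------------------------------------------------------------------


def _bn_forward(z, state: LayerState, axes, training: bool, update_running: bool):
    """Batch-norm over ``axes`` (per remaining feature axis). Returns
    (z_out, xhat, var_used)."""
    scale = state.bn_scale
    shift = state.bn_shift
    bshape = [1] * z.ndim
    feat_axis = 1 if z.ndim == 4 else 1
    bshape[feat_axis] = -1
    if training:
        mean = z.mean(axis=axes)
        var = z.var(axis=axes)  # biased, used for normalization
        if update_running:
            m = int(np.prod([z.shape[a] for a in axes]))
            unbiased = var * (m / max(m - 1, 1))
            state.bn_running_mean *= 1.0 - BN_MOMENTUM
            state.bn_running_mean += BN_MOMENTUM * mean
            state.bn_running_var *= 1.0 - BN_MOMENTUM
            state.bn_running_var += BN_MOMENTUM * unbiased
    else:
        mean = state.bn_running_mean
        var = state.bn_running_var
    xhat = (z - mean.reshape(bshape)) / np.sqrt(var.reshape(bshape) + BN_EPS)
    out = scale.reshape(bshape) * xhat + shift.reshape(bshape)
    return out, xhat, var


def forward_dense(
    state: LayerState,
    x: np.ndarray,
    spec: Optional[DenseSpec] = None,
    training: bool = True,
    update_running: bool = True,
):
    """Dense layer: ``y = relu(bn?(W x + b))``; also returns the ReLU
    derivative mask ``y' = 1[pre > 0]`` (computed before any dropout).

    Returns ``(y, yprime)`` when batch-norm is off, otherwise
    ``(y, yprime, xhat, var)``.
    """
    x = np.atleast_2d(x)
    if x.shape[1] != state.W.shape[1]:
        raise ShapeError(
            f"dense input width {x.shape[1]} != weight in-size {state.W.shape[1]}"
        )
    z = x @ state.W.T + state.b
    if state.bn_scale is not None:
        z, xhat, var = _bn_forward(z, state, axes=(0,), training=training,
                                   update_running=update_running)
        y = np.maximum(z, 0.0)
        yprime = (z > 0).astype(z.dtype)
        return y, yprime, xhat, var
    y = np.maximum(z, 0.0)
    yprime = (z > 0).astype(z.dtype)
    return y, yprime


def _conv2d_same(x: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Stride-1 same-padded cross-correlation. x: (B,Cin,H,W),
    W: (Cout,Cin,kh,kw) -> (B,Cout,H,W)."""
    B, Cin, H, Wd = x.shape
    Cout, Cin2, kh, kw = W.shape
    if Cin != Cin2:
        raise ShapeError(f"conv input channels {Cin} != kernel in-channels {Cin2}")
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    if H < 1 or Wd < 1 or kh > H + 2 * ph or kw > Wd + 2 * pw:
        raise ShapeError(f"kernel ({kh},{kw}) larger than padded input ({H},{Wd})")
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (B,Cin,H,W,kh,kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * Wd, Cin * kh * kw)
    out = cols @ W.reshape(Cout, -1).T  # (B*H*W, Cout)
    return out.reshape(B, H, Wd, Cout).transpose(0, 3, 1, 2)


def _conv2d_weight_grad(x: np.ndarray, g: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """Gradient of a same-padded stride-1 correlation w.r.t. its kernel,
    accumulated (summed) over batch and spatial positions — tied weights.
    x: (B,Cin,H,W), g: (B,Cout,H,W) -> (Cout,Cin,kh,kw)."""
    B, Cin, H, Wd = x.shape
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * Wd, Cin * kh * kw)
    gmat = g.transpose(0, 2, 3, 1).reshape(B * H * Wd, -1)  # (BHW, Cout)
    return (gmat.T @ cols).reshape(-1, Cin, kh, kw)


def _conv2d_data_grad(g: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Gradient of a same-padded stride-1 correlation w.r.t. its input:
    full correlation of g with the channel-transposed, spatially flipped
    kernels. g: (B,Cout,H,W), W: (Cout,Cin,kh,kw) -> (B,Cin,H,W)."""
    Wt = W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (Cin,Cout,kh,kw)
    return _conv2d_same(g, np.ascontiguousarray(Wt))


def forward_conv(
    state: LayerState,
    maps: np.ndarray,
    spec: Optional[ConvSpec] = None,
    training: bool = True,
    update_running: bool = True,
):
    """Convolutional layer: same-padded correlation + bias, optional
    batch-norm (per feature map), then ReLU.  Returns ``(maps_out,
    deriv_mask)`` or ``(maps_out, deriv_mask, xhat, var)`` with batch-norm.
    """
    z = _conv2d_same(maps, state.W) + state.b[None, :, None, None]
    if state.bn_scale is not None:
        z, xhat, var = _bn_forward(z, state, axes=(0, 2, 3), training=training,
                                   update_running=update_running)
        return np.maximum(z, 0.0), (z > 0).astype(z.dtype), xhat, var
    return np.maximum(z, 0.0), (z > 0).astype(z.dtype)


def maxpool(maps: np.ndarray, window: int, stride: int, padding: int = 0):
    """Max pooling with first-index tie-breaking.

    Returns ``(pooled, winners)`` where ``winners[b,c,i,j]`` is the flat
    row-major index into the *unpadded* (H, W) plane of the element that
    won window (i, j).
    """
    B, C, H, W = maps.shape
    xp = np.pad(
        maps,
        ((0, 0), (0, 0), (padding, padding), (padding, padding)),
        constant_values=-np.inf,
    )
    win = sliding_window_view(xp, (window, window), axis=(2, 3))[:, :, ::stride, ::stride]
    Ho, Wo = win.shape[2], win.shape[3]
    flat = win.reshape(B, C, Ho, Wo, -1)
    idx = flat.argmax(axis=-1)  # first occurrence wins ties
    pooled = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    wr = idx // window
    wc = idx % window
    base_r = (np.arange(Ho) * stride - padding)[None, None, :, None]
    base_c = (np.arange(Wo) * stride - padding)[None, None, None, :]
    winners = (base_r + wr) * W + (base_c + wc)
    return pooled, winners.astype(np.int64)


def unpool_scatter(err: np.ndarray, winners: np.ndarray, spatial: Tuple[int, int]):
    """Scatter a pooled error back to winner positions (summing when two
    windows share a winner), conserving the error total."""
    B, C, Ho, Wo = err.shape
    H, W = spatial
    out = np.zeros((B, C, H * W), dtype=err.dtype)
    bidx = np.arange(B)[:, None, None, None]
    cidx = np.arange(C)[None, :, None, None]
    np.add.at(out, (bidx, cidx, winners), err)
    return out.reshape(B, C, H, W)


def apply_dropout(y: np.ndarray, rate: float, rng: Optional[np.random.Generator],
                  training: bool = True):
    """Inverted dropout.  Returns ``(y_masked, mask)`` with a binary
    Bernoulli(1-rate) mask; surviving units are scaled by ``1/(1-rate)``
    at train time.  In eval mode the mask is all ones and y is unchanged."""
    if not (0.0 <= rate < 1.0):
        raise ValueError(f"dropout rate must be in [0,1), got {rate}")
    if not training or rate == 0.0:
        return y, np.ones_like(y)
    if rng is None:
        raise ValueError("dropout in train mode needs an rng")
    mask = (rng.random(y.shape) >= rate).astype(y.dtype)
    return y * mask / (1.0 - rate), mask


# ---------------------------------------------------------------------------
# Full forward
# ---------------------------------------------------------------------------


def forward_layer(
    layer: LayerSpec,
    state: LayerState,
    x: np.ndarray,
    training: bool = True,
    dropout_rng: Optional[np.random.Generator] = None,
) -> Tuple[LayerTrace, np.ndarray]:
    """One layer's forward computation, recorded as a :class:`LayerTrace`.
    Returns ``(trace, output)`` where the output (post-pool, post-dropout)
    is the next layer's input."""
    if layer.kind == "dense":
        if x.ndim > 2:
            x = x.reshape(x.shape[0], -1)
        out = forward_dense(state, x, layer, training=training)
    else:
        out = forward_conv(state, x, layer, training=training)
    if len(out) == 4:
        y, yprime, xhat, var = out
    else:
        y, yprime = out
        xhat = var = None
    tr = LayerTrace(x=x, post_act=y, deriv=yprime,
                    bn_xhat=xhat, bn_var=var, dropout_rate=layer.dropout_rate)
    if layer.kind == "conv" and layer.pool is not None:
        pooled, winners = maxpool(y, layer.pool.window, layer.pool.stride,
                                  layer.pool.padding)
        tr.pooled, tr.pool_winners = pooled, winners
        h = pooled
    else:
        h = y
    h_drop, mask = apply_dropout(h, layer.dropout_rate, dropout_rng, training)
    tr.dropout_mask = mask
    tr.classifier_input = h_drop.reshape(h_drop.shape[0], -1)
    return tr, h_drop


def network_forward(
    spec: NetworkSpec,
    states: Sequence[LayerState],
    batch: np.ndarray,
    mode: str = "train",
    dropout_rng: Optional[np.random.Generator] = None,
    stop_layer: Optional[int] = None,
) -> ForwardTrace:
    """Run the stack, capturing a full :class:`ForwardTrace`.

    ``mode='train'`` uses batch statistics for batch-norm (updating the
    running estimates) and samples dropout masks; ``mode='eval'`` uses
    running statistics and no dropout.  ``stop_layer`` (a 1-based count of
    layers to run) supports early-exit inference: layers at index >=
    stop_layer are never touched.
    """
    if mode not in ("train", "eval"):
        raise ValueError(f"mode must be 'train' or 'eval', got {mode!r}")
    training = mode == "train"
    n_run = spec.n_layers if stop_layer is None else int(stop_layer)
    if not (1 <= n_run <= spec.n_layers):
        raise ValueError(f"stop_layer must be in [1, {spec.n_layers}]")
    trace = ForwardTrace(mode=mode)
    x = np.asarray(batch)
    for li in range(n_run):
        try:
            tr, x = forward_layer(spec.layers[li], states[li], x,
                                  training=training, dropout_rng=dropout_rng)
        except ShapeError as e:
            raise ShapeError(f"layer {li}: {e}") from e
        trace.layers.append(tr)
    return trace


def flatten_for_classifier(trace: ForwardTrace, i: int) -> np.ndarray:
    """Flattened post-pool, post-dropout activity of layer ``i`` — the
    local classifier's input."""
    return trace[i].classifier_input


def unflatten_from_classifier(flat: np.ndarray, shape) -> np.ndarray:
    """Inverse of the classifier flattening (C-order reshape)."""
    if isinstance(shape, int):
        return flat.reshape(flat.shape[0], shape)
    return flat.reshape((flat.shape[0],) + tuple(shape))


# ---------------------------------------------------------------------------
# Shared backward-through-one-layer
# ---------------------------------------------------------------------------


def _bn_backward(g, xhat, var, scale, axes):
    """Backprop through batch-norm computed with batch statistics.
    ``g`` is the upstream gradient (already scaled for a batch-mean loss).
    Returns (g_pre_bn, d_scale, d_shift) where d_* are gradient *sums*
    over ``axes``."""
    bshape = [1] * g.ndim
    bshape[1] = -1
    m = int(np.prod([g.shape[a] for a in axes]))
    d_scale = (g * xhat).sum(axis=axes)
    d_shift = g.sum(axis=axes)
    dxhat = g * scale.reshape(bshape)
    inv = 1.0 / np.sqrt(var.reshape(bshape) + BN_EPS)
    mean_dxhat = dxhat.mean(axis=axes).reshape(bshape)
    mean_dxhat_xhat = (dxhat * xhat).mean(axis=axes).reshape(bshape)
    gx = inv * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)
    return gx, d_scale, d_shift


def backward_through_layer(
    layer: LayerSpec,
    state: LayerState,
    tr: LayerTrace,
    g_flat: np.ndarray,
    backprop_weight: Optional[np.ndarray] = None,
    need_input_grad: bool = False,
) -> LayerGrads:
    """Exact gradients of a batch-mean loss through one layer.

    ``g_flat`` is the loss gradient at the layer's flattened classifier
    input (post-dropout, post-pool).  The chain runs dropout -> un-pool
    (winners only) -> ReLU mask -> batch-norm -> weights.  When
    ``need_input_grad`` is set, the gradient w.r.t. the layer's input is
    computed with ``backprop_weight`` (default: the layer's own weights;
    pass a fixed random array for feedback alignment).
    """
    if layer.kind == "dense":
        g = np.asarray(g_flat)
        if tr.dropout_rate > 0.0:
            g = g * tr.dropout_mask / (1.0 - tr.dropout_rate)
        g = g * tr.deriv
        if state.bn_scale is not None:
            g, d_scale, d_shift = _bn_backward(g, tr.bn_xhat, tr.bn_var,
                                               state.bn_scale, axes=(0,))
        else:
            d_scale = d_shift = None
        dW = g.T @ tr.x
        db = g.sum(axis=0)
        g_in = None
        if need_input_grad:
            Wb = state.W if backprop_weight is None else backprop_weight
            g_in = g @ Wb
        return LayerGrads(dW, db, d_scale, d_shift, g_in)

    # conv
    B = g_flat.shape[0]
    if tr.pooled is not None:
        g = g_flat.reshape(tr.pooled.shape)
    else:
        g = g_flat.reshape(tr.post_act.shape)
    if tr.dropout_rate > 0.0:
        g = g * tr.dropout_mask / (1.0 - tr.dropout_rate)
    if tr.pool_winners is not None:
        g = unpool_scatter(g, tr.pool_winners, tr.post_act.shape[2:])
    g = g * tr.deriv
    if state.bn_scale is not None:
        g, d_scale, d_shift = _bn_backward(g, tr.bn_xhat, tr.bn_var,
                                           state.bn_scale, axes=(0, 2, 3))
    else:
        d_scale = d_shift = None
    kh, kw = layer.kernel
    dW = _conv2d_weight_grad(tr.x, g, kh, kw)
    db = g.sum(axis=(0, 2, 3))
    g_in = None
    if need_input_grad:
        Wb = state.W if backprop_weight is None else backprop_weight
        g_in = _conv2d_data_grad(g, Wb)
    return LayerGrads(dW, db, d_scale, d_shift, g_in)


# ---------------------------------------------------------------------------
# Dale's-law decomposition
# ---------------------------------------------------------------------------


def dale_pairs(state: LayerState) -> Tuple[np.ndarray, np.ndarray]:
    """Canonical split of a weight array into nonnegative excitatory and
    inhibitory magnitudes with ``W = W_plus - W_minus``."""
    return np.maximum(state.W, 0.0), np.maximum(-state.W, 0.0)


def dale_decompose(states: Sequence[LayerState]) -> List[LayerState]:
    """Split every unit into an excitatory/inhibitory pair.

    Each decomposed layer has doubled width; both copies of a unit receive
    identical input and carry the original activity.  All outgoing weights
    of an excitatory copy are >= 0 and of an inhibitory copy are <= 0, and
    the decomposed network computes exactly the same function (run it with
    :func:`dale_forward` on a duplicated input and read the first half).
    Defined for dense, batch-norm-free stacks.
    """
    out = []
    for state in states:
        if state.W.ndim != 2:
            raise ValueError("Dale decomposition is defined for dense layers")
        if state.bn_scale is not None:
            raise ValueError("Dale decomposition assumes batch-norm-free layers")
        Wp, Wm = dale_pairs(state)
        half = np.concatenate([Wp, -Wm], axis=1)  # inputs: (exc copies, inh copies)
        Wd = np.concatenate([half, half], axis=0)  # outputs: exc copy, inh copy
        bd = np.concatenate([state.b, state.b])
        out.append(LayerState(W=Wd, b=bd))
    return out


def dale_forward(dstates: Sequence[LayerState], x: np.ndarray) -> np.ndarray:
    """Forward pass of a decomposed network: duplicate the input across the
    (excitatory, inhibitory) halves and return the excitatory half of the
    last layer's activity, which equals the original network's output."""
    h = np.concatenate([np.atleast_2d(x), np.atleast_2d(x)], axis=1)
    for st in dstates:
        h = np.maximum(h @ st.W.T + st.b, 0.0)
    return h[:, : h.shape[1] // 2]
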