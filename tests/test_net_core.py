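"""Forward computation: dense/conv layers, pooling, dropout, batch-norm,
flattening, and the Dale's-law decomposition."""

import numpy as np
import pytest

from conftest import naive_conv2d_same
from hypothesis import given, settings
from hypothesis import strategies as st

from locolearn.net_core import (
    ConvSpec,
    DenseSpec,
    LayerState,
    NetworkSpec,
    PoolSpec,
    ShapeError,
    apply_dropout,
    dale_decompose,
    dale_forward,
    dale_pairs,
    flatten_for_classifier,
    forward_conv,
    forward_dense,
    forward_layer,
    init_layer_state,
    maxpool,
    network_forward,
    unflatten_from_classifier,
    unpool_scatter,
)
from locolearn.architectures import cifar_convnet_5, cifar_convnet_10, mnist_mlp


# ---------------------------------------------------------------------------
# dense forward
# ---------------------------------------------------------------------------


def test_forward_dense_hand_example():
    state = LayerState(W=np.array([[1.0, -1.0], [0.0, 2.0]]), b=np.array([0.0, -3.0]))
    y, yprime = forward_dense(state, np.array([2.0, 1.0]))
    np.testing.assert_array_equal(y, [[1.0, 0.0]])
    np.testing.assert_array_equal(yprime, [[1.0, 0.0]])


def test_forward_dense_dead_relu():
    state = LayerState(W=np.ones((3, 4)), b=np.array([0.0, -1.0, -2.0]))
    y, yprime = forward_dense(state, np.zeros(4))
    assert not y.any() and not yprime.any()


def test_forward_dense_shape_mismatch():
    state = LayerState(W=np.ones((3, 4)), b=np.zeros(3))
    with pytest.raises(ShapeError):
        forward_dense(state, np.zeros(5))


def test_relu_mask_consistency(rng):
    state = LayerState(W=rng.normal(size=(6, 5)), b=rng.normal(size=6))
    y, yprime = forward_dense(state, rng.normal(size=(8, 5)))
    np.testing.assert_array_equal(y > 0, yprime == 1)


# ---------------------------------------------------------------------------
# conv forward
# ---------------------------------------------------------------------------


def test_conv_identity_kernel(rng):
    W = np.zeros((2, 2, 1, 1))
    W[0, 0], W[1, 1] = 1.0, 1.0
    state = LayerState(W=W, b=np.zeros(2))
    x = rng.normal(size=(3, 2, 5, 5))
    y, yprime = forward_conv(state, x)
    np.testing.assert_allclose(y, np.maximum(x, 0.0))
    np.testing.assert_array_equal(yprime, (x > 0).astype(float))


def test_conv_zero_kernel_positive_bias(rng):
    state = LayerState(W=np.zeros((4, 3, 3, 3)), b=np.full(4, 2.5))
    y, _ = forward_conv(state, rng.normal(size=(2, 3, 6, 6)))
    np.testing.assert_array_equal(y, np.full((2, 4, 6, 6), 2.5))


def test_conv_matches_naive_loop_oracle(rng):
    for _ in range(3):
        x = rng.normal(size=(2, 3, 8, 8))
        W = rng.normal(size=(4, 3, 3, 3))
        b = rng.normal(size=4)
        state = LayerState(W=W, b=b)
        y, _ = forward_conv(state, x)
        expected = np.maximum(naive_conv2d_same(x, W, b), 0.0)
        np.testing.assert_allclose(y, expected, rtol=0, atol=1e-12)


def test_conv_degenerate_input_rejected():
    # same padding keeps any positive-size input legal; an empty spatial
    # extent is the genuinely unconvolvable case
    state = LayerState(W=np.zeros((1, 1, 7, 7)), b=np.zeros(1))
    with pytest.raises(ShapeError):
        forward_conv(state, np.zeros((1, 1, 0, 0)))


def test_conv_channel_mismatch():
    state = LayerState(W=np.zeros((1, 3, 3, 3)), b=np.zeros(1))
    with pytest.raises(ShapeError):
        forward_conv(state, np.zeros((1, 2, 8, 8)))


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------


def test_maxpool_constant_map_tie_rule():
    x = np.full((1, 1, 4, 4), 3.0)
    pooled, winners = maxpool(x, 2, 2, 0)
    np.testing.assert_array_equal(pooled, np.full((1, 1, 2, 2), 3.0))
    # first (row-major lowest) index inside each window wins the tie
    np.testing.assert_array_equal(winners[0, 0], [[0, 2], [8, 10]])


def test_maxpool_single_peak():
    x = np.zeros((1, 1, 6, 6))
    x[0, 0, 3, 4] = 7.0
    pooled, winners = maxpool(x, 3, 2, 1)
    i, j = np.unravel_index(pooled[0, 0].argmax(), pooled.shape[2:])
    assert winners[0, 0, i, j] == 3 * 6 + 4


@pytest.mark.parametrize("window,stride,pad", [(3, 2, 1), (2, 2, 0)])
def test_maxpool_floor_halving_chain(window, stride, pad, rng):
    x = rng.normal(size=(1, 2, 32, 32))
    sizes = []
    for _ in range(5):
        x, _ = maxpool(x, window, stride, pad)
        sizes.append(x.shape[2])
    assert sizes == [16, 8, 4, 2, 1]


def test_pool_scatter_conserves_error_mass(rng):
    x = rng.normal(size=(2, 3, 8, 8))
    pooled, winners = maxpool(x, 3, 2, 1)
    err = rng.normal(size=pooled.shape)
    scattered = unpool_scatter(err, winners, (8, 8))
    np.testing.assert_allclose(scattered.sum(), err.sum(), rtol=1e-12)


# ---------------------------------------------------------------------------
# dropout
# ---------------------------------------------------------------------------


def test_dropout_rate_zero_identity(rng):
    y = rng.normal(size=(4, 5))
    out, mask = apply_dropout(y, 0.0, rng)
    np.testing.assert_array_equal(out, y)
    assert mask.all()


def test_dropout_deterministic_given_seed():
    y = np.ones((10, 10))
    out1, m1 = apply_dropout(y, 0.5, np.random.default_rng(7))
    out2, m2 = apply_dropout(y, 0.5, np.random.default_rng(7))
    np.testing.assert_array_equal(m1, m2)
    np.testing.assert_array_equal(out1, out2)


def test_dropout_survival_fraction(rng):
    _, mask = apply_dropout(np.ones(10**6), 0.5, rng)
    assert abs(mask.mean() - 0.5) < 0.01


def test_dropout_inverted_scaling(rng):
    y = np.ones((2, 1000))
    out, mask = apply_dropout(y, 0.2, rng)
    # survivors are scaled by 1/(1-rate); eval mode leaves y untouched
    np.testing.assert_allclose(out[mask == 1], 1.25)
    out_eval, _ = apply_dropout(y, 0.2, None, training=False)
    np.testing.assert_array_equal(out_eval, y)


def test_dropout_invalid_rate(rng):
    with pytest.raises(ValueError):
        apply_dropout(np.ones(3), 1.0, rng)


# ---------------------------------------------------------------------------
# network forward
# ---------------------------------------------------------------------------


def test_single_layer_net_equals_forward_dense(rng):
    spec = NetworkSpec((DenseSpec(5, 4),), num_classes=3, input_shape=5)
    state = init_layer_state(spec.layers[0], rng)
    x = rng.normal(size=(6, 5))
    trace = network_forward(spec, [state], x, mode="eval")
    y, yprime = forward_dense(state, x, training=False)
    np.testing.assert_array_equal(trace[0].post_act, y)
    np.testing.assert_array_equal(trace[0].deriv, yprime)


def test_eval_forward_bit_identical(rng):
    spec = NetworkSpec(
        (DenseSpec(5, 8, use_batchnorm=True, dropout_rate=0.3), DenseSpec(8, 6)),
        num_classes=3, input_shape=5)
    states = [init_layer_state(l, rng) for l in spec.layers]
    x = rng.normal(size=(4, 5))
    t1 = network_forward(spec, states, x, mode="eval")
    t2 = network_forward(spec, states, x, mode="eval")
    for a, b in zip(t1.layers, t2.layers):
        np.testing.assert_array_equal(a.classifier_input, b.classifier_input)
        assert a.dropout_mask.all()  # no dropout in eval


def test_batchnorm_train_statistics(rng):
    spec = DenseSpec(6, 10, use_batchnorm=True)
    state = init_layer_state(spec, rng)
    x = rng.normal(loc=3.0, scale=2.5, size=(500, 6))
    _, _, xhat, _ = forward_dense(state, x, spec, training=True)
    np.testing.assert_allclose(xhat.mean(axis=0), 0.0, atol=1e-10)
    np.testing.assert_allclose(xhat.var(axis=0), 1.0, rtol=1e-3)


def test_network_forward_error_names_layer(rng):
    spec = NetworkSpec((DenseSpec(5, 4), DenseSpec(4, 3)), 2, 5)
    states = [init_layer_state(l, rng) for l in spec.layers]
    states[1] = LayerState(W=np.ones((3, 9)), b=np.zeros(3))  # corrupt layer 1
    with pytest.raises(ShapeError, match="layer 1"):
        network_forward(spec, states, rng.normal(size=(2, 5)), mode="eval")


# ---------------------------------------------------------------------------
# flattening
# ---------------------------------------------------------------------------


def test_flatten_documented_ordering():
    maps = np.array([[[[1.0, 2.0], [3.0, 4.0]], [[5.0, 6.0], [7.0, 8.0]]]])
    # flattening is channel-major then row-major: plain C-order reshape
    flat = maps.reshape(1, -1)
    np.testing.assert_array_equal(flat[0], [1, 2, 3, 4, 5, 6, 7, 8])
    np.testing.assert_array_equal(
        unflatten_from_classifier(flat, (2, 2, 2)), maps)


def test_flatten_dense_is_identity_on_masked_activation(rng):
    spec = DenseSpec(5, 6, dropout_rate=0.4)
    state = init_layer_state(spec, rng)
    tr, out = forward_layer(spec, state, rng.normal(size=(3, 5)),
                            training=True, dropout_rng=rng)
    np.testing.assert_array_equal(tr.classifier_input, out)
    # dropped units are exactly zero in the classifier input
    assert not tr.classifier_input[tr.dropout_mask == 0].any()


# ---------------------------------------------------------------------------
# Dale decomposition
# ---------------------------------------------------------------------------


def test_dale_canonical_split():
    st = LayerState(W=np.array([[3.0, -2.0]]), b=np.zeros(1))
    Wp, Wm = dale_pairs(st)
    np.testing.assert_array_equal(Wp, [[3.0, 0.0]])
    np.testing.assert_array_equal(Wm, [[0.0, 2.0]])


def test_dale_nonnegative_matrix_has_zero_inhibitory(rng):
    st = LayerState(W=np.abs(rng.normal(size=(4, 3))), b=np.zeros(4))
    d = dale_decompose([st])[0]
    # inhibitory input columns (second half) are all zero
    assert not d.W[:, 3:].any()
    # outgoing sign constraint: excitatory rows feed through W_plus >= 0
    assert (d.W[:, :3] >= 0).all()


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 10_000))
def test_dale_preserves_network_function(seed):
    rng = np.random.default_rng(seed)
    sizes = [4, 6, 5, 3]
    states = []
    for i in range(3):
        states.append(LayerState(W=rng.normal(size=(sizes[i + 1], sizes[i])),
                                 b=rng.normal(size=sizes[i + 1])))
    x = rng.normal(size=(100, 4))
    h = x
    for s in states:
        h = np.maximum(h @ s.W.T + s.b, 0.0)
    np.testing.assert_allclose(dale_forward(dale_decompose(states), x), h,
                               atol=1e-12)


# ---------------------------------------------------------------------------
# published shape propagation
# ---------------------------------------------------------------------------


def test_reference_shape_propagation():
    five = cifar_convnet_5()
    # flattened size entering the first dense layer
    assert five.layers[3].in_size == 4096
    assert five.classifier_input_size(2) == 4096
    ten = cifar_convnet_10()
    assert ten.classifier_input_size(9) == 512
    assert mnist_mlp().classifier_input_size(2) == 1000
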