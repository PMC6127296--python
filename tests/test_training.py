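"""Training harness: schedule, Nesterov updates, single-step oracle,
reproducibility, locality, early exit, and divergence handling."""

import numpy as np
import pytest

from locolearn import fixed_streams as fs
from locolearn.net_core import DenseSpec, NetworkSpec, forward_layer
from locolearn.local_errors import local_gradients
from locolearn.synth import SyntheticSpec, gen_synthetic
from locolearn.training import (
    TrainConfig,
    TrainingDiverged,
    build_loops,
    early_exit_mac_count,
    early_exit_predict,
    evaluate_layers,
    lr_at,
    nag_step,
    train,
)


@pytest.fixture(scope="module")
def small_task():
    return gen_synthetic(SyntheticSpec("gauss_clusters", 4, 20, 600, 300,
                                       noise=1.0, seed=42))


def _small_spec():
    return NetworkSpec((DenseSpec(20, 32), DenseSpec(32, 32)), 4, 20)


# ---------------------------------------------------------------------------
# schedule and optimizer
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("epoch,expected", [(0, 0.1), (24, 0.1), (25, 0.02),
                                            (99, 0.0008)])
def test_lr_schedule(epoch, expected):
    assert lr_at(epoch, TrainConfig()) == pytest.approx(expected)


def test_nag_reduces_to_sgd_without_momentum(rng):
    p = rng.normal(size=(3, 3))
    g = rng.normal(size=(3, 3))
    p2, v2 = nag_step(p, g, np.zeros_like(p), lr=0.1, momentum=0.0)
    np.testing.assert_allclose(p2, p - 0.1 * g)


def test_nag_velocity_decays_geometrically():
    v = np.array([1.0])
    p = np.array([0.0])
    for _ in range(5):
        p, v = nag_step(p, np.zeros(1), v, lr=0.1, momentum=0.9)
    np.testing.assert_allclose(v, [0.9**5])


def test_nag_trajectory_matches_reference_recursion():
    """Ten steps on a 1-D quadratic against an independently coded scalar
    recursion of the same update rule."""
    lr, mu = 0.05, 0.9
    p = 2.0
    v = 0.0
    ref_p, ref_v = 2.0, 0.0
    for _ in range(10):
        g = 2.0 * p  # d/dp p^2
        p_arr, v_arr = nag_step(np.array([p]), np.array([g]), np.array([v]),
                                lr, mu)
        p, v = float(p_arr[0]), float(v_arr[0])
        # reference: v' = mu*v + g ; p' = p - lr*g - lr*mu*v'
        ref_g = 2.0 * ref_p
        ref_v = mu * ref_v + ref_g
        ref_p = ref_p - lr * ref_g - lr * mu * ref_v
        assert p == pytest.approx(ref_p, rel=1e-12)
        assert v == pytest.approx(ref_v, rel=1e-12)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def test_zero_epochs_leaves_states_untouched(small_task):
    cfg = TrainConfig(epochs=0, master_seed=1, method="lel")
    r = train(_small_spec(), small_task, cfg)
    fresh = train(_small_spec(), small_task, cfg)
    assert r.metrics.empty
    for a, b in zip(r.states, fresh.states):
        np.testing.assert_array_equal(a.W, b.W)  # pure init, no updates


def test_single_lel_step_matches_hand_composed_update(small_task):
    """One batch-of-one SYM step without momentum equals the explicit
    forward + local-error update composition."""
    spec = _small_spec()
    cfg = TrainConfig(epochs=1, batch_size=1, master_seed=7, method="lel",
                      momentum=0.0, lr0=0.05, dtype="float64")
    data = type(small_task)(small_task.X_train[:1], small_task.y_train[:1],
                            small_task.X_test[:1], small_task.y_test[:1], 4)
    result = train(spec, data, cfg)

    # hand-compose: same init seeds, same single sample
    states = [
        __import__("locolearn.net_core", fromlist=["init_layer_state"]).init_layer_state(
            layer,
            np.random.Generator(np.random.PCG64(fs.derive_seed(7, li, "init"))),
            "uniform", np.float64)
        for li, layer in enumerate(spec.layers)
    ]
    loops = build_loops(spec, 7, "SYM")
    x = data.X_train.astype(np.float64)
    t = data.y_train
    h = x
    for li, layer in enumerate(spec.layers):
        tr, h_next = forward_layer(layer, states[li], h, training=True)
        grads, _, _, _ = local_gradients(layer, states[li], tr, loops[li], t)
        states[li].W = states[li].W - 0.05 * grads.dW
        states[li].b = states[li].b - 0.05 * grads.db
        h = h_next
    for got, want in zip(result.states, states):
        np.testing.assert_allclose(got.W, want.W, rtol=1e-12)
        np.testing.assert_allclose(got.b, want.b, rtol=1e-12)


def test_full_run_reproducible_bit_identical(small_task):
    cfg = TrainConfig(epochs=3, batch_size=100, master_seed=5, method="lel")
    r1 = train(_small_spec(), small_task, cfg)
    r2 = train(_small_spec(), small_task, cfg)
    assert r1.metrics.to_csv(index=False) == r2.metrics.to_csv(index=False)
    for a, b in zip(r1.states, r2.states):
        np.testing.assert_array_equal(a.W, b.W)


def test_lel_layer_update_is_local(small_task):
    """Zeroing a higher layer's weights cannot change a lower layer's
    trained parameters: no cross-layer error state exists."""
    cfg = TrainConfig(epochs=1, batch_size=100, master_seed=3, method="lel")
    r1 = train(_small_spec(), small_task, cfg)

    spec = _small_spec()
    from locolearn.net_core import init_layer_state
    states = [
        init_layer_state(layer,
                         np.random.Generator(np.random.PCG64(fs.derive_seed(3, li, "init"))),
                         "uniform", np.float32)
        for li, layer in enumerate(spec.layers)
    ]
    states[1].W[:] = 0.0  # vandalize the higher layer before training
    loops = build_loops(spec, 3, "SYM", dtype=np.float32)
    # replay the harness's own batch order and dropout stream
    shuffle_rng = np.random.Generator(np.random.PCG64(fs.derive_seed(3, 0, "shuffle")))
    X = small_task.X_train.astype(np.float32)
    y = small_task.y_train
    order = shuffle_rng.permutation(len(X))
    vel = np.zeros_like(states[0].W)
    velb = np.zeros_like(states[0].b)
    from locolearn.training import nag_step as step
    for start in range(0, len(X), 100):
        idx = order[start:start + 100]
        tr, _ = forward_layer(spec.layers[0], states[0], X[idx], training=True)
        grads, _, _, _ = local_gradients(spec.layers[0], states[0], tr, loops[0],
                                         y[idx])
        states[0].W, vel = step(states[0].W, grads.dW, vel, 0.1, 0.9)
        states[0].b, velb = step(states[0].b, grads.db, velb, 0.1, 0.9)
    np.testing.assert_allclose(r1.states[0].W, states[0].W, rtol=1e-6)


def test_untrained_network_scores_at_chance(small_task):
    spec = _small_spec()
    cfg = TrainConfig(epochs=0, master_seed=11)
    r = train(spec, small_task, cfg)
    loops = build_loops(spec, 11, "SYM", dtype=np.float32)
    accs, _ = evaluate_layers(spec, r.states, loops,
                              small_task.X_test.astype(np.float32),
                              small_task.y_test)
    assert np.abs(accs - 25.0).max() < 12.0  # chance = 25%, binomial noise


def test_divergence_guard_raises(small_task):
    cfg = TrainConfig(epochs=1, batch_size=100, master_seed=0, method="lel",
                      lr0=1e30, dtype="float32")
    with np.errstate(over="ignore", invalid="ignore"):
        with pytest.raises(TrainingDiverged):
            train(_small_spec(), small_task, cfg)


def test_method_ordering_on_rings():
    """Seed-averaged final accuracy on the rings task orders as
    backpropagation >= local errors (SYM) >= feedback alignment, within a
    2-point band (the methods saturate and may tie at this size)."""
    means = {}
    for method in ("bp", "lel", "fa"):
        accs = []
        for seed in range(5):
            ds = gen_synthetic(SyntheticSpec("xor_rings", 2, 2, 2000, 1000,
                                             noise=0.25, seed=300 + seed))
            spec = NetworkSpec((DenseSpec(2, 16), DenseSpec(16, 16)), 2, 2)
            cfg = TrainConfig(epochs=20, batch_size=100, master_seed=seed,
                              method=method, mode="SYM")
            r = train(spec, ds, cfg)
            final = r.metrics[(r.metrics.split == "test")
                              & (r.metrics.epoch == 19)]
            if method == "lel":
                accs.append(float(final[final.layer == 2].accuracy.iloc[0]))
            else:
                accs.append(float(final.accuracy.iloc[0]))
        means[method] = float(np.mean(accs))
    assert means["bp"] + 2.0 >= means["lel"], means
    assert means["lel"] + 2.0 >= means["fa"], means


def test_bp_and_fa_methods_train(small_task):
    for method in ("bp", "fa"):
        cfg = TrainConfig(epochs=5, batch_size=100, master_seed=2, method=method)
        r = train(_small_spec(), small_task, cfg)
        final = r.metrics[(r.metrics.split == "test") & (r.metrics.epoch == 4)]
        assert float(final.accuracy.iloc[0]) > 80.0, method


# ---------------------------------------------------------------------------
# early exit
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def trained_lel(small_task):
    spec = _small_spec()
    cfg = TrainConfig(epochs=5, batch_size=100, master_seed=8, method="lel")
    r = train(spec, small_task, cfg)
    return spec, r


def test_early_exit_last_layer_consistency(small_task, trained_lel):
    spec, r = trained_lel
    X = small_task.X_test.astype(np.float32)
    full = early_exit_predict(spec, r.states, r.loops, X, stop_layer=2)
    accs, _ = evaluate_layers(spec, r.states, r.loops, X, small_task.y_test)
    assert (full == small_task.y_test).mean() * 100 == pytest.approx(accs[1])


def test_early_exit_isolated_from_higher_layers(small_task, trained_lel):
    spec, r = trained_lel
    X = small_task.X_test.astype(np.float32)
    before = early_exit_predict(spec, r.states, r.loops, X, stop_layer=1)
    vandalized = [s.copy() for s in r.states]
    vandalized[1].W[:] = np.nan  # layer 2 must never be touched
    after = early_exit_predict(spec, vandalized, r.loops, X, stop_layer=1)
    np.testing.assert_array_equal(before, after)


def test_early_exit_mac_count_monotone():
    spec = NetworkSpec((DenseSpec(20, 32), DenseSpec(32, 32), DenseSpec(32, 16)),
                       4, 20)
    counts = [early_exit_mac_count(spec, k) for k in (1, 2, 3)]
    assert counts[0] < counts[1] < counts[2]


def test_early_exit_invalid_stop_layer(small_task, trained_lel):
    spec, r = trained_lel
    with pytest.raises(ValueError):
        early_exit_predict(spec, r.states, r.loops,
                           small_task.X_test.astype(np.float32), stop_layer=3)
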