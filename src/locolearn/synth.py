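"""Seeded synthetic classification tasks for desk-scale experiments.

Three task families, each deterministic given its seed and balanced
across classes to within one sample:

``gauss_clusters``
    Linearly separable control: one spherical Gaussian blob per class,
    centers drawn at random directions with pairwise separation well
    above the noise scale.
``xor_rings``
    Linearly non-separable control: samples on concentric annuli (one
    radius band per class) with radial Gaussian noise, embedded in the
    plane.  No linear classifier can do well; a two-layer ReLU network
    can, which is what makes the task useful for depth-benefit and
    method-contrast experiments.
``teacher_net``
    Hierarchically structured labels: the argmax output of a frozen
    random two-hidden-layer ReLU teacher network applied to Gaussian
    inputs, relabeled/resampled until classes are balanced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SyntheticSpec", "Dataset", "gen_synthetic"]


@dataclass(frozen=True)
class SyntheticSpec:
    task: str = "gauss_clusters"
    n_classes: int = 4
    n_features: int = 20
    n_train: int = 2000
    n_test: int = 1000
    noise: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.task not in ("gauss_clusters", "xor_rings", "teacher_net"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")


@dataclass
class Dataset:
    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    n_classes: int

    @property
    def n_features(self) -> int:
        return self.X_train.shape[1]


def _balanced_labels(n: int, C: int, rng: np.random.Generator) -> np.ndarray:
    """Class labels balanced to within one sample, in random order."""
    y = np.arange(n) % C
    rng.shuffle(y)
    return y


def _gauss_centers(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    # unit-direction centers scaled so separation dominates the noise
    centers = rng.normal(size=(spec.n_classes, spec.n_features))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    return centers * 4.0


def _gauss_clusters(spec: SyntheticSpec, n: int, rng: np.random.Generator,
                    centers: np.ndarray):
    y = _balanced_labels(n, spec.n_classes, rng)
    X = centers[y] + spec.noise * rng.normal(size=(n, spec.n_features))
    return X, y


def _xor_rings(spec: SyntheticSpec, n: int, rng: np.random.Generator,
               structure=None):
    y = _balanced_labels(n, spec.n_classes, rng)
    radius = 1.0 + 1.5 * y  # one annulus per class
    r = radius + spec.noise * rng.normal(size=n)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    X2 = np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
    if spec.n_features > 2:
        # embed in a higher-dimensional ambient space with noise dims
        X = np.concatenate(
            [X2, spec.noise * rng.normal(size=(n, spec.n_features - 2))], axis=1
        )
    else:
        X = X2
    return X, y


def _teacher_weights(spec: SyntheticSpec, rng: np.random.Generator):
    h = max(2 * spec.n_features, 16)
    W1 = rng.normal(0, np.sqrt(2.0 / spec.n_features), size=(h, spec.n_features))
    W2 = rng.normal(0, np.sqrt(2.0 / h), size=(h, h))
    W3 = rng.normal(0, np.sqrt(2.0 / h), size=(spec.n_classes, h))
    return W1, W2, W3


def _teacher_net(spec: SyntheticSpec, n: int, rng: np.random.Generator, weights):
    W1, W2, W3 = weights

    def label(X):
        a = np.maximum(X @ W1.T, 0.0)
        a = np.maximum(a @ W2.T, 0.0)
        return (a @ W3.T).argmax(axis=1)

    # rejection-fill per class until balanced to within one sample
    per = [n // spec.n_classes + (1 if c < n % spec.n_classes else 0)
           for c in range(spec.n_classes)]
    Xs = [[] for _ in range(spec.n_classes)]
    need = sum(per)
    guard = 0
    while need > 0 and guard < 10000:
        cand = rng.normal(size=(max(4 * need, 64), spec.n_features))
        lab = label(cand)
        for c in range(spec.n_classes):
            take = cand[lab == c][: per[c] - len(Xs[c])]
            Xs[c].extend(take)
        need = sum(per[c] - len(Xs[c]) for c in range(spec.n_classes))
        guard += 1
    if need > 0:
        raise RuntimeError("teacher network produced a degenerate labeling; reseed")
    X = np.concatenate([np.asarray(Xs[c]) for c in range(spec.n_classes)])
    y = np.concatenate([np.full(per[c], c) for c in range(spec.n_classes)])
    order = rng.permutation(len(y))
    return X[order] + spec.noise * 0.1 * rng.normal(size=X.shape), y[order]


def gen_synthetic(spec: SyntheticSpec) -> Dataset:
    """Generate a train/test dataset; deterministic given ``spec.seed``.
    The task structure (class centers, teacher weights, ring radii) is
    drawn once and shared by both splits."""
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    if spec.task == "gauss_clusters":
        gen, structure = _gauss_clusters, _gauss_centers(spec, rng)
    elif spec.task == "teacher_net":
        gen, structure = _teacher_net, _teacher_weights(spec, rng)
    else:
        gen, structure = _xor_rings, None
    X_train, y_train = gen(spec, spec.n_train, rng, structure)
    X_test, y_test = gen(spec, spec.n_test, rng, structure)
    return Dataset(X_train, y_train, X_test, y_test, spec.n_classes)
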