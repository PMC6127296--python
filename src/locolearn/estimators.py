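"""scikit-learn estimators over the training harness.

These classifiers train a dense multi-layer ReLU network on tabular data
with one of the three methods and expose the usual estimator surface
(``fit`` / ``predict`` / ``predict_proba`` / ``get_params`` /
``set_params``), so they compose with pipelines and model selection.
Convolutional stacks are driven through :func:`locolearn.training.train`
directly (or the CLI) rather than through this tabular interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import softmax
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.preprocessing import LabelEncoder
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .local_errors import scores
from .net_core import DenseSpec, NetworkSpec, network_forward
from .baselines import top_forward
from .training import TrainConfig, train, evaluate_layers, early_exit_predict

__all__ = [
    "LocalErrorClassifier",
    "FeedbackAlignmentClassifier",
    "BackpropClassifier",
]


@dataclass
class _SimpleData:
    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray


class _NetworkClassifier(ClassifierMixin, BaseEstimator):
    """Shared fit/predict machinery; subclasses pin the training method."""

    _method = "lel"

    def __init__(self, hidden_layer_sizes=(64, 64), feedback_mode="SYM",
                 loss="cross_entropy", lr0=0.1, momentum=0.9, epochs=20,
                 lr_drop_factor=5.0, lr_drop_every=25, batch_size=100,
                 dropout_rate=0.0, batchnorm=False, weight_distribution="uniform",
                 random_state=0):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.feedback_mode = feedback_mode
        self.loss = loss
        self.lr0 = lr0
        self.momentum = momentum
        self.epochs = epochs
        self.lr_drop_factor = lr_drop_factor
        self.lr_drop_every = lr_drop_every
        self.batch_size = batch_size
        self.dropout_rate = dropout_rate
        self.batchnorm = batchnorm
        self.weight_distribution = weight_distribution
        self.random_state = random_state

    # -- construction ------------------------------------------------------
    def _build_spec(self, n_features: int, n_classes: int) -> NetworkSpec:
        sizes = [n_features] + list(self.hidden_layer_sizes)
        layers = tuple(
            DenseSpec(sizes[i], sizes[i + 1], use_batchnorm=self.batchnorm,
                      dropout_rate=self.dropout_rate)
            for i in range(len(sizes) - 1)
        )
        return NetworkSpec(layers, num_classes=n_classes, input_shape=n_features)

    def _build_config(self) -> TrainConfig:
        return TrainConfig(
            lr0=self.lr0, momentum=self.momentum, epochs=self.epochs,
            lr_drop_factor=self.lr_drop_factor, lr_drop_every=self.lr_drop_every,
            batch_size=self.batch_size,
            master_seed=0 if self.random_state is None else int(self.random_state),
            method=self._method, mode=self.feedback_mode, loss_kind=self.loss,
            distribution=self.weight_distribution,
        )

    # -- sklearn surface ---------------------------------------------------
    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        self._label_encoder_ = LabelEncoder()
        yi = self._label_encoder_.fit_transform(y)
        self.classes_ = self._label_encoder_.classes_
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        self.n_features_in_ = X.shape[1]
        self.spec_ = self._build_spec(X.shape[1], len(self.classes_))
        cfg = self._build_config()
        # the harness wants a held-out split for its epoch metrics; fitting
        # an estimator uses the training data for both
        result = train(self.spec_, _SimpleData(X, yi, X[:1], yi[:1]), cfg)
        self.states_ = result.states
        self.loops_ = result.loops
        self.top_ = result.top
        self.feedback_ = result.feedback
        self.metrics_ = result.metrics
        self.n_layers_ = self.spec_.n_layers
        return self

    def decision_function(self, X):
        check_is_fitted(self, "states_")
        X = check_array(X, dtype=np.float64)
        trace = network_forward(self.spec_, self.states_, X, mode="eval")
        if self._method == "lel":
            return scores(self.loops_[-1].M, trace[self.n_layers_ - 1].classifier_input)
        return top_forward(self.top_, trace)

    def predict(self, X):
        idx = self.decision_function(X).argmax(axis=1)
        return self.classes_[idx]

    def predict_proba(self, X):
        return softmax(self.decision_function(X), axis=1)


class LocalErrorClassifier(_NetworkClassifier):
    """Network trained purely from layer-local errors.

    Every hidden layer carries a fixed random classifier; its error,
    projected back through the feedback matrix selected by
    ``feedback_mode`` (``SYM``, ``SCFB``, ``INDEP`` or ``TLC``), drives
    that layer's updates during the forward sweep.  Predictions come from
    the last layer's local classifier; ``predict_layer`` exposes the
    early-exit decisions of intermediate layers.
    """

    _method = "lel"

    def predict_layer(self, X, layer: int):
        """Early-exit prediction from layer ``layer`` (1-based); layers
        above it are never evaluated."""
        check_is_fitted(self, "states_")
        X = check_array(X, dtype=np.float64)
        idx = early_exit_predict(self.spec_, self.states_, self.loops_, X, layer)
        return self.classes_[idx]

    def layer_accuracies(self, X, y):
        """Accuracy (%) of every layer's local classifier on ``(X, y)``."""
        check_is_fitted(self, "states_")
        X = check_array(X, dtype=np.float64)
        yi = self._label_encoder_.transform(y)
        accs, _ = evaluate_layers(self.spec_, self.states_, self.loops_, X, yi)
        return accs


class FeedbackAlignmentClassifier(_NetworkClassifier):
    """Baseline trained by backpropagating the top error through fixed
    random feedback matrices instead of transposed weights."""

    _method = "fa"


class BackpropClassifier(_NetworkClassifier):
    """Standard backpropagation baseline over the identical forward stack."""

    _method = "bp"
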