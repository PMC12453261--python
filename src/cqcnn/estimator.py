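"""scikit-learn estimator interface to the hybrid network.

:class:`CQCNNClassifier` wraps model construction, training and prediction
behind the standard fit/predict/predict_proba surface, so the model composes
with sklearn pipelines, ``clone`` and model selection.  Input ``X`` is an
image stack of shape ``(n_samples, side, side)`` (or ``(n, 1, side, side)``),
with intensities in [0, 1]; ``y`` holds two class labels.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError

from .network import CQCNNNetwork, ModelConfig, count_parameters
from .training import TrainConfig, evaluate, metrics_from_predictions, train


class CQCNNClassifier(ClassifierMixin, BaseEstimator):
    """Hybrid classical-quantum convolutional classifier.

    Parameters
    ----------
    n_qubits : int, default 2
        Width of the quantum register (omega); 2 and 3 are the reference
        configurations.
    variant : {"quantum", "classical-control"}
        "classical-control" swaps the circuit for a classical block with an
        identical trainable-parameter count.
    dialect : {"zz-interaction", "eq3-cz"}
        Entangling block of the data encoding.
    epochs, batch_size, learning_rate, optimizer
        Training protocol; defaults follow the reference configuration
        (Adam, batch 32, lr 1e-3).
    random_state : int, default 0
        Seeds weight initialisation, shuffling and dropout; runs are
        bit-reproducible in exact-expectation mode.

    Attributes
    ----------
    network_ : CQCNNNetwork
        The fitted parameter container.
    classes_ : ndarray of shape (2,)
    history_ : dict
        Per-epoch training loss/accuracy curves.
    n_parameters_ : int
        Total trainable parameter count.
    """

    def __init__(self, n_qubits: int = 2, variant: str = "quantum",
                 image_side: int = 128, dialect: str = "zz-interaction",
                 observable: str = "parity", feature_scaling: str = "tanh",
                 dropout_rate: float = 0.25, repetitions: int = 1,
                 epochs: int = 10, batch_size: int = 32,
                 learning_rate: float = 1e-3, optimizer: str = "adam",
                 random_state: int = 0):
        self.n_qubits = n_qubits
        self.variant = variant
        self.image_side = image_side
        self.dialect = dialect
        self.observable = observable
        self.feature_scaling = feature_scaling
        self.dropout_rate = dropout_rate
        self.repetitions = repetitions
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _model_config(self, seed: int) -> ModelConfig:
        return ModelConfig(image_side=self.image_side, omega=self.n_qubits,
                           dropout_rate=self.dropout_rate, dialect=self.dialect,
                           feature_scaling=self.feature_scaling,
                           observable=self.observable,
                           repetitions=self.repetitions, seed=seed,
                           variant=self.variant)

    def _encode_y(self, y):
        y = np.asarray(y).ravel()
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(
                f"binary classifier: need exactly 2 classes, got {classes.size}")
        return classes, np.searchsorted(classes, y)

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=np.float64)
        self.classes_, y_idx = self._encode_y(y)
        seed = 0 if self.random_state is None else int(self.random_state)
        self.network_ = CQCNNNetwork(self._model_config(seed))
        cfg = TrainConfig(batch_size=self.batch_size,
                          learning_rate=self.learning_rate,
                          optimizer=self.optimizer, epochs=self.epochs,
                          seed=seed)
        yv = None
        if X_val is not None:
            yv = np.searchsorted(self.classes_, np.asarray(y_val).ravel())
        self.history_ = train(self.network_, X, y_idx, cfg, X_val, yv)
        self.n_parameters_ = self.network_.n_parameters()
        self.parameter_count_ = count_parameters(self.network_.cfg)
        return self

    def _check_fitted(self):
        if not hasattr(self, "network_"):
            raise NotFittedError("this CQCNNClassifier instance is not fitted yet")

    def predict_proba(self, X):
        self._check_fitted()
        return self.network_.predict_proba(np.asarray(X, dtype=np.float64))

    def predict(self, X):
        self._check_fitted()
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def evaluate(self, X, y, positive_class=None):
        """Confusion-table metrics report against true labels *y*."""
        self._check_fitted()
        y_idx = np.searchsorted(self.classes_, np.asarray(y).ravel())
        pos = 1 if positive_class is None else int(
            np.searchsorted(self.classes_, positive_class))
        pred = self.predict_proba(X).argmax(axis=1)
        return metrics_from_predictions(y_idx, pred, positive_class=pos)
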