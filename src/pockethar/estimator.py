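"""Scikit-learn-style estimator wrapping the 1D-CNN-LSTM.

``CNNLSTMClassifier`` takes a 3-D input ``(n_windows, window_length,
n_features)`` and string or integer class labels, and follows sklearn
conventions: constructor parameters stored verbatim, fitted attributes
with a trailing underscore, ``fit``/``predict``/``predict_proba``/``score``
and ``get_params``/``set_params`` (via ``BaseEstimator``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .model import ArchitectureSpec, TrainConfig, build_model, resolve_architecture

__all__ = ["CNNLSTMClassifier"]


class CNNLSTMClassifier(BaseEstimator, ClassifierMixin):
    """Hybrid convolutional-recurrent window classifier.

    Parameters
    ----------
    architecture : "desk", "paper" or ArchitectureSpec
        Layer stack to realise.  "paper" is the full-scale reference
        network; "desk" divides conv filters and LSTM units by 8.
    learning_rate, epochs, batch_size
        Adam settings; desk-scale defaults.
    checkpoint_policy : "last" or "best_on_holdout"
        With "best_on_holdout" the weights with the highest holdout
        accuracy are restored after training (a holdout must be passed to
        ``fit`` or ``validation_fraction`` must be > 0).
    validation_fraction : float
        Fraction of training windows carved off as holdout when the policy
        needs one and none is supplied.
    random_state : int
        Seeds weight initialisation, shuffling and dropout.

    Attributes
    ----------
    classes_ : ndarray of class labels in sorted order.
    net_ : the underlying NumPy network.
    history_ : DataFrame with columns epoch, loss, holdout_accuracy.
    n_params_ : trainable parameter count.
    """

    def __init__(
        self,
        architecture: "str | ArchitectureSpec" = "desk",
        learning_rate: float = 0.001,
        epochs: int = 10,
        batch_size: int = 256,
        checkpoint_policy: str = "last",
        validation_fraction: float = 0.1,
        random_state: int = 0,
    ):
        self.architecture = architecture
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.checkpoint_policy = checkpoint_policy
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _check_X(self, X: np.ndarray, fitted: bool = False) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3:
            raise ValueError(f"X must be (n_windows, window_length, n_features), got {X.shape}")
        if fitted and X.shape[1:] != (self.window_length_, self.n_features_):
            raise ValueError(
                f"X has shape {X.shape[1:]}, fitted for "
                f"({self.window_length_}, {self.n_features_})"
            )
        return X

    def fit(self, X, y, holdout: "tuple | None" = None):
        # validates TrainConfig-style invariants up front
        TrainConfig(
            learning_rate=self.learning_rate, epochs=self.epochs,
            batch_size=self.batch_size, checkpoint_policy=self.checkpoint_policy,
        )
        X = self._check_X(X)
        y = np.asarray(y)
        if len(X) != len(y) or len(X) == 0:
            raise ValueError("X and y must be non-empty and the same length")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        self.window_length_, self.n_features_ = X.shape[1], X.shape[2]

        rng = np.random.default_rng(self.random_state)
        net = build_model(
            resolve_architecture(self.architecture),
            self.window_length_, self.n_features_,
            seed=int(rng.integers(2**31)),
        )
        if net.n_classes < len(self.classes_):
            raise ValueError(
                f"architecture outputs {net.n_classes} classes, data has {len(self.classes_)}"
            )

        if holdout is None and self.checkpoint_policy == "best_on_holdout":
            n_val = max(1, int(round(self.validation_fraction * len(X))))
            perm = rng.permutation(len(X))
            val, keep = perm[:n_val], perm[n_val:]
            holdout = (X[val], y[val])
            X, y_idx = X[keep], y_idx[keep]

        opt = nn.Adam(lr=self.learning_rate)
        history = []
        best_acc, best_weights = -np.inf, None
        for epoch in range(self.epochs):
            perm = rng.permutation(len(X))
            losses = []
            for lo in range(0, len(X), self.batch_size):
                sel = perm[lo : lo + self.batch_size]
                losses.append(net.train_batch(X[sel], y_idx[sel], rng))
                opt.step(net)
            hold_acc = np.nan
            if holdout is not None:
                hold_acc = self._holdout_accuracy(net, *holdout)
                if self.checkpoint_policy == "best_on_holdout" and hold_acc > best_acc:
                    best_acc, best_weights = hold_acc, net.get_weights()
            history.append(
                {"epoch": epoch + 1, "loss": float(np.mean(losses)),
                 "holdout_accuracy": hold_acc}
            )
        if self.checkpoint_policy == "best_on_holdout" and best_weights is not None:
            net.set_weights(best_weights)
        self.net_ = net
        self.history_ = pd.DataFrame(history)
        self.n_params_ = net.n_params
        return self

    def _net_proba(self, net: nn.NeuralNet, X: np.ndarray) -> np.ndarray:
        probs = net.predict_proba(np.asarray(X, dtype=np.float32))
        if probs.shape[1] > len(self.classes_):
            # surplus logits (architecture wider than the label set): fold
            # their mass away and renormalise over observed classes
            probs = probs[:, : len(self.classes_)]
            probs = probs / probs.sum(axis=1, keepdims=True)
        return probs

    def _holdout_accuracy(self, net: nn.NeuralNet, Xh, yh) -> float:
        idx = np.argmax(self._net_proba(net, Xh), axis=1)
        return float(np.mean(self.classes_[idx] == np.asarray(yh)))

    def predict_proba(self, X) -> np.ndarray:
        X = self._check_X(X, fitted=True)
        return self._net_proba(self.net_, X)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))
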