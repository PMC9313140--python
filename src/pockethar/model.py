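"""Declarative 1D-CNN-LSTM architecture and training configuration.

The reference network: six stride-1 "same"-padded convolutions interleaved
with three average poolings (size 3) and four dropout layers (rate 0.3),
followed by a 512-unit tanh LSTM and four dense layers (100 → 28 → 64 → 6,
relu except the final softmax).  ``default_architecture()`` reproduces it
exactly; ``desk_architecture()`` divides conv filters and LSTM units by 8
for a configuration that trains in minutes on one CPU and is the default
for tests and sweeps.

The network maps a batch of (window_length × n_features) segments to a
6-class probability simplex.  Loss is categorical cross-entropy (the
standard pairing with a softmax output).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np

from . import nn
from .activities import N_CLASSES

__all__ = [
    "ConvSpec", "DropoutSpec", "PoolSpec", "LSTMSpec", "DenseSpec",
    "ArchitectureSpec", "ArchitectureError", "TrainConfig",
    "default_architecture", "desk_architecture", "build_model", "train",
]


class ArchitectureError(ValueError):
    """Raised when a layer stack cannot be realised for the given input shape."""


@dataclass(frozen=True)
class ConvSpec:
    filters: int
    kernel: int
    activation: str = "relu"
    padding: str = "same"


@dataclass(frozen=True)
class DropoutSpec:
    rate: float


@dataclass(frozen=True)
class PoolSpec:
    kind: str = "average"
    size: int = 3
    padding: str = "same"


@dataclass(frozen=True)
class LSTMSpec:
    units: int
    activation: str = "tanh"


@dataclass(frozen=True)
class DenseSpec:
    units: int
    activation: str = "relu"


LayerSpec = Union[ConvSpec, DropoutSpec, PoolSpec, LSTMSpec, DenseSpec]


@dataclass(frozen=True)
class ArchitectureSpec:
    """Ordered layer descriptors for the hybrid network."""

    layers: tuple[LayerSpec, ...]

    def count(self, kind: type) -> int:
        return sum(isinstance(l, kind) for l in self.layers)

    @property
    def n_conv(self) -> int:
        return self.count(ConvSpec)

    @property
    def n_pool(self) -> int:
        return self.count(PoolSpec)

    @property
    def n_dropout(self) -> int:
        return self.count(DropoutSpec)

    @property
    def n_lstm(self) -> int:
        return self.count(LSTMSpec)

    @property
    def n_dense(self) -> int:
        return self.count(DenseSpec)


def default_architecture() -> ArchitectureSpec:
    """The full-scale reference architecture (6 conv / 3 pool / 4 dropout /
    1 LSTM / 4 dense, final dense 6-unit softmax)."""
    return ArchitectureSpec(
        (
            ConvSpec(512, 5),
            DropoutSpec(0.3),
            PoolSpec("average", 3),
            ConvSpec(256, 3),
            DropoutSpec(0.3),
            ConvSpec(64, 3),
            PoolSpec("average", 3),
            ConvSpec(128, 3),
            ConvSpec(256, 5),
            DropoutSpec(0.3),
            ConvSpec(512, 7),
            DropoutSpec(0.3),
            PoolSpec("average", 3),
            LSTMSpec(512, "tanh"),
            DenseSpec(100, "relu"),
            DenseSpec(28, "relu"),
            DenseSpec(64, "relu"),
            DenseSpec(N_CLASSES, "softmax"),
        )
    )


def desk_architecture(divisor: int = 8) -> ArchitectureSpec:
    """Same layout with conv filters and LSTM units divided by *divisor*."""
    scaled = []
    for lay in default_architecture().layers:
        if isinstance(lay, ConvSpec):
            scaled.append(replace(lay, filters=max(1, lay.filters // divisor)))
        elif isinstance(lay, LSTMSpec):
            scaled.append(replace(lay, units=max(1, lay.units // divisor)))
        else:
            scaled.append(lay)
    return ArchitectureSpec(tuple(scaled))


def resolve_architecture(architecture: "str | ArchitectureSpec") -> ArchitectureSpec:
    if isinstance(architecture, ArchitectureSpec):
        return architecture
    if architecture == "paper":
        return default_architecture()
    if architecture == "desk":
        return desk_architecture()
    raise ValueError(f"unknown architecture {architecture!r}")


def build_model(
    spec: ArchitectureSpec,
    window_length: int,
    n_features: int,
    seed: int = 0,
) -> nn.NeuralNet:
    """Realise a spec as a trainable network for the given input shape.

    Pooling is ceil-mode, so the temporal length never drops below 1 and
    any ``window_length >= 1`` is representable (the reference study's
    sweep starts at W=5 with this same stack).
    """
    if window_length < 1:
        raise ArchitectureError(f"window_length must be >= 1, got {window_length}")
    if n_features < 1:
        raise ArchitectureError(f"n_features must be >= 1, got {n_features}")
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    t, c = window_length, n_features
    seq_ended = False
    for lay in spec.layers:
        if isinstance(lay, ConvSpec):
            if seq_ended:
                raise ArchitectureError("convolution after the recurrent layer")
            layers.append(nn.Conv1D(c, lay.filters, lay.kernel, rng))
            if lay.activation == "relu":
                layers.append(nn.ReLU())
            c = lay.filters
        elif isinstance(lay, PoolSpec):
            if lay.kind != "average":
                raise ArchitectureError(f"unsupported pooling kind {lay.kind!r}")
            layers.append(nn.AvgPool1D(lay.size))
            t = -(-t // lay.size)
        elif isinstance(lay, DropoutSpec):
            layers.append(nn.Dropout(lay.rate))
        elif isinstance(lay, LSTMSpec):
            layers.append(nn.LSTM(c, lay.units, rng))
            c = lay.units
            seq_ended = True
        elif isinstance(lay, DenseSpec):
            if not seq_ended:
                raise ArchitectureError("dense layer before the recurrent layer")
            layers.append(nn.Dense(c, lay.units, rng, relu=lay.activation == "relu"))
            c = lay.units
        else:  # pragma: no cover
            raise ArchitectureError(f"unknown layer spec {lay!r}")
    final = spec.layers[-1]
    if not (isinstance(final, DenseSpec) and final.activation == "softmax"):
        raise ArchitectureError("final layer must be a softmax dense layer")
    return nn.NeuralNet(layers, n_classes=final.units)


@dataclass
class TrainConfig:
    """Optimisation settings.

    Full-scale defaults: Adam, learning rate 0.001, 500 epochs, batch 2000.
    ``checkpoint_policy='best_on_holdout'`` keeps the weights with the best
    holdout accuracy; the holdout comes from a validation split carved from
    the training participants by default, or from the test set when
    ``holdout_source='test_set'`` (replicating the reference protocol, at
    the price of test-set leakage).
    """

    optimizer: str = "adam"
    learning_rate: float = 0.001
    epochs: int = 500
    batch_size: int = 2000
    seed: int = 0
    checkpoint_policy: str = "best_on_holdout"
    holdout_source: str = "validation_split"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.checkpoint_policy not in ("best_on_holdout", "last"):
            raise ValueError(f"unknown checkpoint_policy {self.checkpoint_policy!r}")
        if self.holdout_source not in ("validation_split", "test_set"):
            raise ValueError(f"unknown holdout_source {self.holdout_source!r}")


def train(spec, train_windows, config: TrainConfig, test_windows=None):
    """Fit a classifier on a WindowSet under a TrainConfig.

    Thin wrapper over :class:`~pockethar.estimator.CNNLSTMClassifier`.
    Requires all six activity classes in the training windows.  Returns the
    fitted estimator; its ``history_`` frame records per-epoch loss and
    holdout accuracy.
    """
    from .activities import ACTIVITIES
    from .estimator import CNNLSTMClassifier

    present = set(np.unique(train_windows.labels))
    missing = set(ACTIVITIES) - present
    if missing:
        raise ValueError(f"training data lacks classes: {sorted(missing)}")

    holdout = None
    if config.checkpoint_policy == "best_on_holdout":
        if config.holdout_source == "test_set":
            if test_windows is None:
                raise ValueError("holdout_source='test_set' requires test windows")
            holdout = (test_windows.windows, test_windows.labels)
        else:
            # carve the last training participant out as the holdout
            pids = np.unique(train_windows.participant_ids)
            if len(pids) < 2:
                raise ValueError("validation split needs >= 2 training participants")
            val_mask = train_windows.participant_ids == pids[-1]
            holdout = (
                train_windows.windows[val_mask],
                train_windows.labels[val_mask],
            )
            train_windows = train_windows.subset(~val_mask)

    clf = CNNLSTMClassifier(
        architecture=spec,
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        batch_size=config.batch_size,
        checkpoint_policy=config.checkpoint_policy,
        random_state=config.seed,
    )
    clf.fit(train_windows.windows, train_windows.labels, holdout=holdout)
    return clf
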