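"""Core learning units (CLUs): the pluggable neural base learners.

Every ensemble in this package is built from CLUs — small neural classifiers
or regressors described by a :class:`CLUSpec`.  Three kinds are provided:

``mlp``
    a multilayer perceptron for tabular feature vectors; ``layer_sizes``
    lists all layer widths including the width-1 output layer.
``cnn``
    a compact convolutional network for single-channel images: stacked
    conv(3x3)->ReLU->maxpool blocks (filter counts in ``conv_filters``)
    followed by a dense head given by ``layer_sizes``.
``rnn``
    a recurrent network for minute-level sequences: one GRU (or LSTM) layer
    with additive-attention pooling, then a dense head from ``layer_sizes``.

Training applies a step-decay learning-rate schedule (multiply by 0.9 every
``lr_decay_period`` epochs, i.e. the update λ <- λ - 0.1·λ) and keeps the
weights of the epoch with the lowest validation loss, restoring them when
training finishes.  With a fixed spec (including its seed) and fixed data,
two training runs are bitwise identical.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .nn import (
    Activation,
    AdditiveAttention,
    Conv2D,
    Dense,
    Flatten,
    GRU,
    LSTM,
    MaxPool2D,
    Network,
)

__all__ = [
    "CLUSpec",
    "CLU",
    "TrainingLog",
    "ConfigurationError",
    "NotFittedError",
    "TrainingDivergedError",
    "build_clu",
    "lr_schedule_update",
    "train_clu",
    "predict_proba",
    "derive_rng",
]


class ConfigurationError(ValueError):
    """Raised for an invalid CLU specification."""


class NotFittedError(RuntimeError):
    """Raised when prediction is requested from an unfitted model."""


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes NaN."""


def derive_rng(seed: int, *key: int) -> np.random.Generator:
    """A reproducible generator derived from ``seed`` and a purpose key."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed & 0x7FFFFFFF, spawn_key=tuple(key)))


@dataclass(frozen=True)
class CLUSpec:
    """Declarative description of a core learning unit.

    ``layer_sizes`` is the dense stack for ``mlp`` (ending in the width-1
    output) and the dense head for ``cnn``/``rnn``.  ``loss`` must pair with
    ``output_mode``: binary cross-entropy for probability outputs (bagging
    and stacking members), mean squared error for regression outputs
    (boosting residual learners).
    """

    kind: str = "mlp"
    layer_sizes: tuple[int, ...] = (64, 32, 1)
    activation: str = "relu"
    output_mode: str = "probability"
    loss: str = "binary_cross_entropy"
    optimizer: str = "adam"
    initial_lr: float = 1e-3
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0
    conv_filters: tuple[int, ...] = (16, 32, 64)
    rnn_units: int = 64
    rnn_cell: str = "gru"
    attention: bool = True
    lr_decay_period: int = 50

    def __post_init__(self) -> None:
        object.__setattr__(self, "layer_sizes", tuple(int(v) for v in self.layer_sizes))
        object.__setattr__(self, "conv_filters", tuple(int(v) for v in self.conv_filters))
        if self.kind not in {"mlp", "cnn", "rnn"}:
            raise ConfigurationError(f"unknown CLU kind {self.kind!r}")
        if not self.layer_sizes:
            raise ConfigurationError("layer_sizes must be non-empty")
        if any(w <= 0 for w in self.layer_sizes):
            raise ConfigurationError("layer_sizes must be positive")
        if self.layer_sizes[-1] != 1:
            raise ConfigurationError("output layer width must be 1 for binary tasks")
        if self.output_mode not in {"probability", "regression"}:
            raise ConfigurationError(f"unknown output_mode {self.output_mode!r}")
        if self.loss not in {"binary_cross_entropy", "mean_squared_error"}:
            raise ConfigurationError(f"unknown loss {self.loss!r}")
        if self.optimizer not in {"adam", "sgd"}:
            raise ConfigurationError(f"unknown optimizer {self.optimizer!r}")
        if (self.loss == "mean_squared_error") != (self.output_mode == "regression"):
            raise ConfigurationError(
                "loss/output_mode mismatch: mean_squared_error pairs with regression, "
                "binary_cross_entropy with probability"
            )
        if self.rnn_cell not in {"gru", "lstm"}:
            raise ConfigurationError(f"unknown rnn_cell {self.rnn_cell!r}")
        if self.initial_lr <= 0:
            raise ConfigurationError("initial_lr must be positive")
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ConfigurationError("epochs and batch_size must be positive")

    def replace(self, **kw) -> "CLUSpec":
        return dataclasses.replace(self, **kw)

    # -- YAML round-trip --------------------------------------------------
    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["layer_sizes"] = list(self.layer_sizes)
        d["conv_filters"] = list(self.conv_filters)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "CLUSpec":
        return cls(**yaml.safe_load(text))


@dataclass
class TrainingLog:
    """Per-epoch training trace with the checkpointed best epoch."""

    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def append(self, epoch: int, train_loss: float, val_loss: float, lr: float) -> None:
        self.epochs.append(epoch)
        self.train_loss.append(train_loss)
        self.val_loss.append(val_loss)
        self.lr.append(lr)

    @property
    def best_val_loss(self) -> float:
        return self.val_loss[self.best_epoch]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"epoch": self.epochs, "train_loss": self.train_loss, "val_loss": self.val_loss, "lr": self.lr}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class CLU:
    """A core learning unit: spec + (lazily materialised) network weights.

    The network is built on first sight of data, because the input width is
    a property of the dataset, not the spec; initialisation is nevertheless
    fully determined by ``spec.seed`` for a given input shape.
    """

    def __init__(self, spec: CLUSpec) -> None:
        self.spec = spec
        self.network: Network | None = None
        self.input_shape: tuple[int, ...] | None = None
        self.is_fitted = False

    # -- construction -----------------------------------------------------
    def initialize(self, input_shape: Sequence[int]) -> "CLU":
        """Build the network for inputs of shape (per-sample) ``input_shape``."""
        spec = self.spec
        rng = derive_rng(spec.seed, 0)
        loss = "bce_with_logits" if spec.loss == "binary_cross_entropy" else "mse"
        layers: list = []
        if spec.kind == "mlp":
            if len(input_shape) != 1:
                raise ConfigurationError(f"mlp expects flat inputs, got shape {tuple(input_shape)}")
            widths = [input_shape[0], *spec.layer_sizes]
            for i in range(len(widths) - 1):
                layers.append(Dense(widths[i], widths[i + 1], rng))
                if i < len(widths) - 2:
                    layers.append(Activation(spec.activation))
        elif spec.kind == "cnn":
            if len(input_shape) != 3:
                raise ConfigurationError(f"cnn expects (H,W,C) inputs, got shape {tuple(input_shape)}")
            h, w, c = input_shape
            for f in spec.conv_filters:
                if h % 2 or w % 2:
                    raise ConfigurationError(
                        f"image dims must halve cleanly through {len(spec.conv_filters)} pooling stages"
                    )
                layers.append(Conv2D(c, f, rng))
                layers.append(Activation(spec.activation))
                layers.append(MaxPool2D(2))
                h, w, c = h // 2, w // 2, f
            layers.append(Flatten())
            widths = [h * w * c, *spec.layer_sizes]
            for i in range(len(widths) - 1):
                layers.append(Dense(widths[i], widths[i + 1], rng))
                if i < len(widths) - 2:
                    layers.append(Activation(spec.activation))
        else:  # rnn
            if len(input_shape) == 1:
                input_shape = (input_shape[0], 1)
            t, d = input_shape
            cell = GRU if spec.rnn_cell == "gru" else LSTM
            layers.append(cell(d, spec.rnn_units, rng))
            if spec.attention:
                layers.append(AdditiveAttention(spec.rnn_units, rng))
            else:
                layers.append(_LastStep())
            widths = [spec.rnn_units, *spec.layer_sizes]
            for i in range(len(widths) - 1):
                layers.append(Dense(widths[i], widths[i + 1], rng))
                if i < len(widths) - 2:
                    layers.append(Activation(spec.activation))
        self.network = Network(layers, loss=loss, optimizer=spec.optimizer, lr=spec.initial_lr)
        self.input_shape = tuple(input_shape)
        return self

    def _coerce(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.spec.kind == "rnn" and X.ndim == 2:
            X = X[:, :, None]
        if self.input_shape is not None and X.shape[1:] != self.input_shape:
            raise ValueError(f"input shape {X.shape[1:]} does not match expected {self.input_shape}")
        return X

    # -- inference --------------------------------------------------------
    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if not self.is_fitted:
            raise NotFittedError("CLU is not fitted; call train_clu first")
        return self.network.predict(self._coerce(X))

    # -- checkpoint I/O ---------------------------------------------------
    def save_weights(self, path) -> None:
        if self.network is None:
            raise NotFittedError("nothing to save: network not built")
        np.savez(path, *self.network.get_weights(), input_shape=np.array(self.input_shape))

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            shape = tuple(int(v) for v in data["input_shape"])
            if self.network is None:
                self.initialize(shape)
            weights = [data[k] for k in data.files if k != "input_shape"]
            self.network.set_weights(weights)
        self.is_fitted = True


class _LastStep:
    """Pooling fallback when attention is disabled: take the final hidden state."""

    params: list = []
    grads: list = []

    def forward(self, h):
        self._shape = h.shape
        return h[:, -1, :]

    def backward(self, grad):
        out = np.zeros(self._shape)
        out[:, -1, :] = grad
        return out

    def zero_grad(self) -> None:
        pass


def build_clu(spec: CLUSpec) -> CLU:
    """Construct an unfitted CLU from a validated spec."""
    if not isinstance(spec, CLUSpec):
        raise ConfigurationError("build_clu expects a CLUSpec")
    return CLU(spec)


def lr_schedule_update(current_lr: float, epoch_index: int, period: int = 50) -> float:
    """Step-decay schedule: λ <- λ - 0.1·λ at every completed ``period``.

    Returns ``current_lr`` unchanged unless ``epoch_index`` is a positive
    multiple of ``period``, in which case the rate drops to 90% of itself.
    After k decays the rate is λ0 · 0.9^k.
    """
    if current_lr <= 0:
        raise ValueError("current_lr must be positive")
    if period <= 0:
        raise ValueError("period must be positive")
    if epoch_index > 0 and epoch_index % period == 0:
        return current_lr - current_lr * 0.1
    return current_lr


def _check_dataset(name: str, data) -> tuple[np.ndarray, np.ndarray]:
    X, y = data
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    if len(X) == 0:
        raise ValueError(f"{name} set is empty")
    if len(X) != len(y):
        raise ValueError(f"{name} set has {len(X)} rows but {len(y)} labels")
    return X, y


def train_clu(clu: CLU, train, val) -> tuple[CLU, TrainingLog]:
    """Train a CLU with LR step decay and best-validation-loss checkpointing.

    ``train`` and ``val`` are ``(X, y)`` pairs with identical per-sample
    shapes.  The returned CLU carries the weights of the epoch whose
    validation loss was minimal (earliest epoch on ties), which is generally
    not the final epoch.
    """
    Xtr, ytr = _check_dataset("training", train)
    Xva, yva = _check_dataset("validation", val)
    if Xtr.shape[1:] != Xva.shape[1:]:
        raise ValueError("train and validation feature schemas differ")
    if clu.network is None:
        probe = clu.spec.kind == "rnn" and Xtr.ndim == 2
        clu.initialize(Xtr.shape[1:] + ((1,) if probe else ()))
    Xtr = clu._coerce(Xtr)
    Xva = clu._coerce(Xva)

    net = clu.network
    spec = clu.spec
    shuffle_rng = derive_rng(spec.seed, 1)
    log = TrainingLog()
    lr = spec.initial_lr
    best_loss = np.inf
    best_weights = net.get_weights()
    n = len(Xtr)
    for epoch in range(spec.epochs):
        lr = lr_schedule_update(lr, epoch, spec.lr_decay_period)
        net.optimizer.lr = lr
        order = shuffle_rng.permutation(n)
        batch_losses = []
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            batch_losses.append(net.train_batch(Xtr[idx], ytr[idx]))
        train_loss = float(np.mean(batch_losses))
        if not np.isfinite(train_loss):
            raise TrainingDivergedError(f"training loss became non-finite at epoch {epoch}")
        val_loss = net.evaluate(Xva, yva)
        log.append(epoch, train_loss, val_loss, lr)
        if val_loss < best_loss:
            best_loss = val_loss
            best_weights = net.get_weights()
            log.best_epoch = epoch
    net.set_weights(best_weights)
    clu.is_fitted = True
    return clu, log


def predict_proba(clu: CLU, inputs: np.ndarray) -> np.ndarray:
    """Module-level alias for :meth:`CLU.predict_proba`."""
    return clu.predict_proba(inputs)
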