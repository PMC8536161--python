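"""A sequential network tying layers, a loss and an optimizer together."""

from __future__ import annotations

import numpy as np

from .layers import Layer
from .losses import LOSSES
from .optim import OPTIMIZERS


class Network:
    """Sequential stack of layers trained by minibatch gradient descent.

    ``loss`` is one of ``bce_with_logits`` / ``mse``.  With the logit loss the
    raw forward output is a logit; :meth:`predict` maps it through a sigmoid,
    while with ``mse`` the forward output is the prediction itself.
    """

    def __init__(self, layers: list[Layer], loss: str, optimizer: str, lr: float) -> None:
        self.layers = layers
        self.loss_name = loss
        self._loss = LOSSES[loss]
        self.optimizer = OPTIMIZERS[optimizer](lr)

    # -- plumbing ---------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def _params_grads(self) -> tuple[list[np.ndarray], list[np.ndarray]]:
        params: list[np.ndarray] = []
        grads: list[np.ndarray] = []
        for layer in self.layers:
            params.extend(layer.params)
            grads.extend(layer.grads)
        return params, grads

    # -- training ---------------------------------------------------------
    def train_batch(self, x: np.ndarray, y: np.ndarray) -> float:
        out = self.forward(x)
        loss, dout = self._loss(out, y)
        dout = dout.reshape(out.shape)
        for layer in self.layers:
            layer.zero_grad()
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        params, grads = self._params_grads()
        self.optimizer.step(params, grads)
        return loss

    def evaluate(self, x: np.ndarray, y: np.ndarray) -> float:
        out = self.forward(x)
        loss, _ = self._loss(out, y)
        return loss

    def predict(self, x: np.ndarray) -> np.ndarray:
        out = self.forward(x).reshape(len(x), -1)
        out = out[:, 0] if out.shape[1] == 1 else out
        if self.loss_name == "bce_with_logits":
            return 0.5 * (1.0 + np.tanh(0.5 * out))
        return out

    # -- checkpointing ----------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        params, _ = self._params_grads()
        return [p.copy() for p in params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params, _ = self._params_grads()
        if len(params) != len(weights):
            raise ValueError("weight list does not match network parameters")
        for p, w in zip(params, weights):
            p[...] = w
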