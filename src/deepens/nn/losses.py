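"""Loss functions returning (scalar loss, gradient wrt network output)."""

from __future__ import annotations

import numpy as np


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Binary cross-entropy on raw logits (numerically stable form)."""
    z = z.reshape(-1)
    y = y.reshape(-1)
    loss = float(np.mean(np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    p = 0.5 * (1.0 + np.tanh(0.5 * z))
    grad = (p - y) / z.size
    return loss, grad


def mse(p: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    p = p.reshape(-1)
    y = y.reshape(-1)
    d = p - y
    return float(np.mean(d * d)), 2.0 * d / p.size


LOSSES = {"bce_with_logits": bce_with_logits, "mse": mse}
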