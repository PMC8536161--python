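"""Differentiable layers for the deterministic NumPy neural backend.

All layers operate on float64 batch-first arrays and implement an explicit
``forward``/``backward`` pair.  Parameter gradients are accumulated into
``layer.grads`` (parallel to ``layer.params``) during ``backward``.  Every
source of randomness is a caller-supplied :class:`numpy.random.Generator`,
which is what makes same-seed training runs bitwise reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Dense",
    "Activation",
    "Flatten",
    "Reshape",
    "Conv2D",
    "MaxPool2D",
    "UpSample2D",
    "GRU",
    "LSTM",
    "AdditiveAttention",
]


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base class: stateless unless it owns parameters."""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.W = glorot_uniform(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads[0] += self._x.T @ grad
        self.grads[1] += grad.sum(axis=0)
        return grad @ self.W.T


_ACTIVATIONS = {
    "relu": (lambda x: np.maximum(x, 0.0), lambda x, y: (x > 0).astype(float)),
    "tanh": (np.tanh, lambda x, y: 1.0 - y * y),
    "sigmoid": (
        lambda x: 0.5 * (1.0 + np.tanh(0.5 * x)),
        lambda x, y: y * (1.0 - y),
    ),
    "linear": (lambda x: x, lambda x, y: np.ones_like(x)),
}


class Activation(Layer):
    def __init__(self, name: str) -> None:
        super().__init__()
        if name not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {name!r}; choose from {sorted(_ACTIVATIONS)}")
        self.name = name
        self._fn, self._dfn = _ACTIVATIONS[name]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._y = self._fn(x)
        return self._y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._dfn(self._x, self._y)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]) -> None:
        super().__init__()
        self.shape = shape

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._in_shape)


class Conv2D(Layer):
    """3x3 (by default) same-padded convolution, stride 1, NHWC layout.

    The forward/backward pass loops over the kernel offsets (kh*kw matmuls)
    rather than materialising an im2col matrix; at the small spatial sizes
    this backend targets that is both simpler and cache-friendlier.
    """

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, kernel: int = 3) -> None:
        super().__init__()
        fan_in = kernel * kernel * n_in
        fan_out = kernel * kernel * n_out
        self.kernel = kernel
        self.K = glorot_uniform(rng, (kernel, kernel, n_in, n_out), fan_in, fan_out)
        self.b = np.zeros(n_out)
        self.params = [self.K, self.b]
        self.grads = [np.zeros_like(self.K), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel
        p = k // 2
        B, H, W, _ = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._xp = xp
        self._hw = (H, W)
        out = np.tile(self.b, (B, H, W, 1)).astype(float)
        for di in range(k):
            for dj in range(k):
                out += self._xp[:, di : di + H, dj : dj + W, :] @ self.K[di, dj]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k = self.kernel
        H, W = self._hw
        dxp = np.zeros_like(self._xp)
        for di in range(k):
            for dj in range(k):
                xs = self._xp[:, di : di + H, dj : dj + W, :]
                self.grads[0][di, dj] += np.tensordot(xs, grad, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, di : di + H, dj : dj + W, :] += grad @ self.K[di, dj].T
        self.grads[1] += grad.sum(axis=(0, 1, 2))
        p = k // 2
        if p:
            return dxp[:, p:-p, p:-p, :]
        return dxp


class MaxPool2D(Layer):
    """2x2 max pooling; spatial dims must be even (pad upstream if needed)."""

    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = self.size
        B, H, W, C = x.shape
        if H % s or W % s:
            raise ValueError(f"spatial dims ({H},{W}) not divisible by pool size {s}")
        win = x.reshape(B, H // s, s, W // s, s, C).transpose(0, 1, 3, 5, 2, 4).reshape(B, H // s, W // s, C, s * s)
        self._arg = np.argmax(win, axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(win, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        s = self.size
        B, H, W, C = self._in_shape
        dwin = np.zeros((B, H // s, W // s, C, s * s))
        np.put_along_axis(dwin, self._arg[..., None], grad[..., None], axis=-1)
        return dwin.reshape(B, H // s, W // s, C, s, s).transpose(0, 1, 4, 2, 5, 3).reshape(B, H, W, C)


class UpSample2D(Layer):
    """Nearest-neighbour upsampling by an integer factor."""

    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = self.size
        return x.repeat(s, axis=1).repeat(s, axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        s = self.size
        B, H, W, C = grad.shape
        return grad.reshape(B, H // s, s, W // s, s, C).sum(axis=(2, 4))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class GRU(Layer):
    """Single-layer gated recurrent unit returning all hidden states (B,T,H)."""

    def __init__(self, n_in: int, n_units: int, rng: np.random.Generator) -> None:
        super().__init__()
        H = n_units
        self.H = H
        self.W = glorot_uniform(rng, (n_in, 3 * H), n_in, H)
        self.U = glorot_uniform(rng, (H, 3 * H), H, H)
        self.b = np.zeros(3 * H)
        self.params = [self.W, self.U, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.U), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        H = self.H
        Wz, Wr, Wh = self.W[:, :H], self.W[:, H : 2 * H], self.W[:, 2 * H :]
        Uz, Ur, Uh = self.U[:, :H], self.U[:, H : 2 * H], self.U[:, 2 * H :]
        bz, br, bh = self.b[:H], self.b[H : 2 * H], self.b[2 * H :]
        h = np.zeros((B, H))
        self._x = x
        self._cache = []
        hs = np.empty((B, T, H))
        for t in range(T):
            xt = x[:, t, :]
            z = _sigmoid(xt @ Wz + h @ Uz + bz)
            r = _sigmoid(xt @ Wr + h @ Ur + br)
            c = np.tanh(xt @ Wh + (r * h) @ Uh + bh)
            h_new = (1.0 - z) * h + z * c
            self._cache.append((h, z, r, c))
            h = h_new
            hs[:, t, :] = h
        return hs

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        B, T, _ = x.shape
        H = self.H
        Wz, Wr, Wh = self.W[:, :H], self.W[:, H : 2 * H], self.W[:, 2 * H :]
        Uz, Ur, Uh = self.U[:, :H], self.U[:, H : 2 * H], self.U[:, 2 * H :]
        dW = self.grads[0]
        dU = self.grads[1]
        db = self.grads[2]
        dx = np.zeros_like(x)
        dh = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, z, r, c = self._cache[t]
            dht = grad[:, t, :] + dh
            dc = dht * z
            dz = dht * (c - h_prev)
            dh_prev = dht * (1.0 - z)
            da_c = dc * (1.0 - c * c)
            xt = x[:, t, :]
            rh = r * h_prev
            dW[:, 2 * H :] += xt.T @ da_c
            dU[:, 2 * H :] += rh.T @ da_c
            db[2 * H :] += da_c.sum(axis=0)
            drh = da_c @ Uh.T
            dr = drh * h_prev
            dh_prev += drh * r
            da_z = dz * z * (1.0 - z)
            da_r = dr * r * (1.0 - r)
            dW[:, :H] += xt.T @ da_z
            dW[:, H : 2 * H] += xt.T @ da_r
            dU[:, :H] += h_prev.T @ da_z
            dU[:, H : 2 * H] += h_prev.T @ da_r
            db[:H] += da_z.sum(axis=0)
            db[H : 2 * H] += da_r.sum(axis=0)
            dh_prev += da_z @ Uz.T + da_r @ Ur.T
            dx[:, t, :] = da_z @ Wz.T + da_r @ Wr.T + da_c @ Wh.T
            dh = dh_prev
        return dx


class LSTM(Layer):
    """Single-layer LSTM returning all hidden states (B,T,H); gate order i,f,o,g."""

    def __init__(self, n_in: int, n_units: int, rng: np.random.Generator) -> None:
        super().__init__()
        H = n_units
        self.H = H
        self.W = glorot_uniform(rng, (n_in, 4 * H), n_in, H)
        self.U = glorot_uniform(rng, (H, 4 * H), H, H)
        self.b = np.zeros(4 * H)
        self.b[H : 2 * H] = 1.0  # forget-gate bias init
        self.params = [self.W, self.U, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.U), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        H = self.H
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._x = x
        self._cache = []
        hs = np.empty((B, T, H))
        for t in range(T):
            a = x[:, t, :] @ self.W + h @ self.U + self.b
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            o = _sigmoid(a[:, 2 * H : 3 * H])
            g = np.tanh(a[:, 3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            self._cache.append((h, c, i, f, o, g, tanh_c))
            c = c_new
            h = o * tanh_c
            hs[:, t, :] = h
        return hs

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        B, T, _ = x.shape
        H = self.H
        dx = np.zeros_like(x)
        dh = np.zeros((B, H))
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, o, g, tanh_c = self._cache[t]
            dht = grad[:, t, :] + dh
            do = dht * tanh_c
            dct = dht * o * (1.0 - tanh_c * tanh_c) + dc
            di = dct * g
            df = dct * c_prev
            dg = dct * i
            dc = dct * f
            da = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    do * o * (1.0 - o),
                    dg * (1.0 - g * g),
                ],
                axis=1,
            )
            self.grads[0] += x[:, t, :].T @ da
            self.grads[1] += h_prev.T @ da
            self.grads[2] += da.sum(axis=0)
            dx[:, t, :] = da @ self.W.T
            dh = da @ self.U.T
        return dx


class AdditiveAttention(Layer):
    """Additive (Bahdanau-style) attention pooling of (B,T,H) -> (B,H)."""

    def __init__(self, n_units: int, rng: np.random.Generator) -> None:
        super().__init__()
        H = n_units
        self.Wa = glorot_uniform(rng, (H, H), H, H)
        self.ba = np.zeros(H)
        self.v = glorot_uniform(rng, (H,), H, 1)
        self.params = [self.Wa, self.ba, self.v]
        self.grads = [np.zeros_like(self.Wa), np.zeros_like(self.ba), np.zeros_like(self.v)]

    def forward(self, h: np.ndarray) -> np.ndarray:
        u = np.tanh(h @ self.Wa + self.ba)  # (B,T,H)
        e = u @ self.v  # (B,T)
        e = e - e.max(axis=1, keepdims=True)
        a = np.exp(e)
        a /= a.sum(axis=1, keepdims=True)
        self._h, self._u, self._a = h, u, a
        return np.einsum("bt,bth->bh", a, h)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        h, u, a = self._h, self._u, self._a
        da = np.einsum("bh,bth->bt", grad, h)
        dh = a[:, :, None] * grad[:, None, :]
        de = a * (da - (a * da).sum(axis=1, keepdims=True))
        du = de[:, :, None] * self.v
        dz = du * (1.0 - u * u)
        self.grads[0] += np.einsum("bth,bta->ha", h, dz)
        self.grads[1] += dz.sum(axis=(0, 1))
        self.grads[2] += np.einsum("bta,bt->a", u, de)
        dh += dz @ self.Wa.T
        return dh
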