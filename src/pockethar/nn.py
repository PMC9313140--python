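"""Minimal NumPy neural-network engine for 1D convolutional-recurrent nets.

Implements exactly the layer set the activity classifier needs — stride-1
"same" 1D convolution (odd kernels), ceil-mode "same" average pooling,
inverted dropout, a single-layer LSTM returning its last hidden state,
dense layers, and softmax cross-entropy — with explicit backward passes
and an Adam optimizer.  Everything runs in float32 and routes the heavy
lifting through BLAS matmuls (im2col), which keeps desk-scale training in
the minutes range on one CPU.

Weight initialisation is Glorot-uniform, deterministic under the
generator passed at construction; the LSTM forget-gate bias starts at 1.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1D", "ReLU", "AvgPool1D", "Dropout", "LSTM", "Dense",
    "NeuralNet", "Adam", "softmax",
]

_DT = np.float32


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(_DT)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, T, C) -> (B, T, k*C) patches with symmetric zero padding (odd k)."""
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # (B,T,C,k)
    b, t, c, _ = cols.shape
    return np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(b, t, k * c)


class Layer:
    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = {}, {}

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """Stride-1 cross-correlation with 'same' zero padding; odd kernel only."""

    def __init__(self, in_ch: int, filters: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("Conv1D supports odd kernels only")
        self.k, self.cin, self.cout = kernel, in_ch, filters
        self.params["W"] = _glorot(
            rng, (kernel * in_ch, filters), kernel * in_ch, kernel * filters
        )
        self.params["b"] = np.zeros(filters, dtype=_DT)

    def forward(self, x, training, rng=None):
        self._cols = _im2col(x.astype(_DT, copy=False), self.k)
        return self._cols @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        b, t, _ = dy.shape
        cols2 = self._cols.reshape(b * t, -1)
        dy2 = dy.reshape(b * t, -1)
        self.grads["W"] = cols2.T @ dy2
        self.grads["b"] = dy2.sum(axis=0)
        # dx is the 'same' correlation of dy with the flipped, transposed kernel
        W = self.params["W"].reshape(self.k, self.cin, self.cout)
        Wr = np.ascontiguousarray(W[::-1].transpose(0, 2, 1)).reshape(
            self.k * self.cout, self.cin
        )
        return _im2col(dy, self.k) @ Wr


class ReLU(Layer):
    def forward(self, x, training, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0)


class AvgPool1D(Layer):
    """Ceil-mode average pooling, stride = pool size; averages valid cells only.

    Output length is ceil(T/size) for any T >= 1, matching 'same'-padded
    pooling in the common deep-learning frameworks, so arbitrarily short
    windows remain representable.
    """

    def __init__(self, size: int = 3):
        super().__init__()
        self.size = size

    def forward(self, x, training, rng=None):
        b, t, c = x.shape
        s = self.size
        tout = -(-t // s)
        counts = np.minimum(s, t - np.arange(tout) * s).astype(_DT)
        xp = np.pad(x, ((0, 0), (0, tout * s - t), (0, 0)))
        self._t, self._counts = t, counts
        return xp.reshape(b, tout, s, c).sum(axis=2) / counts[None, :, None]

    def backward(self, dy):
        dy_scaled = dy / self._counts[None, :, None]
        dx = np.repeat(dy_scaled, self.size, axis=1)
        return dx[:, : self._t]


class Dropout(Layer):
    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, training, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(_DT) / _DT(keep)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


def _sigmoid(z):
    # clip to keep float32 exp finite; saturation beyond +-60 is exact anyway
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


class LSTM(Layer):
    """Single LSTM layer consuming the full sequence, returning the last h."""

    def __init__(self, in_ch: int, units: int, rng: np.random.Generator):
        super().__init__()
        self.h = units
        self.params["Wx"] = _glorot(rng, (in_ch, 4 * units), in_ch, 4 * units)
        self.params["Wh"] = _glorot(rng, (units, 4 * units), units, 4 * units)
        b = np.zeros(4 * units, dtype=_DT)
        b[units : 2 * units] = 1.0  # forget-gate bias
        self.params["b"] = b

    def forward(self, x, training, rng=None):
        b, t, _ = x.shape
        hdim = self.h
        h = np.zeros((b, hdim), dtype=_DT)
        c = np.zeros((b, hdim), dtype=_DT)
        self._x = x
        self._cache = []
        Wx, Wh, bias = self.params["Wx"], self.params["Wh"], self.params["b"]
        for step in range(t):
            z = x[:, step] @ Wx + h @ Wh + bias
            i = _sigmoid(z[:, :hdim])
            f = _sigmoid(z[:, hdim : 2 * hdim])
            g = np.tanh(z[:, 2 * hdim : 3 * hdim])
            o = _sigmoid(z[:, 3 * hdim :])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            tanh_c = np.tanh(c)
            h = o * tanh_c
            self._cache.append((i, f, g, o, c_prev, h_prev, tanh_c))
        return h

    def backward(self, dh):
        x = self._x
        b, t, cin = x.shape
        hdim = self.h
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(self.params["b"])
        dx = np.empty_like(x)
        dc = np.zeros((b, hdim), dtype=_DT)
        for step in range(t - 1, -1, -1):
            i, f, g, o, c_prev, h_prev, tanh_c = self._cache[step]
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c * tanh_c)
            di, dg, df = dc * g, dc * i, dc * c_prev
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dWx += x[:, step].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, step] = dz @ Wx.T
            dh = dz @ Wh.T
            dc = dc * f
        self.grads["Wx"], self.grads["Wh"], self.grads["b"] = dWx, dWh, db
        return dx


class Dense(Layer):
    def __init__(self, in_ch: int, units: int, rng: np.random.Generator, relu: bool = True):
        super().__init__()
        self.relu = relu
        self.params["W"] = _glorot(rng, (in_ch, units), in_ch, units)
        self.params["b"] = np.zeros(units, dtype=_DT)

    def forward(self, x, training, rng=None):
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        if self.relu:
            self._mask = z > 0
            z = np.where(self._mask, z, 0)
        return z

    def backward(self, dy):
        if self.relu:
            dy = np.where(self._mask, dy, 0)
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class NeuralNet:
    """A plain layer stack ending in class logits (softmax applied on top)."""

    def __init__(self, layers: list[Layer], n_classes: int):
        self.layers = layers
        self.n_classes = n_classes

    @property
    def n_params(self) -> int:
        return sum(p.size for lay in self.layers for p in lay.params.values())

    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        out = x.astype(_DT, copy=False)
        for lay in self.layers:
            out = lay.forward(out, training, rng)
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        probs = np.empty((len(x), self.n_classes), dtype=_DT)
        for lo in range(0, len(x), batch_size):
            sl = slice(lo, lo + batch_size)
            probs[sl] = softmax(self.forward(x[sl], training=False))
        return probs

    def train_batch(self, x: np.ndarray, y_idx: np.ndarray, rng) -> float:
        """Forward + backward on one minibatch; returns the mean cross-entropy."""
        logits = self.forward(x, training=True, rng=rng)
        probs = softmax(logits)
        b = len(x)
        eps = np.finfo(_DT).tiny
        loss = float(-np.mean(np.log(probs[np.arange(b), y_idx] + eps)))
        dlogits = probs
        dlogits[np.arange(b), y_idx] -= 1.0
        dlogits /= _DT(b)
        grad = dlogits
        for lay in reversed(self.layers):
            grad = lay.backward(grad)
        return loss

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for lay in self.layers for p in lay.params.values()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for lay in self.layers:
            for name in lay.params:
                lay.params[name][...] = next(it)


class Adam:
    """Adaptive-moment optimizer, the standard defaults."""

    def __init__(self, lr: float = 0.001, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self, net: NeuralNet) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for lay in net.layers:
            for name, p in lay.params.items():
                g = lay.grads.get(name)
                if g is None:
                    continue
                key = id(p)
                m = self._m.setdefault(key, np.zeros_like(p))
                v = self._v.setdefault(key, np.zeros_like(p))
                m += (1.0 - self.b1) * (g - m)
                v += (1.0 - self.b2) * (g * g - v)
                p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)
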