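"""A compact numpy neural-network engine.

Implements exactly the primitives the pipeline's models need — stride-1
same-padding convolutions, 2x2 max pooling, global pooling, dense layers,
(weighted) softmax cross-entropy, an adaptive-moment optimiser, and an LSTM
layer with full backpropagation through time. Everything is float32,
single-threaded-deterministic, and seeded explicitly.

Layout conventions: images are NHWC; conv kernels are (kh, kw, Cin, Cout);
sequences are (T, features) with batch size one.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


def _conv_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Stride-1 'same' cross-correlation, odd kernels only."""
    kh, kw = w.shape[:2]
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # N,H,W,C,kh,kw
    return np.tensordot(win, w, axes=([4, 5, 3], [0, 1, 2]))


class Conv2d:
    """3x3 (or any odd) kernel, stride 1, zero 'same' padding, with bias."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, kernel: int = 3):
        fan_in = kernel * kernel * c_in
        self.W = Param(he_init(rng, (kernel, kernel, c_in, c_out), fan_in))
        self.b = Param(np.zeros(c_out, dtype=np.float32))
        self._x = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return _conv_same(x, self.W.value) + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        kh, kw = self.W.value.shape[:2]
        ph, pw = kh // 2, kw // 2
        xp = np.pad(self._x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        win = sliding_window_view(xp, (kh, kw), axis=(1, 2))
        dw = np.tensordot(win, dy, axes=([0, 1, 2], [0, 1, 2]))  # C,kh,kw,Cout
        self.W.grad += dw.transpose(1, 2, 0, 3)
        self.b.grad += dy.sum(axis=(0, 1, 2))
        w_flip = self.W.value[::-1, ::-1].transpose(0, 1, 3, 2)
        return _conv_same(dy, w_flip)

    @property
    def params(self):
        return [self.W, self.b]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
            return np.where(self._mask, x, 0.0)
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)

    params: list = []


class MaxPool2x2:
    """2x2/stride-2 max pooling; spatial dims must be even."""

    def __init__(self):
        self._idx = None
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        r = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        flat = r.reshape(n, h // 2, w // 2, c, 4)
        if train:
            self._idx = flat.argmax(axis=-1)
            self._shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h2, w2, c = dy.shape
        flat = np.zeros((n, h2, w2, c, 4), dtype=dy.dtype)
        np.put_along_axis(flat, self._idx[..., None], dy[..., None], axis=-1)
        r = flat.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return r.reshape(self._shape)

    params: list = []


class GlobalMaxPool:
    """Max over the spatial grid -> per-channel feature vector."""

    def __init__(self):
        self._idx = None
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        flat = x.reshape(n, h * w, c)
        if train:
            self._idx = flat.argmax(axis=1)
            self._shape = x.shape
        return flat.max(axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        flat = np.zeros((n, h * w, c), dtype=dy.dtype)
        np.put_along_axis(flat, self._idx[:, None, :], dy[:, None, :], axis=1)
        return flat.reshape(self._shape)

    params: list = []


class Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Param(he_init(rng, (d_in, d_out), d_in))
        self.b = Param(np.zeros(d_out, dtype=np.float32))
        self._x = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T

    @property
    def params(self):
        return [self.W, self.b]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent(
    logits: np.ndarray, targets: np.ndarray, sample_weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Mean (optionally weighted) cross-entropy and its logit gradient.

    ``targets`` are integer class indices; weights multiply per-sample
    losses and gradients, normalised by batch size (so all-ones weights
    reproduce the unweighted loss bit-for-bit).
    """
    n = logits.shape[0]
    p = softmax(logits)
    nll = -np.log(np.maximum(p[np.arange(n), targets], 1e-30))
    if sample_weights is None:
        sample_weights = np.ones(n, dtype=np.float32)
    loss = float(np.mean(sample_weights * nll))
    dlogits = p.copy()
    dlogits[np.arange(n), targets] -= 1.0
    dlogits *= (sample_weights / n)[:, None]
    return loss, dlogits.astype(np.float32)


class AdaMoment:
    """Adaptive-moment optimiser.

    First-moment coefficient ``momentum``, second-moment coefficient
    ``decay``, and additive ``epsilon`` inside the denominator, as three
    independent scalars; ``mode`` selects between the Adam-style update
    (bias-corrected first and second moments) and the RMSProp-style update
    (second moment only, gradient in the numerator).
    """

    def __init__(
        self,
        params,
        lr: float = 0.001,
        momentum: float = 0.9,
        decay: float = 0.9,
        epsilon: float = 1.0,
        mode: str = "adam",
    ):
        if mode not in ("adam", "rmsprop"):
            raise ValueError(f"unknown optimiser mode {mode!r}")
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.decay = decay
        self.epsilon = epsilon
        self.mode = mode
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.momentum, self.decay
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            v[...] = b2 * v + (1.0 - b2) * g * g
            if self.mode == "adam":
                m[...] = b1 * m + (1.0 - b1) * g
                m_hat = m / (1.0 - b1**self._t)
                v_hat = v / (1.0 - b2**self._t)
                p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.epsilon)
            else:
                p.value -= self.lr * g / (np.sqrt(v) + self.epsilon)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class SGD:
    """Plain stochastic gradient descent with 1/(1 + decay*t) lr decay."""

    def __init__(self, params, lr: float = 0.001, decay: float = 0.0, clip_norm: float | None = None):
        self.params = list(params)
        self.lr0 = lr
        self.decay = decay
        self.clip_norm = clip_norm
        self._t = 0

    @property
    def lr(self) -> float:
        return self.lr0 / (1.0 + self.decay * self._t)

    def step(self) -> None:
        if self.clip_norm is not None:
            total = np.sqrt(sum(float(np.sum(p.grad**2)) for p in self.params))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                for p in self.params:
                    p.grad *= scale
        lr = self.lr
        for p in self.params:
            p.value -= lr * p.grad
        self._t += 1

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class LSTMLayer:
    """Single LSTM layer over a (T, d_in) sequence, batch size one.

    Gate order along the 4h axis: input, forget, cell, output. The forget
    gate bias starts at 1 (standard remedy against early vanishing
    gradients); recurrent weights start orthogonal.
    """

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.d_in, self.d_hidden = d_in, d_hidden
        self.Wx = Param(he_init(rng, (d_in, 4 * d_hidden), d_in))
        q, _ = np.linalg.qr(rng.standard_normal((d_hidden, d_hidden)))
        self.Wh = Param(np.tile(q.astype(np.float32), (1, 4)) * 0.5)
        b = np.zeros(4 * d_hidden, dtype=np.float32)
        b[d_hidden : 2 * d_hidden] = 1.0
        self.b = Param(b)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        T = x.shape[0]
        H = self.d_hidden
        hs = np.zeros((T + 1, H), dtype=x.dtype)
        cs = np.zeros((T + 1, H), dtype=x.dtype)
        gates = np.zeros((T, 4 * H), dtype=x.dtype)
        for t in range(T):
            z = x[t] @ self.Wx.value + hs[t] @ self.Wh.value + self.b.value
            i = _sigmoid(z[:H])
            f = _sigmoid(z[H : 2 * H])
            g = np.tanh(z[2 * H : 3 * H])
            o = _sigmoid(z[3 * H :])
            cs[t + 1] = f * cs[t] + i * g
            hs[t + 1] = o * np.tanh(cs[t + 1])
            gates[t] = np.concatenate([i, f, g, o])
        if train:
            self._cache = (x, hs, cs, gates)
        return hs[1:]

    def backward(self, dh_out: np.ndarray) -> np.ndarray:
        x, hs, cs, gates = self._cache
        T = x.shape[0]
        H = self.d_hidden
        dx = np.zeros_like(x)
        dh_next = np.zeros(H, dtype=x.dtype)
        dc_next = np.zeros(H, dtype=x.dtype)
        for t in range(T - 1, -1, -1):
            i, f, g, o = (
                gates[t, :H],
                gates[t, H : 2 * H],
                gates[t, 2 * H : 3 * H],
                gates[t, 3 * H :],
            )
            tanh_c = np.tanh(cs[t + 1])
            dh = dh_out[t] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c**2) + dc_next
            di = dc * g
            df = dc * cs[t]
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ]
            )
            self.Wx.grad += np.outer(x[t], dz)
            self.Wh.grad += np.outer(hs[t], dz)
            self.b.grad += dz
            dx[t] = dz @ self.Wx.value.T
            dh_next = dz @ self.Wh.value.T
            dc_next = dc * f
        return dx

    @property
    def params(self):
        return [self.Wx, self.Wh, self.b]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out
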