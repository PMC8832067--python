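"""Minimal feed-forward / convolutional / recurrent network engine.

Pure-numpy layers with analytic backpropagation, a binary-cross-entropy
(with-logits) loss, and an Adam optimizer — enough to express the seven
classifier families used for crash prediction (linear, MLP, 1-D CNN,
LSTM, GRU and their stacked variants) with bit-reproducible, seeded
training on a CPU.  Every layer's gradients are validated against
finite differences in the test suite.

Shapes: sequence inputs are (N, L, C); dense inputs (N, D); the model
head emits logits (N,), with the sigmoid applied inside the loss and in
``predict_proba`` for numerical stability.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np


def sigmoid(x):
    x = np.asarray(x)
    z = np.exp(-np.abs(x))  # stable: exponent always <= 0
    return np.where(x >= 0, 1.0 / (1.0 + z), z / (1.0 + z))


class Param:
    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = np.asarray(value, dtype=float)
        self.g = np.zeros_like(self.v)


def glorot(rng: np.random.Generator, shape: Tuple[int, ...],
           fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    params: List[Param] = []

    def forward(self, x, train: bool = False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Flatten(Layer):
    params: List[Param] = []

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class ReLU(Layer):
    params: List[Param] = []

    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    params: List[Param] = []

    def __init__(self, rate: float, rng: Optional[np.random.Generator] = None):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = ((self.rng.random(x.shape) < keep) / keep).astype(x.dtype)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Param(glorot(rng, (n_in, n_out), n_in, n_out))
        self.b = Param(np.zeros(n_out))
        self.params = [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.v + self.b.v

    def backward(self, dout):
        self.W.g += self._x.T @ dout
        self.b.g += dout.sum(axis=0)
        return dout @ self.W.v.T


class Conv1D(Layer):
    """1-D convolution with 'same' zero padding and stride 1."""

    def __init__(self, n_in: int, filters: int, ksize: int,
                 rng: np.random.Generator):
        fan_in, fan_out = ksize * n_in, filters
        self.W = Param(glorot(rng, (ksize, n_in, filters), fan_in, fan_out))
        self.b = Param(np.zeros(filters))
        self.params = [self.W, self.b]
        self.ksize = ksize
        self.pad_left = (ksize - 1) // 2
        self.pad_right = ksize - 1 - self.pad_left

    def forward(self, x, train=False):
        N, L, C = x.shape
        xp = np.pad(x, ((0, 0), (self.pad_left, self.pad_right), (0, 0)))
        self._xp, self._L = xp, L
        out = np.broadcast_to(self.b.v, (N, L, self.W.v.shape[2])).copy()
        for i in range(self.ksize):
            out += xp[:, i:i + L, :] @ self.W.v[i]
        return out

    def backward(self, dout):
        L = self._L
        dxp = np.zeros_like(self._xp)
        for i in range(self.ksize):
            sl = self._xp[:, i:i + L, :]
            self.W.g[i] += np.tensordot(sl, dout, axes=([0, 1], [0, 1]))
            dxp[:, i:i + L, :] += dout @ self.W.v[i].T
        self.b.g += dout.sum(axis=(0, 1))
        return dxp[:, self.pad_left:self.pad_left + L, :]


class MaxPool1D(Layer):
    """Non-overlapping max pooling along the time axis (trailing remainder dropped)."""

    params: List[Param] = []

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, train=False):
        N, L, C = x.shape
        Lp = L // self.size
        xr = x[:, :Lp * self.size, :].reshape(N, Lp, self.size, C)
        self._arg = xr.argmax(axis=2)
        self._in_shape = x.shape
        return xr.max(axis=2)

    def backward(self, dout):
        N, Lp, C = dout.shape
        dx = np.zeros(self._in_shape)
        dxr = dx[:, :Lp * self.size, :].reshape(N, Lp, self.size, C)
        n_idx, l_idx, c_idx = np.ogrid[:N, :Lp, :C]
        dxr[n_idx, l_idx, self._arg, c_idx] = dout
        return dx


class GRU(Layer):
    """Gated recurrent unit; h' = (1-z)*c + z*h with reset-gated candidate."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator,
                 return_sequences: bool = False):
        D, H = n_in, hidden
        self.W = Param(glorot(rng, (D, 3 * H), D, H))   # columns: z, r, c
        self.U = Param(glorot(rng, (H, 3 * H), H, H))
        self.b = Param(np.zeros(3 * H))
        self.params = [self.W, self.U, self.b]
        self.hidden = H
        self.return_sequences = return_sequences

    def forward(self, x, train=False):
        N, L, D = x.shape
        H = self.hidden
        h = np.zeros((N, H), dtype=x.dtype)
        self._x = x
        self._cache = []
        # input projections for all timesteps in one matmul
        A = x.reshape(N * L, D) @ self.W.v + self.b.v
        A = A.reshape(N, L, 3 * H)
        seq = np.empty((N, L, H), dtype=x.dtype) if self.return_sequences else None
        Uzr = self.U.v[:, :2 * H]
        Uc = self.U.v[:, 2 * H:]
        for t in range(L):
            a = A[:, t, :]
            hU = h @ Uzr
            z = sigmoid(a[:, :H] + hU[:, :H])
            r = sigmoid(a[:, H:2 * H] + hU[:, H:])
            rh = r * h
            c = np.tanh(a[:, 2 * H:] + rh @ Uc)
            h_new = (1.0 - z) * c + z * h
            self._cache.append((h, z, r, c, rh))
            h = h_new
            if seq is not None:
                seq[:, t, :] = h
        self._h_last = h
        return seq if self.return_sequences else h

    def backward(self, dout):
        x = self._x
        N, L, D = x.shape
        H = self.hidden
        Uzr = self.U.v[:, :2 * H]
        Uc = self.U.v[:, 2 * H:]
        dA = np.empty((N, L, 3 * H), dtype=x.dtype)
        dh = np.zeros((N, H), dtype=x.dtype)
        dUg = np.zeros_like(self.U.g)
        for t in range(L - 1, -1, -1):
            if self.return_sequences:
                dh = dh + dout[:, t, :]
            elif t == L - 1:
                dh = dh + dout
            h_prev, z, r, c, rh = self._cache[t]
            dz = dh * (h_prev - c)
            dc = dh * (1.0 - z)
            dh_prev = dh * z

            dac = dc * (1.0 - c * c)
            drh = dac @ Uc.T
            dr = drh * h_prev
            dh_prev += drh * r
            dar = dr * r * (1.0 - r)
            daz = dz * z * (1.0 - z)
            dazr = np.concatenate([daz, dar], axis=1)
            dh_prev += dazr @ Uzr.T

            dA[:, t, :2 * H] = dazr
            dA[:, t, 2 * H:] = dac
            dUg[:, :2 * H] += h_prev.T @ dazr
            dUg[:, 2 * H:] += rh.T @ dac
            dh = dh_prev
        dA2 = dA.reshape(N * L, 3 * H)
        self.W.g += x.reshape(N * L, D).T @ dA2
        self.b.g += dA2.sum(axis=0)
        self.U.g += dUg
        return (dA2 @ self.W.v.T).reshape(N, L, D)


class LSTM(Layer):
    """Long short-term memory layer with forget-gate bias init of 1."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator,
                 return_sequences: bool = False):
        D, H = n_in, hidden
        self.W = Param(glorot(rng, (D, 4 * H), D, H))   # columns: i, f, g, o
        self.U = Param(glorot(rng, (H, 4 * H), H, H))
        b = np.zeros(4 * H)
        b[H:2 * H] = 1.0
        self.b = Param(b)
        self.params = [self.W, self.U, self.b]
        self.hidden = H
        self.return_sequences = return_sequences

    def forward(self, x, train=False):
        N, L, D = x.shape
        H = self.hidden
        h = np.zeros((N, H), dtype=x.dtype)
        cs = np.zeros((N, H), dtype=x.dtype)
        self._x = x
        self._cache = []
        A = (x.reshape(N * L, D) @ self.W.v + self.b.v).reshape(N, L, 4 * H)
        seq = np.empty((N, L, H), dtype=x.dtype) if self.return_sequences else None
        for t in range(L):
            a = A[:, t, :] + h @ self.U.v
            i = sigmoid(a[:, :H])
            f = sigmoid(a[:, H:2 * H])
            g = np.tanh(a[:, 2 * H:3 * H])
            o = sigmoid(a[:, 3 * H:])
            c_new = f * cs + i * g
            tc = np.tanh(c_new)
            self._cache.append((h, cs, i, f, g, o, tc))
            h = o * tc
            cs = c_new
            if seq is not None:
                seq[:, t, :] = h
        return seq if self.return_sequences else h

    def backward(self, dout):
        x = self._x
        N, L, D = x.shape
        H = self.hidden
        dA = np.empty((N, L, 4 * H), dtype=x.dtype)
        dh = np.zeros((N, H), dtype=x.dtype)
        dc = np.zeros((N, H), dtype=x.dtype)
        dUg = np.zeros_like(self.U.g)
        for t in range(L - 1, -1, -1):
            if self.return_sequences:
                dh = dh + dout[:, t, :]
            elif t == L - 1:
                dh = dh + dout
            h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_prev = dc * f

            dai = di * i * (1.0 - i)
            daf = df * f * (1.0 - f)
            dag = dg * (1.0 - g * g)
            dao = do * o * (1.0 - o)
            da = np.concatenate([dai, daf, dag, dao], axis=1)

            dA[:, t, :] = da
            dUg += h_prev.T @ da
            dh = da @ self.U.v.T
            dc = dc_prev
        dA2 = dA.reshape(N * L, 4 * H)
        self.W.g += x.reshape(N * L, D).T @ dA2
        self.b.g += dA2.sum(axis=0)
        self.U.g += dUg
        return (dA2 @ self.W.v.T).reshape(N, L, D)


class Sequential:
    """Layer pipeline ending in a 1-unit logit head.

    ``forward`` returns logits of shape (N,); ``predict_proba`` applies
    the sigmoid.  Training state (dropout rng) is owned by the layers.
    """

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x, train: bool = False) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out, train=train)
        return out.reshape(out.shape[0])

    def backward(self, dlogit: np.ndarray) -> None:
        grad = dlogit.reshape(-1, 1)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_proba(self, x, batch_size: int = 4096) -> np.ndarray:
        n = x.shape[0]
        if n == 0:
            return np.empty(0)
        ps = self.params()
        if ps and x.dtype != ps[0].v.dtype:
            x = x.astype(ps[0].v.dtype)
        outs = [sigmoid(self.forward(x[i:i + batch_size], train=False))
                for i in range(0, n, batch_size)]
        return np.concatenate(outs)

    def params(self) -> List[Param]:
        return [p for layer in self.layers for p in layer.params]

    def astype(self, dtype) -> "Sequential":
        """Cast all parameters (and their grad buffers) to ``dtype``."""
        for p in self.params():
            p.v = p.v.astype(dtype)
            p.g = p.g.astype(dtype)
        return self

    def zero_grad(self) -> None:
        for p in self.params():
            p.g[...] = 0.0

    def n_parameters(self) -> int:
        return int(sum(p.v.size for p in self.params()))


def bce_with_logits(logits: np.ndarray, y: np.ndarray):
    """Mean binary cross-entropy on logits; returns (loss, dlogits)."""
    n = len(y)
    # softplus(z) - y*z, computed stably
    loss = float(np.mean(np.maximum(logits, 0) - logits * y
                         + np.log1p(np.exp(-np.abs(logits)))))
    dlogit = (sigmoid(logits) - y) / n
    return loss, dlogit


class Adam:
    def __init__(self, params: Iterable[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.v) for p in self.params]
        self.v = [np.zeros_like(p.v) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.g - m)
            v += (1.0 - self.b2) * (p.g * p.g - v)
            p.v -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
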