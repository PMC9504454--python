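"""Layers with explicit forward/backward passes.

Shapes are batch-first: sequence layers take (B, T, C), dense layers
(B, C).  Every layer exposes ``params`` and ``grads`` (parallel lists of
arrays); ``forward`` caches what ``backward`` needs.  LSTM gate order is
input, forget, cell, output; the forget-gate bias is initialized to 1.
"""

from __future__ import annotations

import numpy as np


def _glorot(rng, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params = []
        self.grads = []

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Conv1D(Layer):
    """1-D convolution over the time axis, valid padding, no stride."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.kernel = kernel
        self.W = _glorot(rng, (kernel, c_in, c_out), kernel * c_in, c_out)
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        self._x = x
        K = self.kernel
        To = x.shape[1] - K + 1
        if To < 1:
            raise ValueError("input shorter than the convolution kernel")
        y = np.broadcast_to(self.b, (x.shape[0], To, self.b.size)).copy()
        for j in range(K):
            y += x[:, j : j + To, :] @ self.W[j]
        return y

    def backward(self, dy):
        x = self._x
        K = self.kernel
        To = dy.shape[1]
        dW, db = self.grads
        db[...] = dy.sum(axis=(0, 1))
        dx = np.zeros_like(x)
        for j in range(K):
            xj = x[:, j : j + To, :]
            dW[j][...] = np.einsum("btc,bto->co", xj, dy)
            dx[:, j : j + To, :] += dy @ self.W[j].T
        return dx


class LSTM(Layer):
    """Unidirectional LSTM; returns the full hidden sequence (B, T, H)."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator,
                 reverse: bool = False):
        super().__init__()
        H = hidden
        self.H = H
        self.reverse = reverse
        self.Wx = _glorot(rng, (d_in, 4 * H), d_in, 4 * H)
        self.Wh = _glorot(rng, (H, 4 * H), H, 4 * H)
        self.b = np.zeros(4 * H)
        self.b[H : 2 * H] = 1.0  # forget-gate bias
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x):
        if self.reverse:
            x = x[:, ::-1, :]
        B, T, _ = x.shape
        H = self.H
        h = np.zeros((T + 1, B, H))
        c = np.zeros((B, H))
        gates = np.empty((T, B, 4 * H))
        c_prev = np.empty((T, B, H))
        tanh_c = np.empty((T, B, H))
        xp = x @ self.Wx  # precompute the input projection for all t
        for t in range(T):
            a = xp[:, t, :] + h[t] @ self.Wh + self.b
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            c_prev[t] = c
            c = f * c + i * g
            tc = np.tanh(c)
            tanh_c[t] = tc
            h[t + 1] = o * tc
            gates[t, :, :H] = i
            gates[t, :, H : 2 * H] = f
            gates[t, :, 2 * H : 3 * H] = g
            gates[t, :, 3 * H :] = o
        self._cache = (x, h, gates, c_prev, tanh_c)
        out = np.swapaxes(h[1:], 0, 1)
        if self.reverse:
            out = out[:, ::-1, :]
        return out

    def backward(self, dy):
        if self.reverse:
            dy = dy[:, ::-1, :]
        x, h, gates, c_prev, tanh_c = self._cache
        B, T, _ = x.shape
        H = self.H
        dWx, dWh, db = self.grads
        dWx[...] = 0.0
        dWh[...] = 0.0
        db[...] = 0.0
        dx = np.empty_like(x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        da = np.empty((B, 4 * H))
        for t in range(T - 1, -1, -1):
            i = gates[t, :, :H]
            f = gates[t, :, H : 2 * H]
            g = gates[t, :, 2 * H : 3 * H]
            o = gates[t, :, 3 * H :]
            tc = tanh_c[t]
            dh = dy[:, t, :] + dh_next
            dc = dh * o * (1.0 - tc * tc) + dc_next
            da[:, :H] = dc * g * i * (1.0 - i)
            da[:, H : 2 * H] = dc * c_prev[t] * f * (1.0 - f)
            da[:, 2 * H : 3 * H] = dc * i * (1.0 - g * g)
            da[:, 3 * H :] = dh * tc * o * (1.0 - o)
            dWx += x[:, t, :].T @ da
            dWh += h[t].T @ da
            db += da.sum(axis=0)
            dx[:, t, :] = da @ self.Wx.T
            dh_next = da @ self.Wh.T
            dc_next = dc * f
        if self.reverse:
            dx = dx[:, ::-1, :]
        return dx


class BiLSTM(Layer):
    """Bidirectional LSTM; concatenates forward and backward hidden states.

    ``return_sequences=True`` yields (B, T, 2H); otherwise the final state
    of each direction is concatenated into (B, 2H).
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator,
                 return_sequences: bool = True):
        super().__init__()
        self.fwd = LSTM(d_in, hidden, rng, reverse=False)
        self.bwd = LSTM(d_in, hidden, rng, reverse=True)
        self.return_sequences = return_sequences
        self.H = hidden
        self.params = self.fwd.params + self.bwd.params
        self.grads = self.fwd.grads + self.bwd.grads

    def forward(self, x):
        self._T = x.shape[1]
        yf = self.fwd.forward(x)
        yb = self.bwd.forward(x)
        if self.return_sequences:
            return np.concatenate([yf, yb], axis=2)
        # final state of the forward run; final state of the reversed run
        # is its output at original time 0
        return np.concatenate([yf[:, -1, :], yb[:, 0, :]], axis=1)

    def backward(self, dy):
        H = self.H
        if self.return_sequences:
            dx = self.fwd.backward(dy[:, :, :H])
            dx += self.bwd.backward(dy[:, :, H:])
            return dx
        B = dy.shape[0]
        dyf = np.zeros((B, self._T, H))
        dyb = np.zeros((B, self._T, H))
        dyf[:, -1, :] = dy[:, :H]
        dyb[:, 0, :] = dy[:, H:]
        return self.fwd.backward(dyf) + self.bwd.backward(dyb)


class Sequential:
    """A feed-forward stack of layers with a shared parameter view."""

    def __init__(self, layers):
        self.layers = list(layers)

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    @property
    def n_parameters(self) -> int:
        return int(sum(layer.n_parameters for layer in self.layers))

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def softmax(logits):
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent(logits, targets):
    """(mean cross-entropy, probabilities, dlogits) for integer targets.

    The returned gradient is with respect to the *mean* loss, so batch
    size is already divided out.
    """
    p = softmax(logits)
    B = logits.shape[0]
    idx = (np.arange(B), targets)
    loss = float(-np.log(np.maximum(p[idx], 1e-300)).mean())
    dlogits = p.copy()
    dlogits[idx] -= 1.0
    dlogits /= B
    return loss, p, dlogits


class Adam:
    """Adam optimizer over a list of parameter arrays (updated in place)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)
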