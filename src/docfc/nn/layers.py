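"""Neural-network layers with explicit forward/backward passes.

Minimal but complete layer set for the classifier architectures used here:
dense, dropout, batch normalization, simple RNN, LSTM, GRU, 1-D convolution
and max-pooling. Shapes follow the (batch, features) / (batch, time,
features) convention; every layer exposes ``params``/``grads`` lists that the
optimizer updates in place. Backward passes are verified against
finite-difference gradients in the test suite.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def glorot_uniform(rng: np.random.Generator, n_in: int, n_out: int,
                   shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=shape or (n_in, n_out))


def orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


class Layer:
    """Base class; stateless layers only override forward/backward."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def l2_penalty(self) -> float:
        return 0.0


class Dense(Layer):
    """Fully connected layer, optionally with an L2 kernel penalty."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 l2: float = 0.0) -> None:
        super().__init__()
        self.W = glorot_uniform(rng, n_in, n_out)
        self.b = np.zeros(n_out)
        self.l2 = l2
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, gout):
        self.grads[0][...] = self._x.T @ gout
        if self.l2:
            self.grads[0] += 2.0 * self.l2 * self.W
        self.grads[1][...] = gout.sum(axis=0)
        return gout @ self.W.T

    def l2_penalty(self):
        return float(self.l2 * np.sum(self.W ** 2)) if self.l2 else 0.0


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout):
        return gout * self._mask


class Tanh(Layer):
    def forward(self, x, training):
        self._y = np.tanh(x)
        return self._y

    def backward(self, gout):
        return gout * (1.0 - self._y ** 2)


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, gout):
        return gout if self._mask is None else gout * self._mask


class BatchNorm(Layer):
    """Batch normalization over the batch (and time, if present) axes."""

    def __init__(self, n_features: int, momentum: float = 0.99,
                 eps: float = 1e-3) -> None:
        super().__init__()
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def forward(self, x, training):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean[...] = (self.momentum * self.running_mean
                                      + (1 - self.momentum) * mean)
            self.running_var[...] = (self.momentum * self.running_var
                                     + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        self._axes = axes
        self._m = np.prod([x.shape[a] for a in axes]) if training else None
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._training = training
        return self.gamma * self._xhat + self.beta

    def backward(self, gout):
        axes = self._axes
        self.grads[0][...] = (gout * self._xhat).sum(axis=axes)
        self.grads[1][...] = gout.sum(axis=axes)
        gxhat = gout * self.gamma
        if not self._training:
            return gxhat / self._std
        m = self._m
        return (gxhat - gxhat.mean(axis=axes)
                - self._xhat * (gxhat * self._xhat).mean(axis=axes)) / self._std


class SimpleRNN(Layer):
    """Elman RNN with tanh activation."""

    def __init__(self, n_in: int, units: int, rng: np.random.Generator,
                 return_sequences: bool = False) -> None:
        super().__init__()
        self.units = units
        self.return_sequences = return_sequences
        self.W = glorot_uniform(rng, n_in, units)
        self.U = orthogonal(rng, units)
        self.b = np.zeros(units)
        self.params = [self.W, self.U, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, training):
        N, T, _ = x.shape
        self._x = x
        self._h = np.zeros((N, T + 1, self.units))
        for t in range(T):
            self._h[:, t + 1] = np.tanh(
                x[:, t] @ self.W + self._h[:, t] @ self.U + self.b)
        return self._h[:, 1:] if self.return_sequences else self._h[:, -1]

    def backward(self, gout):
        x, h = self._x, self._h
        N, T, _ = x.shape
        gW, gU, gb = (np.zeros_like(p) for p in self.params)
        gx = np.zeros_like(x)
        gh_next = np.zeros((N, self.units))
        for t in reversed(range(T)):
            gh = gh_next.copy()
            if self.return_sequences:
                gh += gout[:, t]
            elif t == T - 1:
                gh += gout
            gz = gh * (1.0 - h[:, t + 1] ** 2)
            gW += x[:, t].T @ gz
            gU += h[:, t].T @ gz
            gb += gz.sum(axis=0)
            gx[:, t] = gz @ self.W.T
            gh_next = gz @ self.U.T
        self.grads[0][...], self.grads[1][...], self.grads[2][...] = gW, gU, gb
        return gx


class LSTM(Layer):
    """Standard LSTM (forget-gate bias initialised to 1)."""

    def __init__(self, n_in: int, units: int, rng: np.random.Generator,
                 return_sequences: bool = False) -> None:
        super().__init__()
        self.units = units
        self.return_sequences = return_sequences
        self.W = glorot_uniform(rng, n_in, 4 * units, (n_in, 4 * units))
        self.U = np.concatenate([orthogonal(rng, units) for _ in range(4)],
                                axis=1)
        self.b = np.zeros(4 * units)
        self.b[units:2 * units] = 1.0  # forget gate
        self.params = [self.W, self.U, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, training):
        N, T, _ = x.shape
        u = self.units
        self._x = x
        self._h = np.zeros((N, T + 1, u))
        self._c = np.zeros((N, T + 1, u))
        self._gates = np.zeros((N, T, 4 * u))
        for t in range(T):
            z = x[:, t] @ self.W + self._h[:, t] @ self.U + self.b
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u:2 * u])
            g = np.tanh(z[:, 2 * u:3 * u])
            o = _sigmoid(z[:, 3 * u:])
            self._gates[:, t] = np.concatenate([i, f, g, o], axis=1)
            self._c[:, t + 1] = f * self._c[:, t] + i * g
            self._h[:, t + 1] = o * np.tanh(self._c[:, t + 1])
        return self._h[:, 1:] if self.return_sequences else self._h[:, -1]

    def backward(self, gout):
        x, h, c = self._x, self._h, self._c
        N, T, _ = x.shape
        u = self.units
        gW, gU, gb = (np.zeros_like(p) for p in self.params)
        gx = np.zeros_like(x)
        gh_next = np.zeros((N, u))
        gc_next = np.zeros((N, u))
        for t in reversed(range(T)):
            gh = gh_next.copy()
            if self.return_sequences:
                gh += gout[:, t]
            elif t == T - 1:
                gh += gout
            gates = self._gates[:, t]
            i, f, g, o = (gates[:, :u], gates[:, u:2 * u],
                          gates[:, 2 * u:3 * u], gates[:, 3 * u:])
            tc = np.tanh(c[:, t + 1])
            go = gh * tc
            gc = gc_next + gh * o * (1.0 - tc ** 2)
            gi = gc * g
            gf = gc * c[:, t]
            gg = gc * i
            gz = np.concatenate([
                gi * i * (1 - i), gf * f * (1 - f),
                gg * (1.0 - g ** 2), go * o * (1 - o)], axis=1)
            gW += x[:, t].T @ gz
            gU += h[:, t].T @ gz
            gb += gz.sum(axis=0)
            gx[:, t] = gz @ self.W.T
            gh_next = gz @ self.U.T
            gc_next = gc * f
        self.grads[0][...], self.grads[1][...], self.grads[2][...] = gW, gU, gb
        return gx


class GRU(Layer):
    """Gated recurrent unit: h = z*h_prev + (1-z)*h_cand."""

    def __init__(self, n_in: int, units: int, rng: np.random.Generator,
                 return_sequences: bool = False) -> None:
        super().__init__()
        self.units = units
        self.return_sequences = return_sequences
        self.W = glorot_uniform(rng, n_in, 3 * units, (n_in, 3 * units))
        self.U = np.concatenate([orthogonal(rng, units) for _ in range(3)],
                                axis=1)
        self.b = np.zeros(3 * units)
        self.params = [self.W, self.U, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, training):
        N, T, _ = x.shape
        u = self.units
        self._x = x
        self._h = np.zeros((N, T + 1, u))
        self._zrg = np.zeros((N, T, 3 * u))
        for t in range(T):
            hp = self._h[:, t]
            a = x[:, t] @ self.W + self.b
            z = _sigmoid(a[:, :u] + hp @ self.U[:, :u])
            r = _sigmoid(a[:, u:2 * u] + hp @ self.U[:, u:2 * u])
            g = np.tanh(a[:, 2 * u:] + (r * hp) @ self.U[:, 2 * u:])
            self._zrg[:, t] = np.concatenate([z, r, g], axis=1)
            self._h[:, t + 1] = z * hp + (1.0 - z) * g
        return self._h[:, 1:] if self.return_sequences else self._h[:, -1]

    def backward(self, gout):
        x, h = self._x, self._h
        N, T, _ = x.shape
        u = self.units
        gW, gU, gb = (np.zeros_like(p) for p in self.params)
        gx = np.zeros_like(x)
        gh_next = np.zeros((N, u))
        for t in reversed(range(T)):
            gh = gh_next.copy()
            if self.return_sequences:
                gh += gout[:, t]
            elif t == T - 1:
                gh += gout
            hp = h[:, t]
            zrg = self._zrg[:, t]
            z, r, g = zrg[:, :u], zrg[:, u:2 * u], zrg[:, 2 * u:]
            gz = gh * (hp - g) * z * (1 - z)
            gg = gh * (1.0 - z) * (1.0 - g ** 2)
            grh = gg @ self.U[:, 2 * u:].T          # grad wrt (r * hp)
            gr = grh * hp * r * (1 - r)
            ga = np.concatenate([gz, gr, gg], axis=1)
            gW += x[:, t].T @ ga
            gb += ga.sum(axis=0)
            gU[:, :u] += hp.T @ gz
            gU[:, u:2 * u] += hp.T @ gr
            gU[:, 2 * u:] += (r * hp).T @ gg
            gx[:, t] = ga @ self.W.T
            gh_next = (gh * z + gz @ self.U[:, :u].T
                       + gr @ self.U[:, u:2 * u].T + grh * r)
        self.grads[0][...], self.grads[1][...], self.grads[2][...] = gW, gU, gb
        return gx


class Conv1D(Layer):
    """1-D convolution over time, 'same' padding, stride 1."""

    def __init__(self, n_in: int, filters: int, kernel_size: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.kernel_size = kernel_size
        fan_in = n_in * kernel_size
        self.W = glorot_uniform(rng, fan_in, filters,
                                (kernel_size, n_in, filters))
        self.b = np.zeros(filters)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _pad(self, T):
        k = self.kernel_size
        total = k - 1
        return total // 2, total - total // 2

    def forward(self, x, training):
        N, T, C = x.shape
        pl, pr = self._pad(T)
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        self._xp = xp
        k = self.kernel_size
        out = np.empty((N, T, self.W.shape[2]))
        for t in range(T):
            # (N, k, C) . (k, C, F) -> (N, F)
            out[:, t] = np.tensordot(xp[:, t:t + k], self.W, axes=([1, 2],
                                                                   [0, 1]))
        return out + self.b

    def backward(self, gout):
        xp = self._xp
        N, Tp, C = xp.shape
        k = self.kernel_size
        T = gout.shape[1]
        gW = np.zeros_like(self.W)
        gxp = np.zeros_like(xp)
        for t in range(T):
            gW += np.tensordot(xp[:, t:t + k], gout[:, t], axes=([0], [0]))
            gxp[:, t:t + k] += np.tensordot(gout[:, t], self.W,
                                            axes=([1], [2]))
        self.grads[0][...] = gW
        self.grads[1][...] = gout.sum(axis=(0, 1))
        pl, pr = self._pad(T)
        return gxp[:, pl:Tp - pr]


class MaxPool1D(Layer):
    """Max pooling over time, pool size = stride, 'valid' padding."""

    def __init__(self, pool: int = 2) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x, training):
        N, T, C = x.shape
        To = T // self.pool
        if To < 1:
            raise ValueError("sequence shorter than pool size")
        xr = x[:, :To * self.pool].reshape(N, To, self.pool, C)
        self._arg = xr.argmax(axis=2)
        self._shape = x.shape
        return xr.max(axis=2)

    def backward(self, gout):
        N, To, C = gout.shape
        gx = np.zeros(self._shape)
        n_idx, t_idx, c_idx = np.ogrid[:N, :To, :C]
        times = t_idx * self.pool + self._arg
        gx[n_idx, times, c_idx] = gout
        return gx
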