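"""A small seeded feed-forward/recurrent network engine on numpy.

Implements exactly the layer zoo the six parametric classifiers need —
dense, dropout, 1-D convolution, max-pooling, flatten, simple recurrent,
LSTM, bidirectional LSTM and GRU — with hand-derived backpropagation, a
softmax cross-entropy head and an Adam optimizer. Everything is driven by a
single integer seed: initialization, dropout masks and batch shuffling are
all drawn from generators spawned from it, so training is bit-reproducible
on one thread.

Conventions:

* Dense/recurrent kernels use Glorot-uniform initialization, biases zero
  (LSTM forget-gate bias 1).
* LSTM and the simple recurrent cell carry a single bias vector per gate;
  the GRU carries separate input and recurrent biases per gate and applies
  the reset gate after the recurrent matrix product, i.e.
  ``h~ = tanh(W_h x + b_in + r * (U_h h + b_rec))`` and
  ``h = (1 - z) * h_prev + z * h~``.
* Inputs are (batch, features) for dense stacks, (batch, steps, channels)
  for convolutional/recurrent stacks.
"""

from __future__ import annotations

import numpy as np


def _glorot(rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: subclasses fill ``params``/``grads`` and the two passes."""

    def __init__(self) -> None:
        self.params: list = []
        self.grads: list = []

    def initialize(self, rng: np.random.Generator) -> None:  # pragma: no cover
        pass

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grads(self) -> None:
        for g in self.grads:
            g[...] = 0.0


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, activation: str | None = None) -> None:
        super().__init__()
        self.in_dim, self.out_dim, self.activation = in_dim, out_dim, activation
        self.W = np.zeros((in_dim, out_dim))
        self.b = np.zeros(out_dim)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def initialize(self, rng: np.random.Generator) -> None:
        self.W[...] = _glorot(rng, self.W.shape, self.in_dim, self.out_dim)
        self.b[...] = 0.0

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        y = x @ self.W + self.b
        if self.activation == "relu":
            self._mask = y > 0
            y = y * self._mask
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            dy = dy * self._mask
        self.grads[0] += self._x.T @ dy
        self.grads[1] += dy.sum(axis=0)
        return dy @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity at inference. Mask rng set by the network."""

    def __init__(self, rate: float = 0.3) -> None:
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Conv1D(Layer):
    """Valid-padding 1-D convolution over (batch, steps, channels)."""

    def __init__(self, in_channels: int, filters: int, kernel: int, activation: str | None = "relu") -> None:
        super().__init__()
        self.in_channels, self.filters, self.kernel = in_channels, filters, kernel
        self.activation = activation
        self.W = np.zeros((kernel, in_channels, filters))
        self.b = np.zeros(filters)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def initialize(self, rng: np.random.Generator) -> None:
        fan_in = self.kernel * self.in_channels
        self.W[...] = _glorot(rng, self.W.shape, fan_in, self.filters)
        self.b[...] = 0.0

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, T, C = x.shape
        if T < self.kernel:
            raise ValueError(f"sequence length {T} shorter than kernel {self.kernel}")
        # windows: (B, L, C, k) with L = T - k + 1
        windows = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=1)
        self._windows = windows
        self._in_shape = x.shape
        y = np.tensordot(windows, self.W, axes=([3, 2], [0, 1])) + self.b
        if self.activation == "relu":
            self._mask = y > 0
            y = y * self._mask
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            dy = dy * self._mask
        # dW[j, c, f] = sum_{b, t} x[b, t + j, c] dy[b, t, f]
        dW = np.tensordot(self._windows, dy, axes=([0, 1], [0, 1]))  # (C, k, F)
        self.grads[0] += dW.transpose(1, 0, 2)
        self.grads[1] += dy.sum(axis=(0, 1))
        dx = np.zeros(self._in_shape)
        L = dy.shape[1]
        for j in range(self.kernel):
            dx[:, j : j + L, :] += dy @ self.W[j].T
        return dx


class MaxPool1D(Layer):
    """Non-overlapping max pooling over the step axis (trailing remainder dropped)."""

    def __init__(self, width: int = 2) -> None:
        super().__init__()
        self.width = width

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, T, C = x.shape
        L = T // self.width
        xr = x[:, : L * self.width].reshape(B, L, self.width, C)
        self._argmax = xr.argmax(axis=2)
        self._in_shape = x.shape
        return xr.max(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, L, C = dy.shape
        dx = np.zeros(self._in_shape)
        dxr = dx[:, : L * self.width].reshape(B, L, self.width, C)
        b_idx, l_idx, c_idx = np.ogrid[:B, :L, :C]
        dxr[b_idx, l_idx, self._argmax, c_idx] = dy
        return dx


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class SimpleRNN(Layer):
    """tanh recurrence, single bias; emits the final hidden state."""

    def __init__(self, in_dim: int, units: int) -> None:
        super().__init__()
        self.in_dim, self.units = in_dim, units
        self.W = np.zeros((in_dim, units))
        self.U = np.zeros((units, units))
        self.b = np.zeros(units)
        self.params = [self.W, self.U, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def initialize(self, rng: np.random.Generator) -> None:
        self.W[...] = _glorot(rng, self.W.shape, self.in_dim, self.units)
        self.U[...] = _glorot(rng, self.U.shape, self.units, self.units)
        self.b[...] = 0.0

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, T, _ = x.shape
        h = np.zeros((B, self.units))
        self._x, self._hs = x, [h]
        for t in range(T):
            h = np.tanh(x[:, t] @ self.W + h @ self.U + self.b)
            self._hs.append(h)
        return h

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, hs = self._x, self._hs
        B, T, _ = x.shape
        dx = np.zeros_like(x)
        dh = dy
        for t in range(T - 1, -1, -1):
            da = dh * (1.0 - hs[t + 1] ** 2)
            self.grads[0] += x[:, t].T @ da
            self.grads[1] += hs[t].T @ da
            self.grads[2] += da.sum(axis=0)
            dx[:, t] = da @ self.W.T
            dh = da @ self.U.T
        return dx


class LSTM(Layer):
    """Standard LSTM cell, single bias per gate (gate order i, f, g, o)."""

    def __init__(self, in_dim: int, units: int) -> None:
        super().__init__()
        self.in_dim, self.units = in_dim, units
        self.W = np.zeros((in_dim, 4 * units))
        self.U = np.zeros((units, 4 * units))
        self.b = np.zeros(4 * units)
        self.params = [self.W, self.U, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def initialize(self, rng: np.random.Generator) -> None:
        u = self.units
        self.W[...] = _glorot(rng, self.W.shape, self.in_dim, u)
        self.U[...] = _glorot(rng, self.U.shape, u, u)
        self.b[...] = 0.0
        self.b[u : 2 * u] = 1.0  # forget-gate bias

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, T, _ = x.shape
        u = self.units
        h = np.zeros((B, u))
        c = np.zeros((B, u))
        self._x = x
        self._cache = []
        for t in range(T):
            z = x[:, t] @ self.W + h @ self.U + self.b
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = _sigmoid(z[:, 3 * u :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            self._cache.append((h, c, i, f, g, o, tc))
            h, c = o * tc, c_new
        return h

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        B, T, _ = x.shape
        u = self.units
        dx = np.zeros_like(x)
        dh, dc = dy, np.zeros((B, u))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc**2)
            di, df, dg = dc * g, dc * c_prev, dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1.0 - g**2), do * o * (1 - o)],
                axis=1,
            )
            self.grads[0] += x[:, t].T @ dz
            self.grads[1] += h_prev.T @ dz
            self.grads[2] += dz.sum(axis=0)
            dx[:, t] = dz @ self.W.T
            dh = dz @ self.U.T
            dc = dc * f
        return dx


class BiLSTM(Layer):
    """Forward and backward LSTMs; emits concatenated final hidden states."""

    def __init__(self, in_dim: int, units: int) -> None:
        super().__init__()
        self.units = units
        self.fwd = LSTM(in_dim, units)
        self.bwd = LSTM(in_dim, units)
        self.params = self.fwd.params + self.bwd.params
        self.grads = self.fwd.grads + self.bwd.grads

    def initialize(self, rng: np.random.Generator) -> None:
        self.fwd.initialize(rng)
        self.bwd.initialize(rng)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        hf = self.fwd.forward(x, train)
        hb = self.bwd.forward(x[:, ::-1], train)
        return np.concatenate([hf, hb], axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        u = self.units
        dxf = self.fwd.backward(dy[:, :u])
        dxb = self.bwd.backward(dy[:, u:])
        return dxf + dxb[:, ::-1]


class GRU(Layer):
    """GRU with separate input/recurrent biases per gate (gate order z, r, h)."""

    def __init__(self, in_dim: int, units: int) -> None:
        super().__init__()
        self.in_dim, self.units = in_dim, units
        self.W = np.zeros((in_dim, 3 * units))
        self.U = np.zeros((units, 3 * units))
        self.b_in = np.zeros(3 * units)
        self.b_rec = np.zeros(3 * units)
        self.params = [self.W, self.U, self.b_in, self.b_rec]
        self.grads = [np.zeros_like(p) for p in self.params]

    def initialize(self, rng: np.random.Generator) -> None:
        u = self.units
        self.W[...] = _glorot(rng, self.W.shape, self.in_dim, u)
        self.U[...] = _glorot(rng, self.U.shape, u, u)
        self.b_in[...] = 0.0
        self.b_rec[...] = 0.0

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, T, _ = x.shape
        u = self.units
        h = np.zeros((B, u))
        self._x = x
        self._cache = []
        for t in range(T):
            xp = x[:, t] @ self.W + self.b_in
            hp = h @ self.U + self.b_rec
            z = _sigmoid(xp[:, :u] + hp[:, :u])
            r = _sigmoid(xp[:, u : 2 * u] + hp[:, u : 2 * u])
            s = hp[:, 2 * u :]
            hh = np.tanh(xp[:, 2 * u :] + r * s)
            h_new = (1.0 - z) * h + z * hh
            self._cache.append((h, z, r, s, hh))
            h = h_new
        return h

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        B, T, _ = x.shape
        u = self.units
        dx = np.zeros_like(x)
        dh = dy
        for t in range(T - 1, -1, -1):
            h_prev, z, r, s, hh = self._cache[t]
            dz = dh * (hh - h_prev)
            dhh = dh * z
            dh_prev = dh * (1.0 - z)
            da = dhh * (1.0 - hh**2)  # pre-tanh candidate
            dr = da * s
            ds = da * r
            dz_pre = dz * z * (1.0 - z)
            dr_pre = dr * r * (1.0 - r)
            dxp = np.concatenate([dz_pre, dr_pre, da], axis=1)
            dhp = np.concatenate([dz_pre, dr_pre, ds], axis=1)
            self.grads[0] += x[:, t].T @ dxp
            self.grads[1] += h_prev.T @ dhp
            self.grads[2] += dxp.sum(axis=0)
            self.grads[3] += dhp.sum(axis=0)
            dx[:, t] = dxp @ self.W.T
            dh = dh_prev + dhp @ self.U.T
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    B = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = -np.mean(np.log(p[np.arange(B), y] + eps))
    grad = p.copy()
    grad[np.arange(B), y] -= 1.0
    return loss, grad / B


class Adam:
    def __init__(self, params: list, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class Network:
    """A sequential stack with a softmax cross-entropy head.

    ``input_kind`` controls how a (batch, features) matrix is presented to
    the first layer: "flat" passes it through, "sequence_1ch" reshapes to
    (batch, features, 1) for convolutional stacks, "single_step" to
    (batch, 1, features) for the recurrent cells (which consume the whole
    descriptor as one timestep).
    """

    def __init__(self, layers: list, input_kind: str = "flat") -> None:
        if input_kind not in ("flat", "sequence_1ch", "single_step"):
            raise ValueError(f"unknown input_kind {input_kind!r}")
        self.layers = layers
        self.input_kind = input_kind
        self.history: dict = {"loss": [], "accuracy": []}

    # -- plumbing ---------------------------------------------------------
    @property
    def params(self) -> list:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list:
        return [g for layer in self.layers for g in layer.grads]

    def n_params(self) -> int:
        return sum(p.size for p in self.params)

    def _reshape(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.input_kind == "sequence_1ch":
            return X[:, :, None]
        if self.input_kind == "single_step":
            return X[:, None, :]
        return X

    def initialize(self, seed: int) -> None:
        ss = np.random.SeedSequence(seed)
        init_rng, self._shuffle_rng, drop_rng = [np.random.default_rng(s) for s in ss.spawn(3)]
        for layer in self.layers:
            layer.initialize(init_rng)
            if isinstance(layer, Dropout):
                layer.rng = drop_rng

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        a = self._reshape(X)
        for layer in self.layers:
            a = layer.forward(a, train)
        return a

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.zero_grads()

    # -- training ---------------------------------------------------------
    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        lr: float = 1e-3,
        batch_size: int = 32,
        max_epochs: int = 200,
        patience: int = 10,
        min_delta: float = 1e-5,
        seed: int = 0,
    ) -> dict:
        """Minimize softmax cross-entropy with Adam; early stop on a training
        loss plateau (no improvement > min_delta for ``patience`` epochs)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.initialize(seed)
        opt = Adam(self.params, lr=lr)
        n = X.shape[0]
        best_loss, since_best = np.inf, 0
        for epoch in range(max_epochs):
            order = self._shuffle_rng.permutation(n)
            epoch_loss, correct = 0.0, 0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                logits = self.forward(X[idx], train=True)
                loss, dlogits = cross_entropy(logits, y[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}, batch offset {start}; "
                        "lower the learning rate or rescale the features"
                    )
                self.zero_grads()
                self.backward(dlogits)
                opt.step(self.grads)
                epoch_loss += loss * len(idx)
                correct += int((logits.argmax(axis=1) == y[idx]).sum())
            epoch_loss /= n
            self.history["loss"].append(epoch_loss)
            self.history["accuracy"].append(correct / n)
            if epoch_loss < best_loss - min_delta:
                best_loss, since_best = epoch_loss, 0
            else:
                since_best += 1
                if since_best >= patience:
                    break
        return self.history

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities (rows sum to 1); dropout disabled."""
        return softmax(self.forward(X, train=False))
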