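"""Layers with forward passes and hand-written reverse-mode gradients.

All layers share one contract: ``forward(x, train)`` caches what backward
needs; ``backward(grad_out)`` accumulates parameter gradients into
``self.grads`` and returns the gradient w.r.t. the layer input.  Arrays are
float32 throughout; batch-time axes are flattened where a layer is
pointwise over features (batch norm, dropout, dense heads on sequences are
not needed — the architectures only apply dense layers to 2D inputs).
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # overflow-safe via tanh: σ(x) = (tanh(x/2) + 1) / 2
    return 0.5 * (np.tanh(0.5 * x) + 1.0)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, (n_in, n_out)).astype(F32)
        self.b = np.zeros(n_out, dtype=F32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.grads[0] += self._x.T @ g
        self.grads[1] += g.sum(axis=0)
        return g @ self.W.T


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, g):
        return np.where(self._mask, g, 0.0)


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / F32(keep)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class BatchNorm(Layer):
    """Batch normalization over all leading axes (features on the last axis).

    Works for (N, F) dense activations, (N, T, F) sequences and, via the
    ``channel_axis`` option, (N, C, H, W) convolutional maps.
    """

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5,
                 channel_axis: int = -1):
        super().__init__()
        self.gamma = np.ones(n_features, dtype=F32)
        self.beta = np.zeros(n_features, dtype=F32)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(n_features, dtype=F32)
        self.running_var = np.ones(n_features, dtype=F32)
        self.momentum = momentum
        self.eps = eps
        self.channel_axis = channel_axis

    def _to2d(self, x):
        x = np.moveaxis(x, self.channel_axis, -1)
        self._shape = x.shape
        return x.reshape(-1, x.shape[-1])

    def _from2d(self, x2):
        return np.moveaxis(x2.reshape(self._shape), -1, self.channel_axis)

    def forward(self, x, train):
        x2 = self._to2d(x)
        if train:
            mean = x2.mean(axis=0)
            var = x2.var(axis=0)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(F32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x2 - mean) * self._istd
        return self._from2d(self._xhat * self.gamma + self.beta)

    def backward(self, g):
        g2 = self._to2d(g)
        n = g2.shape[0]
        self.grads[0] += (g2 * self._xhat).sum(axis=0)
        self.grads[1] += g2.sum(axis=0)
        gx_hat = g2 * self.gamma
        gx = (
            gx_hat
            - gx_hat.mean(axis=0)
            - self._xhat * (gx_hat * self._xhat).mean(axis=0)
        ) * self._istd
        return self._from2d(gx.astype(F32))


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: tuple):
        super().__init__()
        self.shape = shape  # per-example shape

    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, g):
        return g.reshape(self._shape)


class Conv2D(Layer):
    """3x3 'same' convolution, stride 1, NHWC layout internally.

    Implemented as a sum of k² shifted matmuls over the channel axis, which
    keeps the work inside BLAS without materializing an im2col tensor.
    Weights are stored (k, k, c_in, c_out).
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        super().__init__()
        fan_in, fan_out = c_in * k * k, c_out * k * k
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.W = rng.uniform(-limit, limit, (k, k, c_in, c_out)).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.k = k

    def forward(self, x, train):
        # x: (N, C, H, W) at the interface; compute in channels-last
        N, C, H, W = x.shape
        p = self.k // 2
        xl = np.moveaxis(x, 1, -1)  # (N, H, W, C)
        xp = np.zeros((N, H + 2 * p, W + 2 * p, C), dtype=F32)
        xp[:, p:p + H, p:p + W] = xl
        self._xp = xp
        self._hw = (H, W)
        out = np.zeros((N, H, W, self.W.shape[-1]), dtype=F32)
        flat = out.reshape(-1, self.W.shape[-1])
        for i in range(self.k):
            for j in range(self.k):
                patch = xp[:, i:i + H, j:j + W].reshape(-1, C)
                flat += patch @ self.W[i, j]
        out += self.b
        return np.moveaxis(out, -1, 1)

    def backward(self, g):
        H, W = self._hw
        p = self.k // 2
        N = g.shape[0]
        c_in, c_out = self.W.shape[2], self.W.shape[3]
        gl = np.ascontiguousarray(np.moveaxis(g, 1, -1))  # (N, H, W, c_out)
        gflat = gl.reshape(-1, c_out)
        self.grads[1] += gflat.sum(axis=0)
        dxp = np.zeros_like(self._xp)
        for i in range(self.k):
            for j in range(self.k):
                patch = self._xp[:, i:i + H, j:j + W].reshape(-1, c_in)
                self.grads[0][i, j] += patch.T @ gflat
                dxp[:, i:i + H, j:j + W] += (gflat @ self.W[i, j].T).reshape(N, H, W, c_in)
        dx = dxp[:, p:p + H, p:p + W]
        return np.moveaxis(dx, -1, 1)


class LSTM(Layer):
    """Single-direction LSTM over (N, T, F) sequences.

    Gate order i, f, g, o in one fused weight block; the forget-gate bias is
    initialized to 1.  ``return_sequences`` yields (N, T, H), otherwise the
    last hidden state (N, H).  ``reverse`` processes the sequence backward
    (used by the bidirectional wrapper).
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator,
                 return_sequences: bool = True, reverse: bool = False):
        super().__init__()
        H = n_hidden
        limit = np.sqrt(6.0 / (n_in + 4 * H))
        self.Wx = rng.uniform(-limit, limit, (n_in, 4 * H)).astype(F32)
        # orthogonal recurrent init, one block per gate
        blocks = [np.linalg.qr(rng.normal(size=(H, H)))[0] for _ in range(4)]
        self.Wh = np.concatenate(blocks, axis=1).astype(F32)
        self.b = np.zeros(4 * H, dtype=F32)
        self.b[H:2 * H] = 1.0
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]
        self.H = H
        self.return_sequences = return_sequences
        self.reverse = reverse

    def forward(self, x, train):
        if self.reverse:
            x = x[:, ::-1]
        N, T, F_in = x.shape
        H = self.H
        self._x = x
        xproj = x.reshape(N * T, F_in) @ self.Wx + self.b
        xproj = xproj.reshape(N, T, 4 * H)
        h = np.zeros((N, H), dtype=F32)
        c = np.zeros((N, H), dtype=F32)
        self._gates = np.empty((T, N, 4 * H), dtype=F32)
        self._cs = np.empty((T, N, H), dtype=F32)
        self._tcs = np.empty((T, N, H), dtype=F32)
        self._hs = np.empty((T, N, H), dtype=F32)
        for t in range(T):
            z = self._gates[t]
            np.add(xproj[:, t], h @ self.Wh, out=z)
            z[:, :2 * H] = _sigmoid(z[:, :2 * H])
            np.tanh(z[:, 2 * H:3 * H], out=z[:, 2 * H:3 * H])
            z[:, 3 * H:] = _sigmoid(z[:, 3 * H:])
            c = z[:, H:2 * H] * c + z[:, :H] * z[:, 2 * H:3 * H]
            tc = np.tanh(c)
            h = z[:, 3 * H:] * tc
            self._cs[t] = c
            self._tcs[t] = tc
            self._hs[t] = h
        out = self._hs.transpose(1, 0, 2)
        if self.return_sequences:
            return out[:, ::-1] if self.reverse else out
        return out[:, -1]

    def backward(self, grad):
        x = self._x
        N, T, F_in = x.shape
        H = self.H
        if self.return_sequences:
            gh_seq = grad[:, ::-1] if self.reverse else grad
            gh_seq = gh_seq.transpose(1, 0, 2)
        else:
            gh_seq = np.zeros((T, N, H), dtype=F32)
            gh_seq[-1] = grad
        dWx, dWh, db = self.grads
        dh_next = np.zeros((N, H), dtype=F32)
        dc_next = np.zeros((N, H), dtype=F32)
        dz_all = np.empty((T, N, 4 * H), dtype=F32)
        for t in range(T - 1, -1, -1):
            gates = self._gates[t]
            i, f = gates[:, :H], gates[:, H:2 * H]
            g, o = gates[:, 2 * H:3 * H], gates[:, 3 * H:]
            c_prev = self._cs[t - 1] if t > 0 else np.zeros((N, H), dtype=F32)
            tc = self._tcs[t]
            dh = gh_seq[t] + dh_next
            dc = dh * o * (1.0 - tc * tc) + dc_next
            dz = dz_all[t]
            dz[:, :H] = dc * g * i * (1.0 - i)
            dz[:, H:2 * H] = dc * c_prev * f * (1.0 - f)
            dz[:, 2 * H:3 * H] = dc * i * (1.0 - g * g)
            dz[:, 3 * H:] = dh * tc * o * (1.0 - o)
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        dz_flat = dz_all.transpose(1, 0, 2).reshape(N * T, 4 * H)
        h_prev = np.concatenate(
            [np.zeros((1, N, H), dtype=F32), self._hs[:-1]], axis=0
        ).transpose(1, 0, 2).reshape(N * T, H)
        dWh += h_prev.T @ dz_flat
        dWx += x.reshape(N * T, F_in).T @ dz_flat
        db += dz_flat.sum(axis=0)
        dx = (dz_flat @ self.Wx.T).reshape(N, T, F_in)
        return dx[:, ::-1] if self.reverse else dx


class BiLSTM(Layer):
    """Bidirectional LSTM: forward and backward passes concatenated on the
    feature axis, output shape (N, T, 2H)."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = LSTM(n_in, n_hidden, rng, return_sequences=True, reverse=False)
        self.bwd = LSTM(n_in, n_hidden, rng, return_sequences=True, reverse=True)
        self.params = self.fwd.params + self.bwd.params
        self.grads = self.fwd.grads + self.bwd.grads
        self.H = n_hidden

    def forward(self, x, train):
        return np.concatenate(
            [self.fwd.forward(x, train), self.bwd.forward(x, train)], axis=2
        )

    def backward(self, g):
        return self.fwd.backward(g[:, :, :self.H]) + self.bwd.backward(g[:, :, self.H:])


class Sequential:
    """Plain layer chain with shared parameter/gradient views."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    @property
    def params(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for l in self.layers for g in l.grads]

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w
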