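"""Minimal seeded neural-network primitives (NumPy).

Only what the two-branch binding model needs: 1-D "same" convolution,
non-overlapping max-pooling, dense layers, inverted dropout, the fused
sigmoid + binary-cross-entropy head, and Adam.  Shapes follow the
channels-last convention: sequence tensors are (batch, length, channels).

All stochastic elements (initialisation, dropout masks) draw from generators
handed in by the caller, so a model run is exactly reproducible from a seed.
"""

from __future__ import annotations

import numpy as np


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float64)


class Conv1D:
    """Same-padded 1-D convolution, weights (k, c_in, c_out)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        self.kernel = kernel
        self.W = he_init(rng, (kernel, c_in, c_out), fan_in=kernel * c_in)
        self.b = np.zeros(c_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, pad = self.kernel, self.kernel // 2
        B, L, _ = x.shape
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        out = np.broadcast_to(self.b, (B, L, self.b.shape[0])).copy()
        for t in range(k):
            out += xp[:, t : t + L, :] @ self.W[t]
        self._xp = xp
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k, pad = self.kernel, self.kernel // 2
        B, L, _ = dout.shape
        xp = self._xp
        self.dW = np.empty_like(self.W)
        dxp = np.zeros_like(xp)
        for t in range(k):
            self.dW[t] = np.einsum("blc,blo->co", xp[:, t : t + L, :], dout)
            dxp[:, t : t + L, :] += dout @ self.W[t].T
        self.db = dout.sum(axis=(0, 1))
        return dxp[:, pad : pad + L, :]

    @property
    def params(self):
        return [("W", self.W), ("b", self.b)]

    @property
    def grads(self):
        return [self.dW, self.db]


class MaxPool1D:
    """Non-overlapping max pool along the length axis; trailing remainder dropped."""

    def __init__(self, pool: int):
        self.pool = pool

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, C = x.shape
        Lp = L // self.pool
        xw = x[:, : Lp * self.pool, :].reshape(B, Lp, self.pool, C)
        self._argmax = xw.argmax(axis=2)
        self._in_shape = x.shape
        return xw.max(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, Lp, C = dout.shape
        dxw = np.zeros((B, Lp, self.pool, C))
        bi, li, ci = np.ogrid[:B, :Lp, :C]
        dxw[bi, li, self._argmax, ci] = dout
        dx = np.zeros(self._in_shape)
        dx[:, : Lp * self.pool, :] = dxw.reshape(B, Lp * self.pool, C)
        return dx

    params: list = []
    grads: list = []


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    params: list = []
    grads: list = []


class Dense:
    def __init__(
        self,
        n_in: int,
        n_out: int,
        rng: np.random.Generator | None,
        zero_init: bool = False,
    ):
        if zero_init:
            self.W = np.zeros((n_in, n_out))
        else:
            assert rng is not None
            self.W = he_init(rng, (n_in, n_out), fan_in=n_in)
        self.b = np.zeros(n_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    @property
    def params(self):
        return [("W", self.W), ("b", self.b)]

    @property
    def grads(self):
        return [self.dW, self.db]


class Dropout:
    """Inverted dropout; identity when not training or rate == 0."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask

    params: list = []
    grads: list = []


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss_and_grad(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Binary cross-entropy on logits; returns (mean loss, dL/dz).

    Computed from logits (log-sum-exp form) for numerical stability; the
    gradient is the familiar (sigmoid(z) - y) / n.
    """
    z = z.ravel()
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    dz = (sigmoid(z) - y) / z.shape[0]
    return loss, dz.reshape(-1, 1)


class Adam:
    """Adaptive-moment estimation over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
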