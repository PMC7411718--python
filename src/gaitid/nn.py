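"""Minimal NumPy neural-network engine for the gait identification models.

Implements exactly the pieces the identification networks need: 1-D
convolution over time with 'same' padding, dense layers, ReLU, inverted
dropout, an LSTM with hard-sigmoid gate activations and recurrent dropout,
softmax cross-entropy, and Adam. Forward passes store what backward needs;
training code drives ``forward``/``backward`` explicitly.

Conventions: batches first; time series are (B, T, C); all floats are
float32 for throughput. Layers are deterministic given the ``rng`` they are
handed (dropout masks) and the one used at initialization.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    """A trainable array and its gradient accumulator."""

    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = np.asarray(value, dtype=DTYPE)
        self.g = np.zeros_like(self.v)


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def hard_sigmoid(x: np.ndarray) -> np.ndarray:
    """Piecewise-linear sigmoid: clip(0.2 x + 0.5, 0, 1)."""
    return np.clip(0.2 * x + 0.5, 0.0, 1.0)


def _hard_sigmoid_grad_from_output(y: np.ndarray) -> np.ndarray:
    # slope 0.2 on the open linear region, 0 on the clipped flats
    return 0.2 * ((y > 0.0) & (y < 1.0))


def softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and d(loss)/d(logits) for integer labels."""
    probs = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()
    grad = probs
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(DTYPE)


class Layer:
    params: list[Param]

    def forward(self, x, training: bool = False, rng=None):
        raise NotImplementedError

    def backward(self, dout):
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = Param(glorot_uniform(rng, (in_dim, out_dim), in_dim, out_dim))
        self.b = Param(np.zeros(out_dim))
        self.params = [self.W, self.b]

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.W.v + self.b.v

    def backward(self, dout):
        self.W.g += self._x.T @ dout
        self.b.g += dout.sum(axis=0)
        return dout @ self.W.v.T


class ReLU(Layer):
    params: list[Param] = []

    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    params: list[Param] = []

    def __init__(self, keep_prob: float):
        if not 0.0 < keep_prob <= 1.0:
            raise ValueError("keep_prob must be in (0, 1]")
        self.keep_prob = keep_prob

    def forward(self, x, training=False, rng=None):
        if not training or self.keep_prob == 1.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) < self.keep_prob).astype(DTYPE)
        self._mask /= self.keep_prob
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    params: list[Param] = []

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Conv1D(Layer):
    """Temporal convolution, stride 1, zero 'same' padding (output T == input T).

    The kernel spans all input channels; weights are (K, C_in, C_out). For an
    even kernel length K the left pad is (K-1)//2 and the right pad K//2.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        fan_in, fan_out = kernel * in_ch, kernel * out_ch
        self.W = Param(glorot_uniform(rng, (kernel, in_ch, out_ch), fan_in, fan_out))
        self.b = Param(np.zeros(out_ch))
        self.kernel = kernel
        self.in_ch, self.out_ch = in_ch, out_ch
        self.params = [self.W, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        B, T, C = x.shape
        K = self.kernel
        pad_l, pad_r = (K - 1) // 2, K // 2
        padded = np.zeros((B, T + K - 1, C), dtype=DTYPE)
        padded[:, pad_l : pad_l + T] = x
        windows = np.lib.stride_tricks.sliding_window_view(padded, K, axis=1)
        # windows: (B, T, C, K) -> (B, T, K, C)
        return np.ascontiguousarray(windows.transpose(0, 1, 3, 2))

    def forward(self, x, training=False, rng=None):
        B, T, C = x.shape
        if C != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {C}")
        cols = self._im2col(np.asarray(x, dtype=DTYPE))
        self._cols, self._in_shape = cols, (B, T, C)
        flat = cols.reshape(B * T, self.kernel * C)
        out = flat @ self.W.v.reshape(self.kernel * C, self.out_ch) + self.b.v
        return out.reshape(B, T, self.out_ch)

    def backward(self, dout):
        B, T, C = self._in_shape
        K = self.kernel
        dflat = dout.reshape(B * T, self.out_ch)
        cols_flat = self._cols.reshape(B * T, K * C)
        self.W.g += (cols_flat.T @ dflat).reshape(K, C, self.out_ch)
        self.b.g += dflat.sum(axis=0)
        dcols = (dflat @ self.W.v.reshape(K * C, self.out_ch).T).reshape(B, T, K, C)
        pad_l = (K - 1) // 2
        dpad = np.zeros((B, T + K - 1, C), dtype=DTYPE)
        for k in range(K):
            dpad[:, k : k + T] += dcols[:, :, k]
        return dpad[:, pad_l : pad_l + T]


class LSTM(Layer):
    """LSTM with hard-sigmoid gates, tanh cell/output activations.

    Gate order in the fused weight matrices is (input, forget, candidate,
    output); the forget-gate bias starts at 1. Recurrent dropout applies one
    mask, fixed across time steps, to the hidden state entering the
    recurrent matmul (training only). ``return_sequences`` selects between
    the full (B, T, U) output and the final (B, U) vector.
    """

    def __init__(
        self,
        in_dim: int,
        units: int,
        rng: np.random.Generator,
        return_sequences: bool = False,
        recurrent_dropout: float = 0.0,
    ):
        U = units
        self.Wx = Param(glorot_uniform(rng, (in_dim, 4 * U), in_dim, 4 * U))
        self.Wh = Param(glorot_uniform(rng, (U, 4 * U), U, 4 * U))
        b = np.zeros(4 * U, dtype=DTYPE)
        b[U : 2 * U] = 1.0  # forget-gate bias
        self.b = Param(b)
        self.units = U
        self.in_dim = in_dim
        self.return_sequences = return_sequences
        self.recurrent_dropout = recurrent_dropout
        self.params = [self.Wx, self.Wh, self.b]

    def forward(self, x, training=False, rng=None):
        x = np.asarray(x, dtype=DTYPE)
        B, T, C = x.shape
        U = self.units
        keep = 1.0 - self.recurrent_dropout
        if training and keep < 1.0:
            rmask = (rng.random((B, U)) < keep).astype(DTYPE) / keep
        else:
            rmask = None
        h = np.zeros((B, U), dtype=DTYPE)
        c = np.zeros((B, U), dtype=DTYPE)
        # caches for BPTT
        self._x = x
        self._rmask = rmask
        self._i = np.empty((T, B, U), dtype=DTYPE)
        self._f = np.empty((T, B, U), dtype=DTYPE)
        self._g = np.empty((T, B, U), dtype=DTYPE)
        self._o = np.empty((T, B, U), dtype=DTYPE)
        self._tc = np.empty((T, B, U), dtype=DTYPE)
        self._c_prev = np.empty((T, B, U), dtype=DTYPE)
        self._hd = np.empty((T, B, U), dtype=DTYPE)
        seq = np.empty((B, T, U), dtype=DTYPE)
        xz = x @ self.Wx.v + self.b.v  # (B, T, 4U), input part precomputed
        for t in range(T):
            hd = h * rmask if rmask is not None else h
            z = xz[:, t] + hd @ self.Wh.v
            i = hard_sigmoid(z[:, :U])
            f = hard_sigmoid(z[:, U : 2 * U])
            g = np.tanh(z[:, 2 * U : 3 * U])
            o = hard_sigmoid(z[:, 3 * U :])
            self._c_prev[t] = c
            self._hd[t] = hd
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            self._i[t], self._f[t], self._g[t], self._o[t], self._tc[t] = i, f, g, o, tc
            seq[:, t] = h
        self._seq = seq
        return seq if self.return_sequences else seq[:, -1]

    def backward(self, dout):
        x = self._x
        B, T, C = x.shape
        U = self.units
        if self.return_sequences:
            dseq = np.asarray(dout, dtype=DTYPE)
        else:
            dseq = np.zeros((B, T, U), dtype=DTYPE)
            dseq[:, -1] = dout
        dx_z = np.empty((T, B, 4 * U), dtype=DTYPE)  # grads wrt fused pre-activations
        dh_next = np.zeros((B, U), dtype=DTYPE)
        dc_next = np.zeros((B, U), dtype=DTYPE)
        WhT = self.Wh.v.T
        for t in range(T - 1, -1, -1):
            i, f, g, o = self._i[t], self._f[t], self._g[t], self._o[t]
            tc = self._tc[t]
            dh = dseq[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            dg = dc * i
            df = dc * self._c_prev[t]
            dc_next = dc * f
            dz = np.empty((B, 4 * U), dtype=DTYPE)
            dz[:, :U] = di * _hard_sigmoid_grad_from_output(i)
            dz[:, U : 2 * U] = df * _hard_sigmoid_grad_from_output(f)
            dz[:, 2 * U : 3 * U] = dg * (1.0 - g * g)
            dz[:, 3 * U :] = do * _hard_sigmoid_grad_from_output(o)
            dx_z[t] = dz
            dh_prev = dz @ WhT
            if self._rmask is not None:
                dh_prev *= self._rmask
            dh_next = dh_prev
            self.Wh.g += self._hd[t].T @ dz
        dz_bt = dx_z.transpose(1, 0, 2)  # (B, T, 4U)
        self.Wx.g += np.einsum("btc,btu->cu", x, dz_bt, optimize=True)
        self.b.g += dz_bt.sum(axis=(0, 1))
        return dz_bt @ self.Wx.v.T


class Adam:
    """Adam with optional global-norm gradient clipping."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
        clip_norm: float | None = 5.0,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.v) for p in params]
        self.v = [np.zeros_like(p.v) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.g[...] = 0.0

    def step(self):
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((p.g.astype(np.float64) ** 2).sum())
                                for p in self.params))
            if total > self.clip_norm:
                scale = DTYPE(self.clip_norm / (total + 1e-12))
                for p in self.params:
                    p.g *= scale
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.beta1) * (p.g - m)
            v += (1.0 - self.beta2) * (p.g * p.g - v)
            p.v -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
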