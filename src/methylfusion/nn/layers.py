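"""Layers with hand-written forward/backward passes.

Conventions
-----------
* Every layer stores its parameters in ``self.params`` and the matching
  gradients in ``self.grads`` (same keys, accumulated by ``backward``).
* Non-trainable state (batch-norm running statistics) lives in
  ``self.buffers``.
* ``forward`` caches whatever ``backward`` needs; a layer must therefore
  be called at most once per training step.
* ``training`` toggles dropout and batch-norm statistics; stochastic
  layers draw from the ``rng`` handed to ``forward``, so a fixed
  generator makes the whole training step reproducible.
"""

from __future__ import annotations

import numpy as np

#: Default parameter dtype.  float32 keeps BLAS fast; gradient-check
#: tests switch to float64 for headroom against finite-difference noise.
DTYPE = np.float32


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], dtype) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    """Base class: parameter/gradient bookkeeping shared by all layers."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k, p in self.params.items():
            self.grads[k] = np.zeros_like(p)

    def forward(self, x, *, training: bool = False, rng: np.random.Generator | None = None):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError


class Embedding(Layer):
    """Lookup table mapping residue indices to dense vectors."""

    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.vocab_size = vocab_size
        self.params["W"] = rng.standard_normal((vocab_size, dim)).astype(DTYPE)
        self.zero_grad()

    def forward(self, idx, *, training=False, rng=None):
        idx = np.asarray(idx)
        if idx.min() < 0 or idx.max() >= self.vocab_size:
            bad = idx[(idx < 0) | (idx >= self.vocab_size)][0]
            raise ValueError(f"embedding index {int(bad)} outside [0, {self.vocab_size})")
        self._idx = idx
        return self.params["W"][idx]

    def backward(self, dy):
        np.add.at(self.grads["W"], self._idx, dy)
        return None  # integer inputs have no gradient


class Dense(Layer):
    """Affine layer ``y = x @ W + b`` (no activation)."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = _glorot(rng, (in_features, out_features), DTYPE)
        self.params["b"] = np.zeros(out_features, dtype=DTYPE)
        self.zero_grad()

    def forward(self, x, *, training=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] += self._x.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, *, training=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout: active only in training mode."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, *, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Conv2d(Layer):
    """2D convolution (stride 1) via im2col + matrix multiply.

    Input layout (N, C, H, W); zero padding ``pad = (pad_h, pad_w)``.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: tuple[int, int],
        pad: tuple[int, int],
        rng: np.random.Generator,
    ):
        super().__init__()
        kh, kw = kernel
        self.kernel = (kh, kw)
        self.pad = pad
        self.in_channels = in_channels
        fan_in = in_channels * kh * kw
        # He-style init suits the ReLU that follows each convolution
        std = np.sqrt(2.0 / fan_in)
        self.params["W"] = (rng.standard_normal((out_channels, fan_in)) * std).astype(DTYPE)
        self.params["b"] = np.zeros(out_channels, dtype=DTYPE)
        self.zero_grad()

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
        n, c, h, w = x.shape
        kh, kw = self.kernel
        ph, pw = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        hout = h + 2 * ph - kh + 1
        wout = w + 2 * pw - kw + 1
        s = xp.strides
        view = np.lib.stride_tricks.as_strided(
            xp,
            shape=(n, c, hout, wout, kh, kw),
            strides=(s[0], s[1], s[2], s[3], s[2], s[3]),
            writeable=False,
        )
        cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(n * hout * wout, c * kh * kw)
        return np.ascontiguousarray(cols), (hout, wout)

    def forward(self, x, *, training=False, rng=None):
        if x.shape[1] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {x.shape[1]}")
        self._xshape = x.shape
        cols, (hout, wout) = self._im2col(x)
        self._cols = cols
        self._hw_out = (hout, wout)
        y = cols @ self.params["W"].T + self.params["b"]
        n = x.shape[0]
        cout = self.params["W"].shape[0]
        return y.reshape(n, hout, wout, cout).transpose(0, 3, 1, 2)

    def backward(self, dy):
        n, cout, hout, wout = dy.shape
        dyf = dy.transpose(0, 2, 3, 1).reshape(-1, cout)
        self.grads["W"] += dyf.T @ self._cols
        self.grads["b"] += dyf.sum(axis=0)

        dcols = dyf @ self.params["W"]  # (n*hout*wout, c*kh*kw)
        _, c, h, w = self._xshape
        kh, kw = self.kernel
        ph, pw = self.pad
        dcols = dcols.reshape(n, hout, wout, c, kh, kw)
        dxp = np.zeros((n, c, h + 2 * ph, w + 2 * pw), dtype=dy.dtype)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i : i + hout, j : j + wout] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, ph : ph + h, pw : pw + w]


class BatchNorm2d(Layer):
    """Per-channel batch normalisation over (N, H, W).

    Training mode normalises by batch statistics and updates running
    estimates (exponential average, unbiased variance); eval mode uses
    the running estimates, making inference deterministic.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(channels, dtype=DTYPE)
        self.params["beta"] = np.zeros(channels, dtype=DTYPE)
        self.buffers["running_mean"] = np.zeros(channels, dtype=DTYPE)
        self.buffers["running_var"] = np.ones(channels, dtype=DTYPE)
        self.zero_grad()

    def forward(self, x, *, training=False, rng=None):
        gamma = self.params["gamma"][None, :, None, None]
        beta = self.params["beta"][None, :, None, None]
        if training:
            axes = (0, 2, 3)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = x.shape[0] * x.shape[2] * x.shape[3]
            self._m = m
            unbiased = var * m / max(m - 1, 1)
            mom = self.momentum
            self.buffers["running_mean"] = (
                (1 - mom) * self.buffers["running_mean"] + mom * mean
            ).astype(x.dtype)
            self.buffers["running_var"] = (
                (1 - mom) * self.buffers["running_var"] + mom * unbiased
            ).astype(x.dtype)
            self._inv_std = 1.0 / np.sqrt(var + self.eps)
            self._xhat = (x - mean[None, :, None, None]) * self._inv_std[None, :, None, None]
            self._training = True
            return gamma * self._xhat + beta
        self._training = False
        inv = 1.0 / np.sqrt(self.buffers["running_var"] + self.eps)
        self._inv_std = inv
        return gamma * ((x - self.buffers["running_mean"][None, :, None, None])
                        * inv[None, :, None, None]) + beta

    def backward(self, dy):
        gamma = self.params["gamma"][None, :, None, None]
        if not self._training:
            return dy * gamma * self._inv_std[None, :, None, None]
        axes = (0, 2, 3)
        xhat = self._xhat
        self.grads["gamma"] += (dy * xhat).sum(axis=axes)
        self.grads["beta"] += dy.sum(axis=axes)
        dxhat = dy * gamma
        m = self._m
        sum_dxhat = dxhat.sum(axis=axes, keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=axes, keepdims=True)
        inv_std = self._inv_std[None, :, None, None]
        return (inv_std / m) * (m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class LSTM(Layer):
    """Single LSTM layer over a full sequence.

    Input (N, T, input_size) → output (N, T, hidden) of hidden states.
    Gate layout in the fused weight matrices is [input, forget, cell,
    output]; the forget-gate bias starts at 1 (the usual remedy against
    early vanishing of the cell state).
    """

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        h = hidden_size
        self.hidden_size = h
        self.params["Wx"] = _glorot(rng, (input_size, 4 * h), DTYPE)
        self.params["Wh"] = _glorot(rng, (h, 4 * h), DTYPE)
        b = np.zeros(4 * h, dtype=DTYPE)
        b[h : 2 * h] = 1.0
        self.params["b"] = b
        self.zero_grad()

    def forward(self, x, *, training=False, rng=None):
        n, t, _ = x.shape
        h = self.hidden_size
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        hs = np.zeros((n, t, h), dtype=x.dtype)
        self._cache = []
        h_prev = np.zeros((n, h), dtype=x.dtype)
        c_prev = np.zeros((n, h), dtype=x.dtype)
        for step in range(t):
            a = x[:, step] @ Wx + h_prev @ Wh + b
            i = _sigmoid(a[:, :h])
            f = _sigmoid(a[:, h : 2 * h])
            g = np.tanh(a[:, 2 * h : 3 * h])
            o = _sigmoid(a[:, 3 * h :])
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_new = o * tc
            hs[:, step] = h_new
            self._cache.append((x[:, step], h_prev, c_prev, i, f, g, o, tc))
            h_prev, c_prev = h_new, c
        return hs

    def backward(self, dhs):
        n, t, h = dhs.shape
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dx = np.zeros((n, t, Wx.shape[0]), dtype=dhs.dtype)
        dh_next = np.zeros((n, h), dtype=dhs.dtype)
        dc_next = np.zeros((n, h), dtype=dhs.dtype)
        for step in reversed(range(t)):
            x_t, h_prev, c_prev, i, f, g, o, tc = self._cache[step]
            dh = dhs[:, step] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            da = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.grads["Wx"] += x_t.T @ da
            self.grads["Wh"] += h_prev.T @ da
            self.grads["b"] += da.sum(axis=0)
            dx[:, step] = da @ Wx.T
            dh_next = da @ Wh.T
            dc_next = dc * f
        return dx
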