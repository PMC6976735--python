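"""Minimal CPU neural-network layers with explicit backpropagation.

Everything the conditional GAN needs — strided convolution, transposed
convolution, batch normalization, LeakyReLU/ReLU/Tanh, binary cross-entropy
with logits, Adam and He initialization — built directly on numpy arrays of
shape (N, C, H, W). Layers cache their forward inputs; ``backward`` returns
the input gradient and accumulates parameter gradients in ``grads``.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# convolution primitives (im2col / col2im)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    N, C, H, W = xp.shape
    ho = (H - kh) // stride + 1
    wo = (W - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, ho, wo, kh, kw)
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(N, C * kh * kw, ho * wo)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols: np.ndarray, in_hw, kh, kw, stride, pad, ho, wo):
    N = dcols.shape[0]
    C = dcols.shape[1] // (kh * kw)
    H, W = in_hw
    dxp = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(N, C, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += d[
                :, :, i, j
            ]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


def _conv_fwd(x, W, stride, pad):
    F = W.shape[0]
    cols, ho, wo = _im2col(x, W.shape[2], W.shape[3], stride, pad)
    out = np.matmul(W.reshape(F, -1), cols)  # (N, F, L) via BLAS
    return out.reshape(x.shape[0], F, ho, wo), cols, ho, wo


def _conv_dw(dout, cols, wshape):
    F = wshape[0]
    d = dout.reshape(dout.shape[0], F, -1)
    return np.matmul(d, cols.transpose(0, 2, 1)).sum(axis=0).reshape(wshape)


def _conv_dx(dout, W, in_hw, stride, pad):
    F = W.shape[0]
    n, _, ho, wo = dout.shape
    dcols = np.matmul(W.reshape(F, -1).T, dout.reshape(n, F, -1))
    return _col2im(dcols, in_hw, W.shape[2], W.shape[3], stride, pad, ho, wo)


DTYPE = np.float32  # training precision; float64 available per-layer for checks


def he_init(rng: np.random.Generator, shape, fan_in: int, dtype=None) -> np.ndarray:
    """He (Kaiming) normal initialization; biases are initialized to zero."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(dtype or DTYPE)


class Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError

    def zero_grad(self):
        for k in self.grads:
            self.grads[k][...] = 0.0


class Conv2d(Layer):
    """k x k convolution, ``stride`` and symmetric zero ``pad``."""

    def __init__(self, cin, cout, k=4, stride=2, pad=1, rng=None, dtype=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        dtype = dtype or DTYPE
        self.stride, self.pad = stride, pad
        self.params = {
            "W": he_init(rng, (cout, cin, k, k), cin * k * k, dtype),
            "b": np.zeros(cout, dtype=dtype),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train=True):
        out, cols, ho, wo = _conv_fwd(x, self.params["W"], self.stride, self.pad)
        self._cache = (cols, x.shape[2:])
        return out + self.params["b"].reshape(1, -1, 1, 1)

    def backward(self, dout):
        cols, in_hw = self._cache
        self.grads["W"] += _conv_dw(dout, cols, self.params["W"].shape)
        self.grads["b"] += dout.sum(axis=(0, 2, 3))
        return _conv_dx(dout, self.params["W"], in_hw, self.stride, self.pad)


class ConvTranspose2d(Layer):
    """Transposed convolution, the adjoint of Conv2d with the same k/stride/pad.

    With k=4, stride=2, pad=1 it exactly doubles the spatial size.
    """

    def __init__(self, cin, cout, k=4, stride=2, pad=1, rng=None, dtype=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        dtype = dtype or DTYPE
        self.stride, self.pad, self.k = stride, pad, k
        # stored in the adjoint-conv orientation: (cin, cout, k, k)
        self.params = {
            "W": he_init(rng, (cin, cout, k, k), cin * k * k, dtype),
            "b": np.zeros(cout, dtype=dtype),
        }
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}

    def _out_hw(self, h, w):
        return (
            (h - 1) * self.stride - 2 * self.pad + self.k,
            (w - 1) * self.stride - 2 * self.pad + self.k,
        )

    def forward(self, x, train=True):
        out_hw = self._out_hw(*x.shape[2:])
        out = _conv_dx(x, self.params["W"], out_hw, self.stride, self.pad)
        self._cache = (x, out_hw)
        return out + self.params["b"].reshape(1, -1, 1, 1)

    def backward(self, dout):
        x, _ = self._cache
        dx, cols, _, _ = _conv_fwd(dout, self.params["W"], self.stride, self.pad)
        self.grads["W"] += _conv_dw(x, cols, self.params["W"].shape)
        self.grads["b"] += dout.sum(axis=(0, 2, 3))
        return dx


class BatchNorm2d(Layer):
    def __init__(self, c, momentum=0.1, eps=1e-5, dtype=None):
        super().__init__()
        dtype = dtype or DTYPE
        self.eps, self.momentum = eps, momentum
        self.params = {"gamma": np.ones(c, dtype=dtype), "beta": np.zeros(c, dtype=dtype)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(1, -1, 1, 1)) / std.reshape(1, -1, 1, 1)
        self._cache = (xhat, std)
        return self.params["gamma"].reshape(1, -1, 1, 1) * xhat + self.params[
            "beta"
        ].reshape(1, -1, 1, 1)

    def backward(self, dout):
        xhat, std = self._cache
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.grads["gamma"] += (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += dout.sum(axis=(0, 2, 3))
        g = self.params["gamma"].reshape(1, -1, 1, 1)
        dxhat = dout * g
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) / std.reshape(1, -1, 1, 1)
        return dx


class LeakyReLU(Layer):
    def __init__(self, slope=0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.slope * dout)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(slope=0.0)


class Tanh(Layer):
    def forward(self, x, train=True):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout):
        return dout * (1.0 - self._y**2)


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def param_layers(self):
        return [l for l in self.layers if getattr(l, "params", None)]

    def zero_grad(self):
        for l in self.param_layers():
            l.zero_grad()


def bce_with_logits(logits: np.ndarray, target: float):
    """Mean binary cross-entropy on sigmoid scores; returns (loss, dlogits).

    Numerically stable: loss_i = max(z,0) - z*t + log(1 + exp(-|z|)).
    """
    z = np.asarray(logits, dtype=float)
    if not np.all(np.isfinite(z)):
        raise FloatingPointError("non-finite discriminator scores")
    loss = np.maximum(z, 0) - z * target + np.log1p(np.exp(-np.abs(z)))
    dz = (1.0 / (1.0 + np.exp(-z)) - target) / z.size
    return float(loss.mean()), dz


class Adam:
    def __init__(self, layers, lr=2e-4, beta1=0.5, beta2=0.999, eps=1e-8):
        self.layers = [l for l in layers if getattr(l, "params", None)]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def zero_grad(self):
        for l in self.layers:
            l.zero_grad()

    def step(self):
        self.t += 1
        c1 = 1 - self.b1**self.t
        c2 = 1 - self.b2**self.t
        for l, m, v in zip(self.layers, self.m, self.v):
            for k, p in l.params.items():
                g = l.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g**2
                p -= self.lr * (m[k] / c1) / (np.sqrt(v[k] / c2) + self.eps)
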