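"""Minimal CNN building blocks (forward + backprop) on numpy.

Implements exactly the operations the segmentation network needs: 2D
convolution (stride 1, configurable zero-padding), batch normalization,
ReLU, 2x2 max pooling, 2x2 stride-2 transpose convolution, channel
concatenation, fused sigmoid/softmax cross-entropy losses and the Adam
optimizer.  Convolutions are computed as im2col matrix products; the
gradient with respect to the input is itself a convolution with the
180-degree-rotated, channel-transposed kernel, so the same im2col path
serves forward and backward.

All layers follow the same contract: ``forward(x, training)`` caches what
backward needs, ``backward(gy)`` returns the input gradient and fills
``grads`` for every entry of ``params``.  Gradient correctness is verified
against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(B, C, H, W) -> (B*Ho*Wo, C*k*k) patch matrix for stride-1 conv."""
    if pad > 0:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    b, c, ho, wo = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * ho * wo, c * k * k)
    return np.ascontiguousarray(cols), (ho, wo)


def _conv(x: np.ndarray, weight: np.ndarray, pad: int) -> np.ndarray:
    """Stride-1 cross-correlation of x (B,C,H,W) with weight (O,C,k,k)."""
    o, c, k, _ = weight.shape
    cols, (ho, wo) = _im2col(x, k, pad)
    y = cols @ weight.reshape(o, c * k * k).T
    return y.reshape(x.shape[0], ho, wo, o).transpose(0, 3, 1, 2)


class Layer:
    def __init__(self):
        self.params: dict = {}
        self.grads: dict = {}

    def forward(self, x, training=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution, stride 1, zero padding (pad=1 keeps size for k=3)."""

    def __init__(self, in_c, out_c, k=3, pad=1, rng=None, dtype=np.float32,
                 bias=True):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.k, self.pad, self.in_c, self.out_c = k, pad, in_c, out_c
        fan_in = in_c * k * k
        self.params["W"] = (rng.standard_normal((out_c, in_c, k, k))
                            * np.sqrt(2.0 / fan_in)).astype(dtype)
        if bias:
            self.params["b"] = np.zeros(out_c, dtype=dtype)

    def forward(self, x, training=False):
        self._x = x if training else None
        y = _conv(x, self.params["W"], self.pad)
        if "b" in self.params:
            y += self.params["b"][None, :, None, None]
        return y

    def backward(self, gy):
        x, k, pad = self._x, self.k, self.pad
        o = self.out_c
        cols, _ = _im2col(x, k, pad)
        gy_r = gy.transpose(0, 2, 3, 1).reshape(-1, o)
        self.grads["W"] = (gy_r.T @ cols).reshape(self.params["W"].shape)
        if "b" in self.params:
            self.grads["b"] = gy_r.sum(axis=0)
        w_flip = self.params["W"][:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        return _conv(gy, np.ascontiguousarray(w_flip), k - 1 - pad)


class BatchNorm2d(Layer):
    def __init__(self, c, momentum=0.1, eps=1e-5, dtype=np.float32):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(c, dtype=dtype)
        self.params["beta"] = np.zeros(c, dtype=dtype)
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        if training:
            self._cache = (xhat, invstd)
        return self.params["gamma"][None, :, None, None] * xhat \
            + self.params["beta"][None, :, None, None]

    def backward(self, gy):
        xhat, invstd = self._cache
        n = gy.shape[0] * gy.shape[2] * gy.shape[3]
        self.grads["gamma"] = (gy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = gy.sum(axis=(0, 2, 3))
        g = self.params["gamma"]
        sum_gy = gy.sum(axis=(0, 2, 3), keepdims=False)[None, :, None, None]
        sum_gy_xhat = (gy * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        gx = (g * invstd)[None, :, None, None] / n * (
            n * gy - sum_gy - xhat * sum_gy_xhat
        )
        return gx


class ReLU(Layer):
    def forward(self, x, training=False):
        if training:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, gy):
        return gy * self._mask


class MaxPool2x2(Layer):
    def forward(self, x, training=False):
        b, c, h, w = x.shape
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2)
        flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h // 2, w // 2, 4)
        if training:
            self._idx = flat.argmax(axis=-1)
            self._in_shape = x.shape
        return flat.max(axis=-1)

    def backward(self, gy):
        b, c, h, w = self._in_shape
        flat = np.zeros((b, c, h // 2, w // 2, 4), dtype=gy.dtype)
        np.put_along_axis(flat, self._idx[..., None], gy[..., None], axis=-1)
        xr = flat.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return xr.reshape(b, c, h, w)


class ConvTranspose2x2(Layer):
    """2x2 transpose convolution with stride 2 (doubles the spatial size)."""

    def __init__(self, in_c, out_c, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_c, self.out_c = in_c, out_c
        self.params["W"] = (rng.standard_normal((in_c, out_c, 2, 2))
                            * np.sqrt(2.0 / in_c)).astype(dtype)
        self.params["b"] = np.zeros(out_c, dtype=dtype)

    def forward(self, x, training=False):
        if training:
            self._x = x
        b, c, h, w = x.shape
        # y[b,o,2i+p,2j+q] = sum_c x[b,c,i,j] W[c,o,p,q]  (no overlap: k = stride)
        t = np.einsum("bchw,copq->bohpwq", x, self.params["W"], optimize=True)
        y = t.reshape(b, self.out_c, 2 * h, 2 * w)
        return y + self.params["b"][None, :, None, None]

    def backward(self, gy):
        x = self._x
        b, c, h, w = x.shape
        g = gy.reshape(b, self.out_c, h, 2, w, 2)
        self.grads["W"] = np.einsum("bchw,bohpwq->copq", x, g, optimize=True)
        self.grads["b"] = gy.sum(axis=(0, 2, 3))
        return np.einsum("bohpwq,copq->bchw", g, self.params["W"], optimize=True)


# ---------------------------------------------------------------------------
# losses (fused with the final nonlinearity for numerical stability)


def sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z, axis=1):
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def bce_with_logits(logits, target):
    """Mean binary cross-entropy over all pixels; returns (loss, grad)."""
    z = logits
    t = target.astype(z.dtype)
    loss = np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z))))
    grad = (sigmoid(z) - t) / z.size
    return float(loss), grad.astype(z.dtype)


def softmax_ce_with_logits(logits, target, relu_first=False, eps=1e-12):
    """Mean categorical cross-entropy; target is an integer class map.

    With ``relu_first`` the logits pass through ReLU before the softmax
    (the head used by the multiclass model); the gradient is masked
    accordingly.
    """
    z = np.maximum(logits, 0) if relu_first else logits
    p = softmax(z, axis=1)
    b, k, h, w = p.shape
    onehot = np.zeros_like(p)
    idx = target.astype(np.int64)
    np.put_along_axis(onehot, idx[:, None, :, :], 1.0, axis=1)
    n = b * h * w
    loss = -np.sum(onehot * np.log(np.maximum(p, eps))) / n
    grad = (p - onehot) / n
    if relu_first:
        grad = grad * (logits > 0)
    return float(loss), grad.astype(logits.dtype)


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    def __init__(self, layers, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for l, m, v in zip(self.layers, self.m, self.v):
            for k, p in l.params.items():
                g = l.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                p -= self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)


def numerical_gradient(f, x, eps=1e-5):
    """Central-difference gradient of scalar f at x (test oracle)."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
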