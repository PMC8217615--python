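"""Trainable layers with explicit forward/backward passes (float32 NCHW).

Each layer caches what its backward pass needs during ``forward`` and fills
``self.grads`` (parallel to ``self.params``) during ``backward``.  Parameter
names are local; composites prefix them to build the checkpoint namespace.
"""

from __future__ import annotations

import numpy as np

from .functional import col2im, im2col


class Layer:
    """Base: ``params``/``grads`` are dicts of name -> array (same keys)."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}  # non-trainable state (BN stats)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """k x k cross-correlation, He-normal init, no bias (a BatchNorm follows)."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        k: int,
        stride: int = 1,
        pad: int = 0,
        *,
        rng: np.random.Generator,
        input_grad: bool = True,
    ):
        super().__init__()
        std = np.sqrt(2.0 / (in_ch * k * k))
        self.params["weight"] = rng.normal(0.0, std, (out_ch, in_ch, k, k)).astype(np.float32)
        self.k, self.stride, self.pad = k, stride, pad
        self.input_grad = input_grad  # first layer can skip the input gradient

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x_shape = x.shape
        col, (ho, wo) = im2col(x, self.k, self.stride, self.pad)
        self._col = col if training else None
        w = self.params["weight"]
        out = w.reshape(w.shape[0], -1) @ col.reshape(col.shape[0], -1)
        return out.reshape(w.shape[0], x.shape[0], ho, wo).transpose(1, 0, 2, 3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        w = self.params["weight"]
        o = w.shape[0]
        dmat = dout.transpose(1, 0, 2, 3).reshape(o, -1)
        colmat = self._col.reshape(self._col.shape[0], -1)
        self.grads["weight"] = (dmat @ colmat.T).reshape(w.shape)
        if not self.input_grad:
            self._col = None
            return np.zeros(self._x_shape, dtype=dout.dtype)
        dcol = (w.reshape(o, -1).T @ dmat).reshape(self._col.shape)
        self._col = None
        return col2im(dcol, self._x_shape, self.k, self.stride, self.pad)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics (momentum 0.1)."""

    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.params["weight"] = np.ones(ch, dtype=np.float32)
        self.params["bias"] = np.zeros(ch, dtype=np.float32)
        self.buffers["running_mean"] = np.zeros(ch, dtype=np.float32)
        self.buffers["running_var"] = np.ones(ch, dtype=np.float32)
        self.eps, self.momentum = eps, momentum

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            n = x.shape[0] * x.shape[2] * x.shape[3]
            unbiased = var * n / max(n - 1, 1)
            rm, rv = self.buffers["running_mean"], self.buffers["running_var"]
            rm += (self.momentum * (mean - rm)).astype(rm.dtype)
            rv += (self.momentum * (unbiased - rv)).astype(rv.dtype)
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        self._std = np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) / self._std[:, None, None]
        self._xhat = xhat if training else None
        return self.params["weight"][:, None, None] * xhat + self.params["bias"][:, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat = self._xhat
        self._xhat = None
        self.grads["weight"] = (dout * xhat).sum(axis=(0, 2, 3)).astype(self.params["weight"].dtype)
        self.grads["bias"] = dout.sum(axis=(0, 2, 3)).astype(self.params["bias"].dtype)
        g = self.params["weight"][:, None, None]
        dxhat = dout * g
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) / self._std[:, None, None]
        return dx.astype(dout.dtype)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, np.float32(0))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, np.float32(0))


class MaxPool2d(Layer):
    """k x k max pooling; backward routes gradients to the argmax tap."""

    def __init__(self, k: int = 3, stride: int = 2, pad: int = 1):
        super().__init__()
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x_shape = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2), constant_values=-np.inf)
        self._xp_shape = xp.shape
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        win = win[:, :, :: self.stride, :: self.stride]
        n, c, ho, wo, _, _ = win.shape
        flat = win.reshape(n, c, ho, wo, -1)
        self._arg = flat.argmax(axis=-1)
        return flat.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, hp, wp = self._xp_shape
        ho, wo = dout.shape[2], dout.shape[3]
        ay, ax = np.divmod(self._arg, self.k)
        oy = np.arange(ho)[None, None, :, None] * self.stride
        ox = np.arange(wo)[None, None, None, :] * self.stride
        rows = oy + ay
        cols = ox + ax
        plane = np.arange(n * c)[:, None] * (hp * wp)
        flat_idx = (plane + (rows * wp + cols).reshape(n * c, -1)).ravel()
        dxp = np.bincount(flat_idx, weights=dout.ravel().astype(np.float64), minlength=n * c * hp * wp)
        dxp = dxp.reshape(self._xp_shape).astype(dout.dtype)
        p = self.pad
        return dxp[:, :, p : hp - p, p : wp - p] if p else dxp


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        h, w = self._hw
        return np.broadcast_to(dout[:, :, None, None] / np.float32(h * w), dout.shape + (h, w)).astype(dout.dtype)


class Linear(Layer):
    """Fully connected head; uniform(-1/sqrt(fan_in), +) init for weight and bias."""

    def __init__(self, in_f: int, out_f: int, *, rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / np.sqrt(in_f)
        self.params["weight"] = rng.uniform(-bound, bound, (out_f, in_f)).astype(np.float32)
        self.params["bias"] = rng.uniform(-bound, bound, out_f).astype(np.float32)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["weight"].T + self.params["bias"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["weight"] = dout.T @ self._x
        self.grads["bias"] = dout.sum(axis=0)
        return dout @ self.params["weight"]


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean 2-class (or k-class) cross-entropy on unnormalized scores.

    Returns (loss, dlogits) where dlogits is the gradient of the mean loss.
    """
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = float(-np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(np.float32)
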