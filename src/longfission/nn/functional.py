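"""Low-level array operations: valid cross-correlation and im2col/col2im.

The convolution convention is cross-correlation (no kernel flip): the kernel
sweeps the image left-to-right, top-to-bottom at a constant stride, and each
output pixel is the inner product of the kernel with the receptive region.
Output spatial dims are ``floor((input - kernel) / stride) + 1`` per axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ConvSpec:
    """A kernel (2-D, or (C, k, k) for multi-channel input) plus its stride."""

    weights: np.ndarray
    stride: int = 1

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim not in (2, 3):
            raise ValueError("kernel must be 2-D or (channels, k, k)")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        object.__setattr__(self, "weights", w)


def convolve2d_valid(image: np.ndarray, conv: ConvSpec) -> np.ndarray:
    """Valid cross-correlation of ``image`` with the kernel in ``conv``.

    ``image`` is 2-D (or (C, H, W) matching a (C, k, k) kernel, summing over
    channels).  Raises if the kernel does not fit inside the image.
    """
    img = np.asarray(image, dtype=np.float64)
    w = conv.weights
    if img.ndim == 2 and w.ndim == 2:
        img = img[None]
        w = w[None]
    elif not (img.ndim == 3 and w.ndim == 3 and img.shape[0] == w.shape[0]):
        raise ValueError("image/kernel channel mismatch")
    _, h, wid = img.shape
    _, kh, kw = w.shape
    if kh > h or kw > wid:
        raise ValueError(f"kernel {kh}x{kw} larger than image {h}x{wid}")
    s = conv.stride
    win = np.lib.stride_tricks.sliding_window_view(img, (kh, kw), axis=(1, 2))
    win = win[:, ::s, ::s]  # (C, Ho, Wo, kh, kw)
    return np.einsum("chwij,cij->hw", win, w)


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Unfold NCHW input into a (C*k*k, N, Ho, Wo) column tensor.

    Layout groups the k*k taps contiguously per channel, matching a
    (O, C*k*k) reshaped weight matrix for a single GEMM.
    """
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, h, w = x.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    col = np.empty((c * k * k, n, ho, wo), dtype=x.dtype)
    xt = x.transpose(1, 0, 2, 3)
    idx = 0
    for ci in range(c):
        for ky in range(k):
            for kx in range(k):
                col[idx] = xt[ci, :, ky : ky + stride * ho : stride, kx : kx + stride * wo : stride]
                idx += 1
    return col, (ho, wo)


def col2im(
    dcol: np.ndarray,
    x_shape: tuple[int, int, int, int],
    k: int,
    stride: int,
    pad: int,
) -> np.ndarray:
    """Fold a (C*k*k, N, Ho, Wo) gradient back onto the NCHW input (adjoint of im2col)."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    dxp = np.zeros((n, c, hp, wp), dtype=dcol.dtype)
    idx = 0
    for ci in range(c):
        for ky in range(k):
            for kx in range(k):
                dxp[:, ci, ky : ky + stride * ho : stride, kx : kx + stride * wo : stride] += dcol[idx]
                idx += 1
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp
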