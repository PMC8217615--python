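"""Independent brute-force oracles used to check the library's fast paths."""

from __future__ import annotations

import numpy as np


def brute_conv(image: np.ndarray, kernel: np.ndarray, stride: int = 1) -> np.ndarray:
    """Nested-loop valid cross-correlation (single channel)."""
    h, w = image.shape
    kh, kw = kernel.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    out = np.zeros((ho, wo), dtype=np.float64)
    for i in range(ho):
        for j in range(wo):
            acc = 0.0
            for a in range(kh):
                for b in range(kw):
                    acc += image[i * stride + a, j * stride + b] * kernel[a, b]
            out[i, j] = acc
    return out


def flood_fill_components(binary: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Iterative flood-fill labeling; ids in raster-scan order of first pixel."""
    binary = np.asarray(binary, dtype=bool)
    labels = np.zeros(binary.shape, dtype=np.int64)
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    next_id = 0
    for r0 in range(binary.shape[0]):
        for c0 in range(binary.shape[1]):
            if binary[r0, c0] and labels[r0, c0] == 0:
                next_id += 1
                stack = [(r0, c0)]
                labels[r0, c0] = next_id
                while stack:
                    r, c = stack.pop()
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if (
                            0 <= rr < binary.shape[0]
                            and 0 <= cc < binary.shape[1]
                            and binary[rr, cc]
                            and labels[rr, cc] == 0
                        ):
                            labels[rr, cc] = next_id
                            stack.append((rr, cc))
    return labels


def pair_tally(labels, preds) -> np.ndarray:
    """Loop-based 2x2 confusion tally."""
    counts = np.zeros((2, 2), dtype=np.int64)
    for y, p in zip(labels, preds):
        counts[y][p] += 1
    return counts


def same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """Do two labelings induce the same partition (up to label renaming)?"""
    a, b = np.asarray(a).ravel(), np.asarray(b).ravel()
    fwd: dict[int, int] = {}
    rev: dict[int, int] = {}
    for x, y in zip(a, b):
        if (x == 0) != (y == 0):
            return False
        if x == 0:
            continue
        if fwd.setdefault(x, y) != y or rev.setdefault(y, x) != x:
            return False
    return True
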