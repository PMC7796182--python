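"""Gray-level co-occurrence matrix (GLCM) texture statistics.

Gray values are quantized to ``levels`` bins (64 by default) and ordered
pixel pairs at a fixed displacement ``(drow, dcol)`` are counted into
``C(i, j)``; the matrix is normalized to probabilities ``P = C / N`` where
``N`` is the total pair count, so its entries sum to 1.  The default
displacement ``(0, 1)`` is the horizontal 0-degree direction; 45/90/135
degrees are available through :func:`offset_for_angle`.

Six statistics summarize the matrix, in this order: energy, contrast,
correlation, sum entropy, entropy, inverse difference moment.  Entropies use
the natural logarithm; a texture-free (single-entry) matrix has entropy 0.
"""

from __future__ import annotations

import numpy as np

__all__ = ["quantize_gray", "offset_for_angle", "glcm", "glcm_stats",
           "GLCM_STAT_NAMES"]

GLCM_STAT_NAMES = ("energy", "contrast", "correlation", "sum_entropy",
                   "entropy", "inverse_difference_moment")

_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def quantize_gray(gray: np.ndarray, levels: int) -> np.ndarray:
    """Quantize 8-bit gray values into ``levels`` equal-width bins."""
    if levels < 2:
        raise ValueError("levels must be >= 2")
    g = np.asarray(gray)
    return (g.astype(np.intp) * levels) // 256


def offset_for_angle(angle_deg: int, distance: int = 1) -> tuple[int, int]:
    """(drow, dcol) displacement for one of the four standard directions."""
    if angle_deg not in _ANGLE_OFFSETS:
        raise ValueError("angle must be one of 0, 45, 90, 135")
    dr, dc = _ANGLE_OFFSETS[angle_deg]
    return dr * distance, dc * distance


def glcm(gray: np.ndarray, levels: int = 64,
         offset: tuple[int, int] = (0, 1)) -> np.ndarray:
    """Normalized co-occurrence matrix of ordered pairs at ``offset``."""
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("glcm expects a single-channel image")
    dr, dc = offset
    if dr == 0 and dc == 0:
        raise ValueError("offset must be nonzero")
    h, w = gray.shape
    r0, r1 = max(0, -dr), h - max(0, dr)
    c0, c1 = max(0, -dc), w - max(0, dc)
    if r1 <= r0 or c1 <= c0:
        raise ValueError("image too small: no pixel pairs at this offset")
    q = quantize_gray(gray, levels)
    a = q[r0:r1, c0:c1].ravel()
    b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
    counts = np.zeros((levels, levels), dtype=np.float64)
    np.add.at(counts, (a, b), 1.0)
    return counts / counts.sum()


def glcm_stats(P: np.ndarray) -> np.ndarray:
    """The six co-occurrence statistics (see module docstring for order)."""
    P = np.asarray(P, dtype=np.float64)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("expected a square co-occurrence matrix")
    g = P.shape[0]
    i = np.arange(g, dtype=np.float64)
    pi = P.sum(axis=1)          # marginal over rows (first pixel)
    pj = P.sum(axis=0)
    energy = float((P ** 2).sum())
    diff2 = (i[:, None] - i[None, :]) ** 2
    contrast = float((diff2 * P).sum())
    mu_i = float(i @ pi)
    mu_j = float(i @ pj)
    var_i = float(((i - mu_i) ** 2) @ pi)
    var_j = float(((i - mu_j) ** 2) @ pj)
    if var_i > 0 and var_j > 0:
        cov = float((((i - mu_i)[:, None] * (i - mu_j)[None, :]) * P).sum())
        correlation = cov / np.sqrt(var_i * var_j)
    else:
        correlation = 0.0       # zero-variance guard
    # p_{x+y}(k), k = i + j in 0 .. 2G-2
    ii, jj = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
    psum = np.bincount((ii + jj).ravel(), weights=P.ravel(), minlength=2 * g - 1)
    sum_entropy = float(-(psum[psum > 0] * np.log(psum[psum > 0])).sum())
    nz = P[P > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    idm = float((P / (1.0 + diff2)).sum())
    return np.array([energy, contrast, correlation, sum_entropy, entropy, idm])
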