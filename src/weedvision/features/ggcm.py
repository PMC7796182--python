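"""Gray level-gradient co-occurrence matrix (GGCM) texture statistics.

The GGCM couples the gray value of each pixel with its local gradient
magnitude: a Sobel gradient plane is computed from the gray image, both
planes are quantized (64 levels each by default, the gradient after
normalization by its maximum), and the joint histogram ``H(g, s)`` over
(gray level, gradient level) pairs is accumulated over all pixels.

Fifteen statistics summarize the matrix — the classical gray-gradient set:
small/large gradient dominance, gray and gradient distribution
non-uniformity, energy, gray and gradient mean, gray and gradient mean
square error, correlation, gray / gradient / mixed entropy, inertia and
inverse difference (deficit) moment.  Entropies use the natural logarithm.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .glcm import quantize_gray

__all__ = ["gradient_magnitude", "quantize_gradient", "ggcm", "ggcm_stats",
           "GGCM_STAT_NAMES"]

GGCM_STAT_NAMES = (
    "small_gradient_dominance", "large_gradient_dominance",
    "gray_nonuniformity", "gradient_nonuniformity", "energy",
    "gray_mean", "gradient_mean", "gray_mse", "gradient_mse",
    "correlation", "gray_entropy", "gradient_entropy", "mixed_entropy",
    "inertia", "inverse_difference_moment",
)


def gradient_magnitude(gray: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude (reflect boundary, unnormalized kernels)."""
    f = np.asarray(gray, dtype=np.float64)
    if f.ndim != 2:
        raise ValueError("gradient_magnitude expects a single-channel image")
    gx = ndi.sobel(f, axis=1, mode="reflect")
    gy = ndi.sobel(f, axis=0, mode="reflect")
    return np.hypot(gx, gy)


def quantize_gradient(grad: np.ndarray, levels: int) -> np.ndarray:
    """Quantize a nonnegative gradient plane to ``levels`` bins (max-normalized)."""
    if levels < 2:
        raise ValueError("levels must be >= 2")
    grad = np.asarray(grad, dtype=np.float64)
    gmax = grad.max()
    if gmax <= 0:
        return np.zeros(grad.shape, dtype=np.intp)
    q = (grad / gmax * levels).astype(np.intp)
    return np.minimum(q, levels - 1)


def ggcm(gray: np.ndarray, gray_levels: int = 64,
         grad_levels: int = 64) -> np.ndarray:
    """Joint (gray level, gradient level) count matrix of shape (Gg, Gs)."""
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("ggcm expects a single-channel image")
    if gray.shape[0] < 3 or gray.shape[1] < 3:
        raise ValueError("image must be at least 3x3 for the gradient operator")
    g = quantize_gray(gray, gray_levels).ravel()
    s = quantize_gradient(gradient_magnitude(gray), grad_levels).ravel()
    counts = np.zeros((gray_levels, grad_levels), dtype=np.float64)
    np.add.at(counts, (g, s), 1.0)
    return counts


def ggcm_stats(H: np.ndarray) -> np.ndarray:
    """The fifteen gray-gradient statistics (order in ``GGCM_STAT_NAMES``)."""
    H = np.asarray(H, dtype=np.float64)
    if H.ndim != 2:
        raise ValueError("expected a 2-D joint histogram")
    total = H.sum()
    if total <= 0:
        raise ValueError("empty histogram")
    gg, gs = H.shape
    g = np.arange(gg, dtype=np.float64)
    s = np.arange(gs, dtype=np.float64)
    P = H / total
    pg = P.sum(axis=1)           # gray marginal
    ps = P.sum(axis=0)           # gradient marginal
    row_sums = H.sum(axis=1)
    col_sums = H.sum(axis=0)

    small_grad = float((H / (s[None, :] + 1.0) ** 2).sum() / total)
    large_grad = float((H * s[None, :] ** 2).sum() / total)
    gray_nonunif = float((row_sums ** 2).sum() / total)
    grad_nonunif = float((col_sums ** 2).sum() / total)
    energy = float((P ** 2).sum())
    gray_mean = float(g @ pg)
    grad_mean = float(s @ ps)
    gray_mse = float(np.sqrt(((g - gray_mean) ** 2) @ pg))
    grad_mse = float(np.sqrt(((s - grad_mean) ** 2) @ ps))
    if gray_mse > 0 and grad_mse > 0:
        cov = float((((g - gray_mean)[:, None] * (s - grad_mean)[None, :]) * P).sum())
        correlation = cov / (gray_mse * grad_mse)
    else:
        correlation = 0.0        # zero-variance guard
    gray_entropy = float(-(pg[pg > 0] * np.log(pg[pg > 0])).sum())
    grad_entropy = float(-(ps[ps > 0] * np.log(ps[ps > 0])).sum())
    nz = P[P > 0]
    mixed_entropy = float(-(nz * np.log(nz)).sum())
    diff2 = (g[:, None] - s[None, :]) ** 2
    inertia = float((diff2 * P).sum())
    idm = float((P / (1.0 + diff2)).sum())
    return np.array([
        small_grad, large_grad, gray_nonunif, grad_nonunif, energy,
        gray_mean, grad_mean, gray_mse, grad_mse, correlation,
        gray_entropy, grad_entropy, mixed_entropy, inertia, idm,
    ])
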