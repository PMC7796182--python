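"""Histogram-of-oriented-gradients shape descriptor.

Standard dense HOG: the image is divided into square cells of ``cell`` pixels,
gradients ([-1, 0, 1] derivative kernels, unsigned orientation over [0, 180))
are binned into 9 orientation bins per cell, and every 2x2 group of adjacent
cells forms a block of 36 values, L2-Hys normalized, with a stride of one
cell.  On an S x S image this yields ``(S/cell - 1)^2 * 36`` dimensions
(324 for S=256, cell=64).
"""

from __future__ import annotations

import numpy as np
from skimage.feature import hog as _sk_hog

__all__ = ["hog_features", "hog_length"]


def hog_length(side: int, cell: int) -> int:
    """Descriptor length for an S x S image with the given cell size."""
    if cell < 1 or cell > side:
        raise ValueError("cell size must be in [1, image side]")
    if side % cell:
        raise ValueError("image side must be divisible by the cell size")
    return (side // cell - 1) ** 2 * 36


def hog_features(gray: np.ndarray, cell: int = 64) -> np.ndarray:
    """HOG descriptor of a square single-channel image."""
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("hog_features expects a single-channel image")
    side = gray.shape[0]
    if gray.shape[1] != side:
        raise ValueError("hog_features expects a square image")
    hog_length(side, cell)  # validates cell vs side
    vec = _sk_hog(
        gray.astype(np.float64),
        orientations=9,
        pixels_per_cell=(cell, cell),
        cells_per_block=(2, 2),
        block_norm="L2-Hys",
        feature_vector=True,
    )
    return np.asarray(vec, dtype=np.float64)
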