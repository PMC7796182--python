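"""Rotation-invariant local binary pattern (LBP) texture features.

An 8-bit code is formed for every interior pixel by comparing it with its
3x3 neighborhood, clockwise from the top-left neighbor (that neighbor is the
most significant bit); a neighbor greater than or equal to the center sets its
bit.  Rotating the image permutes the neighbors circularly, so two rotation
conventions are exposed:

``rotlbp_code``
    the minimum over the 8 circular bit-rotations of the code (e.g. the
    rotations of decimal 125 are 125, 250, 245, 235, 215, 175, 95, 190 and
    the rotation-invariant value is 95);
``riu2_bin``
    the 10-bin "uniform" quantization — codes with at most 2 circular 0/1
    transitions map to their set-bit count (bins 0..8), all others to bin 9.

The per-image descriptor histograms riu2 bins within square cells, giving
``(S/cell)^2 * 10`` dimensions on an ``S x S`` image (160 for S=256, cell=64).
"""

from __future__ import annotations

import numpy as np

__all__ = ["rotate_code", "rotlbp_code", "riu2_bin", "lbp_codes", "rotlbp_features"]

# clockwise from the top-left neighbor; index 0 -> most significant bit
_NEIGHBOR_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
)


def rotate_code(code: int, k: int) -> int:
    """Circularly rotate an 8-bit code left by ``k`` positions."""
    if not 0 <= code <= 255:
        raise ValueError("code must be an 8-bit value")
    k %= 8
    return ((code << k) | (code >> (8 - k))) & 0xFF


def rotlbp_code(code: int) -> int:
    """Minimum over all 8 circular bit-rotations of an 8-bit pattern."""
    return min(rotate_code(code, k) for k in range(8))


def riu2_bin(code: int) -> int:
    """Map an 8-bit pattern to its rotation-invariant uniform bin (0..9).

    Uniform patterns (at most two circular 0<->1 transitions) are binned by
    their number of set bits; all non-uniform patterns share bin 9.
    """
    if not 0 <= code <= 255:
        raise ValueError("code must be an 8-bit value")
    transitions = bin((code ^ rotate_code(code, 1)) & 0xFF).count("1")
    if transitions <= 2:
        return bin(code).count("1")
    return 9


_RIU2_TABLE = np.array([riu2_bin(c) for c in range(256)], dtype=np.uint8)
_MINROT_TABLE = np.array([rotlbp_code(c) for c in range(256)], dtype=np.uint8)


def lbp_codes(gray: np.ndarray) -> np.ndarray:
    """Per-pixel 8-bit LBP codes over the interior of a grayscale image.

    Returns an ``(H-2, W-2)`` uint8 array (border pixels have no full 3x3
    neighborhood and are excluded).  Ties (neighbor equal to center) set the
    bit, so flat regions deterministically yield the all-ones pattern 255.
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("lbp_codes expects a single-channel image")
    if gray.shape[0] < 3 or gray.shape[1] < 3:
        raise ValueError("image must be at least 3x3")
    center = gray[1:-1, 1:-1]
    codes = np.zeros(center.shape, dtype=np.uint8)
    for bit, (dr, dc) in enumerate(_NEIGHBOR_OFFSETS):
        nb = gray[1 + dr:gray.shape[0] - 1 + dr, 1 + dc:gray.shape[1] - 1 + dc]
        codes |= ((nb >= center).astype(np.uint8) << (7 - bit))
    return codes


def rotlbp_features(gray: np.ndarray, cell: int = 64) -> np.ndarray:
    """Cell-wise riu2 histogram descriptor of an ``S x S`` grayscale image.

    The image is divided into ``(S/cell)^2`` square cells; each interior
    pixel's LBP code is quantized to its riu2 bin and counted in its cell's
    10-bin histogram.  Histograms are concatenated row-major, giving
    ``(S/cell)^2 * 10`` values.
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("rotlbp_features expects a single-channel image")
    side = gray.shape[0]
    if gray.shape[1] != side:
        raise ValueError("rotlbp_features expects a square image")
    if cell < 1 or cell > side:
        raise ValueError("cell size must be in [1, image side]")
    if side % cell:
        raise ValueError("image side must be divisible by the cell size")
    n = side // cell
    bins = _RIU2_TABLE[lbp_codes(gray)]
    # absolute coordinates of interior pixels
    rows = np.arange(1, side - 1)[:, None] // cell
    cols = np.arange(1, side - 1)[None, :] // cell
    cell_idx = (rows * n + cols)
    flat = (cell_idx * 10 + bins.astype(np.intp)).ravel()
    hist = np.bincount(flat, minlength=n * n * 10)
    return hist.astype(np.float64)
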