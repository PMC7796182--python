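"""Gabor filter-bank texture descriptor.

A bank of 5 scales x 8 orientations yields 40 complex band-pass responses;
the magnitude of each response is pooled (mean) over a 3x3 grid of sub-blocks,
giving a 360-dimensional descriptor ordered scale-major, then orientation,
then row-major sub-blocks.

Default parameters: wavelengths 4, 4*sqrt(2), 8, 8*sqrt(2), 16 pixels
(a geometric progression of half-octaves), orientations k*pi/8 for k=0..7,
bandwidth 1 octave.  The image is reflect-padded before convolution so a
spatially homogeneous input produces homogeneous responses.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.signal import fftconvolve
from skimage.filters import gabor_kernel

__all__ = ["GABOR_WAVELENGTHS", "gabor_bank", "gabor_features"]

GABOR_WAVELENGTHS = (4.0, 4.0 * math.sqrt(2), 8.0, 8.0 * math.sqrt(2), 16.0)
N_ORIENTATIONS = 8


def gabor_bank(wavelengths=GABOR_WAVELENGTHS, n_orientations=N_ORIENTATIONS):
    """Complex Gabor kernels ordered scale-major, then orientation."""
    kernels = []
    for lam in wavelengths:
        for k in range(n_orientations):
            theta = k * np.pi / n_orientations
            kernels.append(gabor_kernel(frequency=1.0 / lam, theta=theta,
                                        bandwidth=1.0))
    return kernels


def _block_means(mag: np.ndarray, grid: int) -> np.ndarray:
    h, w = mag.shape
    rb = [h * i // grid for i in range(grid + 1)]
    cb = [w * j // grid for j in range(grid + 1)]
    out = np.empty(grid * grid)
    for i in range(grid):
        for j in range(grid):
            out[i * grid + j] = mag[rb[i]:rb[i + 1], cb[j]:cb[j + 1]].mean()
    return out


def gabor_features(gray: np.ndarray, wavelengths=GABOR_WAVELENGTHS,
                   n_orientations: int = N_ORIENTATIONS, grid: int = 3) -> np.ndarray:
    """Pooled Gabor magnitude descriptor (length scales * orientations * grid^2)."""
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2:
        raise ValueError("gabor_features expects a single-channel image")
    kernels = gabor_bank(wavelengths, n_orientations)
    pad = max(max(k.shape) for k in kernels) // 2
    padded = np.pad(gray, pad, mode="reflect")
    feats = []
    for k in kernels:
        resp = fftconvolve(padded, k, mode="same")
        mag = np.abs(resp[pad:pad + gray.shape[0], pad:pad + gray.shape[1]])
        feats.append(_block_means(mag, grid))
    return np.concatenate(feats)
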