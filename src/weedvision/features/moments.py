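"""Hu moment-invariant shape descriptor (eight invariants).

The grayscale image is treated as a 2-D intensity distribution with
``x = column`` and ``y = row``.  Normalized central moments

    eta_pq = mu_pq / mu_00 ** (1 + (p + q) / 2)

feed the seven classical Hu invariants phi_1..phi_7 plus an eighth,

    phi_8 = 2 eta_11 [(eta_30 + eta_12)^2 - (eta_03 + eta_21)^2]
            - 2 (eta_20 - eta_02)(eta_30 + eta_12)(eta_21 + eta_03),

which completes the third-order invariant set.  All eight are invariant to
translation of the content within the frame; phi_1..phi_7 are additionally
scale invariant; phi_8 vanishes for shapes with four-fold mirror symmetry.
"""

from __future__ import annotations

import numpy as np

__all__ = ["central_moments", "normalized_moments", "hu_moments8"]


def central_moments(gray: np.ndarray, order: int = 3) -> np.ndarray:
    """Intensity-weighted central moments mu_pq, p = x-order, q = y-order."""
    f = np.asarray(gray, dtype=np.float64)
    if f.ndim != 2:
        raise ValueError("central_moments expects a single-channel image")
    m00 = f.sum()
    if m00 <= 0:
        raise ValueError("degenerate moments: image has zero total intensity")
    h, w = f.shape
    x = np.arange(w, dtype=np.float64)
    y = np.arange(h, dtype=np.float64)
    xbar = (f.sum(axis=0) @ x) / m00
    ybar = (f.sum(axis=1) @ y) / m00
    dx = x - xbar
    dy = y - ybar
    xp = np.stack([dx ** p for p in range(order + 1)])   # (order+1, W)
    yq = np.stack([dy ** q for q in range(order + 1)])   # (order+1, H)
    # mu[p, q] = sum_yx f(y, x) dx^p dy^q
    return np.einsum("qh,hw,pw->pq", yq, f, xp)


def normalized_moments(gray: np.ndarray) -> np.ndarray:
    """Scale-normalized central moments eta_pq up to order 3."""
    mu = central_moments(gray, order=3)
    eta = np.zeros_like(mu)
    for p in range(4):
        for q in range(4):
            if p + q >= 2:
                eta[p, q] = mu[p, q] / mu[0, 0] ** (1 + (p + q) / 2)
    return eta


def hu_moments8(gray: np.ndarray) -> np.ndarray:
    """The eight Hu moment invariants of a grayscale image."""
    eta = normalized_moments(gray)
    n20, n02, n11 = eta[2, 0], eta[0, 2], eta[1, 1]
    n30, n03 = eta[3, 0], eta[0, 3]
    n21, n12 = eta[2, 1], eta[1, 2]
    a = n30 + n12
    b = n21 + n03
    phi1 = n20 + n02
    phi2 = (n20 - n02) ** 2 + 4 * n11 ** 2
    phi3 = (n30 - 3 * n12) ** 2 + (3 * n21 - n03) ** 2
    phi4 = a ** 2 + b ** 2
    phi5 = (n30 - 3 * n12) * a * (a ** 2 - 3 * b ** 2) \
        + (3 * n21 - n03) * b * (3 * a ** 2 - b ** 2)
    phi6 = (n20 - n02) * (a ** 2 - b ** 2) + 4 * n11 * a * b
    phi7 = (3 * n21 - n03) * a * (a ** 2 - 3 * b ** 2) \
        - (n30 - 3 * n12) * b * (3 * a ** 2 - b ** 2)
    phi8 = 2 * n11 * (a ** 2 - b ** 2) - 2 * (n20 - n02) * a * b
    return np.array([phi1, phi2, phi3, phi4, phi5, phi6, phi7, phi8])
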