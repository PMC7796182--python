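"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain double loops over pixels or matrix
entries, straight from the defining formulas, deliberately sharing no code
with the package.
"""

import math

import numpy as np


# ---------------------------------------------------------------- LBP ------

def rotlbp_bruteforce(code: int) -> int:
    """Min over circular rotations, via string rotation."""
    bits = format(code, "08b")
    return min(int(bits[k:] + bits[:k], 2) for k in range(8))


def riu2_bruteforce(code: int) -> int:
    """riu2 bin via explicit circular transition counting."""
    bits = [(code >> i) & 1 for i in range(8)]
    transitions = sum(bits[i] != bits[(i + 1) % 8] for i in range(8))
    return sum(bits) if transitions <= 2 else 9


# --------------------------------------------------------------- GLCM ------

def glcm_bruteforce(gray, levels, offset):
    """Ordered pair counting by explicit pixel loops."""
    gray = np.asarray(gray)
    dr, dc = offset
    h, w = gray.shape
    C = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                i = (int(gray[r, c]) * levels) // 256
                j = (int(gray[r2, c2]) * levels) // 256
                C[i, j] += 1
    return C / C.sum()


def glcm_stats_bruteforce(P):
    """Energy, contrast, correlation, sum entropy, entropy, IDM by loops."""
    P = np.asarray(P, dtype=float)
    g = P.shape[0]
    energy = contrast = entropy = idm = 0.0
    mu_i = mu_j = 0.0
    psum = np.zeros(2 * g - 1)
    for i in range(g):
        for j in range(g):
            p = P[i, j]
            energy += p * p
            contrast += (i - j) ** 2 * p
            idm += p / (1 + (i - j) ** 2)
            if p > 0:
                entropy -= p * math.log(p)
            mu_i += i * p
            mu_j += j * p
            psum[i + j] += p
    var_i = var_j = cov = 0.0
    for i in range(g):
        for j in range(g):
            p = P[i, j]
            var_i += (i - mu_i) ** 2 * p
            var_j += (j - mu_j) ** 2 * p
            cov += (i - mu_i) * (j - mu_j) * p
    corr = cov / math.sqrt(var_i * var_j) if var_i > 0 and var_j > 0 else 0.0
    sum_entropy = -sum(p * math.log(p) for p in psum if p > 0)
    return np.array([energy, contrast, corr, sum_entropy, entropy, idm])


# --------------------------------------------------------------- GGCM ------

def sobel_magnitude_bruteforce(gray):
    """3x3 Sobel magnitude with symmetric (edge-reflected) padding."""
    g = np.asarray(gray, dtype=float)
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
    ky = kx.T
    pad = np.pad(g, 1, mode="symmetric")
    out = np.zeros_like(g)
    for r in range(g.shape[0]):
        for c in range(g.shape[1]):
            win = pad[r:r + 3, c:c + 3]
            out[r, c] = math.hypot((kx * win).sum(), (ky * win).sum())
    return out


def ggcm_bruteforce(gray, gray_levels, grad_levels):
    """Joint (gray, gradient) histogram by explicit pixel loops."""
    gray = np.asarray(gray)
    grad = sobel_magnitude_bruteforce(gray)
    gmax = grad.max()
    H = np.zeros((gray_levels, grad_levels))
    for r in range(gray.shape[0]):
        for c in range(gray.shape[1]):
            i = (int(gray[r, c]) * gray_levels) // 256
            if gmax > 0:
                j = min(int(grad[r, c] / gmax * grad_levels), grad_levels - 1)
            else:
                j = 0
            H[i, j] += 1
    return H


def ggcm_stats_bruteforce(H):
    """All fifteen gray-gradient statistics by explicit loops."""
    H = np.asarray(H, dtype=float)
    gg, gs = H.shape
    total = H.sum()
    P = H / total
    pg = [P[i, :].sum() for i in range(gg)]
    ps = [P[:, j].sum() for j in range(gs)]
    small = sum(H[i, j] / (j + 1) ** 2 for i in range(gg) for j in range(gs)) / total
    large = sum(H[i, j] * j ** 2 for i in range(gg) for j in range(gs)) / total
    gray_nu = sum(H[i, :].sum() ** 2 for i in range(gg)) / total
    grad_nu = sum(H[:, j].sum() ** 2 for j in range(gs)) / total
    energy = sum(P[i, j] ** 2 for i in range(gg) for j in range(gs))
    mu_g = sum(i * pg[i] for i in range(gg))
    mu_s = sum(j * ps[j] for j in range(gs))
    sd_g = math.sqrt(sum((i - mu_g) ** 2 * pg[i] for i in range(gg)))
    sd_s = math.sqrt(sum((j - mu_s) ** 2 * ps[j] for j in range(gs)))
    if sd_g > 0 and sd_s > 0:
        corr = sum((i - mu_g) * (j - mu_s) * P[i, j]
                   for i in range(gg) for j in range(gs)) / (sd_g * sd_s)
    else:
        corr = 0.0
    h_g = -sum(p * math.log(p) for p in pg if p > 0)
    h_s = -sum(p * math.log(p) for p in ps if p > 0)
    h_m = -sum(P[i, j] * math.log(P[i, j])
               for i in range(gg) for j in range(gs) if P[i, j] > 0)
    inertia = sum((i - j) ** 2 * P[i, j] for i in range(gg) for j in range(gs))
    idm = sum(P[i, j] / (1 + (i - j) ** 2) for i in range(gg) for j in range(gs))
    return np.array([small, large, gray_nu, grad_nu, energy, mu_g, mu_s,
                     sd_g, sd_s, corr, h_g, h_s, h_m, inertia, idm])


# ---------------------------------------------------------- Hu moments -----

def hu_bruteforce(gray):
    """All eight Hu invariants via double-loop moment summation."""
    f = np.asarray(gray, dtype=float)
    h, w = f.shape
    m00 = mx = my = 0.0
    for r in range(h):
        for c in range(w):
            m00 += f[r, c]
            mx += c * f[r, c]
            my += r * f[r, c]
    xb, yb = mx / m00, my / m00
    mu = np.zeros((4, 4))
    for r in range(h):
        for c in range(w):
            for p in range(4):
                for q in range(4):
                    if p + q <= 3:
                        mu[p, q] += (c - xb) ** p * (r - yb) ** q * f[r, c]
    eta = np.zeros((4, 4))
    for p in range(4):
        for q in range(4):
            if p + q >= 2:
                eta[p, q] = mu[p, q] / m00 ** (1 + (p + q) / 2.0)
    n20, n02, n11 = eta[2, 0], eta[0, 2], eta[1, 1]
    n30, n03, n21, n12 = eta[3, 0], eta[0, 3], eta[2, 1], eta[1, 2]
    a, b = n30 + n12, n21 + n03
    return np.array([
        n20 + n02,
        (n20 - n02) ** 2 + 4 * n11 ** 2,
        (n30 - 3 * n12) ** 2 + (3 * n21 - n03) ** 2,
        a ** 2 + b ** 2,
        (n30 - 3 * n12) * a * (a ** 2 - 3 * b ** 2)
        + (3 * n21 - n03) * b * (3 * a ** 2 - b ** 2),
        (n20 - n02) * (a ** 2 - b ** 2) + 4 * n11 * a * b,
        (3 * n21 - n03) * a * (a ** 2 - 3 * b ** 2)
        - (n30 - 3 * n12) * b * (3 * a ** 2 - b ** 2),
        2 * n11 * (a ** 2 - b ** 2) - 2 * (n20 - n02) * a * b,
    ])


# -------------------------------------------------------------- color ------

def srgb_to_lab_bruteforce(rgb255):
    """One sRGB pixel to CIE L*a*b* (D65) via the standard formulas."""
    def lin(u):
        u = u / 255.0
        return u / 12.92 if u <= 0.04045 else ((u + 0.055) / 1.055) ** 2.4

    r, g, b = (lin(v) for v in rgb255)
    # sRGB D65 matrix
    x = 0.4124564 * r + 0.3575761 * g + 0.1804375 * b
    y = 0.2126729 * r + 0.7151522 * g + 0.0721750 * b
    z = 0.0193339 * r + 0.1191920 * g + 0.9503041 * b
    xn, yn, zn = 0.95047, 1.0, 1.08883

    def ff(t):
        return t ** (1 / 3) if t > (6 / 29) ** 3 else t / (3 * (6 / 29) ** 2) + 4 / 29

    fx, fy, fz = ff(x / xn), ff(y / yn), ff(z / zn)
    return np.array([116 * fy - 16, 500 * (fx - fy), 200 * (fy - fz)])
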