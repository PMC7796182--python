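"""The six leaf descriptors and their default configurations.

Each descriptor maps a 256x256 grayscale leaf image to a fixed-length real
vector:

========  =======================================  ==========
name      descriptor                               dimensions
========  =======================================  ==========
HOG       oriented-gradient histograms (cell 64)   324
RotLBP    rotation-invariant LBP (riu2, cell 64)   160
Gabor     5-scale x 8-orientation filter bank      360
GLCM      co-occurrence matrix statistics          6
GGCM      gray-gradient co-occurrence statistics   15
HU        Hu moment invariants                     8
========  =======================================  ==========

:func:`extract` dispatches on the canonical descriptor name
(case-insensitive) with the default parameters above.
"""

from __future__ import annotations

import numpy as np

from .hog import hog_features, hog_length
from .lbp import rotate_code, rotlbp_code, riu2_bin, lbp_codes, rotlbp_features
from .moments import hu_moments8, central_moments, normalized_moments
from .gabor import gabor_features, gabor_bank, GABOR_WAVELENGTHS
from .glcm import glcm, glcm_stats, quantize_gray, offset_for_angle, GLCM_STAT_NAMES
from .ggcm import ggcm, ggcm_stats, gradient_magnitude, quantize_gradient, GGCM_STAT_NAMES

__all__ = [
    "DESCRIPTOR_NAMES", "DESCRIPTOR_DIMS", "canonical_name", "extract",
    "hog_features", "hog_length",
    "rotate_code", "rotlbp_code", "riu2_bin", "lbp_codes", "rotlbp_features",
    "hu_moments8", "central_moments", "normalized_moments",
    "gabor_features", "gabor_bank", "GABOR_WAVELENGTHS",
    "glcm", "glcm_stats", "quantize_gray", "offset_for_angle", "GLCM_STAT_NAMES",
    "ggcm", "ggcm_stats", "gradient_magnitude", "quantize_gradient", "GGCM_STAT_NAMES",
]

#: default parameters shared by training and field detection
DEFAULT_PARAMS = {
    "HOG": {"cell": 64},
    "RotLBP": {"cell": 64},
    "Gabor": {"n_scales": 5, "n_orientations": 8, "grid": 3},
    "GLCM": {"levels": 64, "offset": (0, 1)},
    "GGCM": {"gray_levels": 64, "grad_levels": 64},
    "HU": {},
}

DESCRIPTOR_NAMES = ("HOG", "RotLBP", "Gabor", "GLCM", "GGCM", "HU")

#: descriptor lengths on a 256x256 input at default parameters
DESCRIPTOR_DIMS = {
    "HOG": 324,
    "RotLBP": 160,
    "Gabor": 360,
    "GLCM": 6,
    "GGCM": 15,
    "HU": 8,
}

_CANONICAL = {name.lower(): name for name in DESCRIPTOR_NAMES}


def canonical_name(name: str) -> str:
    """Resolve a case-insensitive descriptor name to its canonical spelling."""
    key = name.strip().lower()
    if key not in _CANONICAL:
        raise ValueError(f"unknown descriptor {name!r}; "
                         f"expected one of {DESCRIPTOR_NAMES}")
    return _CANONICAL[key]


def extract(name: str, gray: np.ndarray) -> np.ndarray:
    """Apply one descriptor (by canonical name) with its default parameters."""
    name = canonical_name(name)
    if name == "HOG":
        return hog_features(gray, cell=DEFAULT_PARAMS["HOG"]["cell"])
    if name == "RotLBP":
        return rotlbp_features(gray, cell=DEFAULT_PARAMS["RotLBP"]["cell"])
    if name == "Gabor":
        return gabor_features(gray)
    if name == "GLCM":
        p = DEFAULT_PARAMS["GLCM"]
        return glcm_stats(glcm(gray, levels=p["levels"], offset=p["offset"]))
    if name == "GGCM":
        p = DEFAULT_PARAMS["GGCM"]
        return ggcm_stats(ggcm(gray, gray_levels=p["gray_levels"],
                               grad_levels=p["grad_levels"]))
    if name == "HU":
        return hu_moments8(gray)
    raise AssertionError("unreachable")
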