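"""Image loading, color conversion, and size normalization.

Images are plain :class:`numpy.ndarray` grids: ``(H, W, 3)`` uint8 for color,
``(H, W)`` uint8 for grayscale.  Pixel coordinates are 0-based ``(row, col)``
and all boxes are half-open intervals ``[r0, r1) x [c0, c1)``.

The size normalization used throughout the pipeline preserves the leaf shape:
the image is scaled uniformly so its longer side matches the target side, and
the remaining canvas is filled with exact zeros.  Every descriptor downstream
therefore sees a square frame in which background pixels are 0.
"""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio
from skimage import color as _skcolor
from skimage.transform import resize as _sk_resize

__all__ = [
    "load_image",
    "save_image",
    "normalize_size",
    "to_gray",
    "rgb_to_lab",
]

#: Rec. 601 luminance weights used for grayscale conversion.
GRAY_WEIGHTS = (0.299, 0.587, 0.114)


def load_image(path) -> np.ndarray:
    """Read a raster image (PNG/JPEG/TIFF/BMP) as uint8, dropping any alpha."""
    img = np.asarray(iio.imread(path))
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[:, :, :3]
    if img.dtype != np.uint8:
        img = np.clip(img, 0, 255).astype(np.uint8)
    return img


def save_image(path, img: np.ndarray) -> None:
    """Write an image as PNG (or whatever the extension dictates)."""
    iio.imwrite(path, np.asarray(img, dtype=np.uint8))


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.size == 0 or img.ndim not in (2, 3):
        raise ValueError("empty or malformed image")
    return img


def normalize_size(img: np.ndarray, target_side: int = 256,
                   anchor: str = "topleft") -> np.ndarray:
    """Scale ``img`` uniformly to fit a ``target_side`` square, zero-padding the rest.

    The scale factor is ``s = target_side / max(H, W)`` for both axes, so the
    aspect ratio (leaf shape) is unchanged; the scaled content is placed at the
    top-left corner (or centered with ``anchor='center'``) and every remaining
    pixel is exactly 0 in every channel.  Bilinear interpolation is used, with
    anti-aliasing when shrinking.  Idempotent: a ``target_side`` square input
    is returned unchanged.
    """
    img = _check_image(img)
    if target_side < 1:
        raise ValueError("target_side must be >= 1")
    if anchor not in ("topleft", "center"):
        raise ValueError(f"unknown anchor {anchor!r}")
    h, w = img.shape[:2]
    if h == target_side and w == target_side:
        return img.copy()
    s = target_side / max(h, w)
    new_h = int(round(s * h))
    new_w = int(round(s * w))
    # the longer side maps exactly onto the target
    new_h = min(max(new_h, 1), target_side)
    new_w = min(max(new_w, 1), target_side)
    scaled = _sk_resize(
        img.astype(np.float64),
        (new_h, new_w) + img.shape[2:],
        order=1,
        mode="edge",
        anti_aliasing=(s < 1),
        preserve_range=True,
    )
    scaled = np.clip(np.rint(scaled), 0, 255).astype(np.uint8)
    out_shape = (target_side, target_side) + img.shape[2:]
    out = np.zeros(out_shape, dtype=np.uint8)
    if anchor == "topleft":
        r0, c0 = 0, 0
    else:
        r0 = (target_side - new_h) // 2
        c0 = (target_side - new_w) // 2
    out[r0:r0 + new_h, c0:c0 + new_w] = scaled
    return out


def to_gray(img: np.ndarray) -> np.ndarray:
    """Convert an RGB image to 8-bit grayscale with Rec. 601 luminance weights."""
    img = _check_image(img)
    if img.ndim == 2:
        return img.astype(np.uint8)
    if img.shape[2] != 3:
        raise ValueError("to_gray expects a 3-channel RGB image")
    wr, wg, wb = GRAY_WEIGHTS
    f = img.astype(np.float64)
    gray = wr * f[:, :, 0] + wg * f[:, :, 1] + wb * f[:, :, 2]
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def rgb_to_lab(img: np.ndarray) -> np.ndarray:
    """Convert an sRGB uint8 image to CIE L*a*b* (D65 white point).

    Returns a float array of shape ``(H, W, 3)`` holding the L (0..100),
    a (green-red) and b (blue-yellow) planes.  Vegetation pixels have a < 0;
    neutral grays sit on a = b = 0.
    """
    img = _check_image(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("rgb_to_lab expects a 3-channel RGB image")
    return _skcolor.rgb2lab(img)
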