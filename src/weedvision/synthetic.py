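"""Deterministic synthetic leaf crops and field scenes with ground truth.

The generator emulates the two kinds of data the pipeline consumes:

* **Leaf crops** (:func:`make_leaf`): a single plant rendered on an exactly
  zero background and size-normalized to 256x256, like a cropped, padded
  leaf sample.  Corn leaves are broad, elongated blades with smooth
  low-frequency shading and regular parallel vein striping; weed leaves are
  rosettes of thin blades carrying high-frequency speckle texture and a
  smaller area.  These are precisely the texture cues the co-occurrence,
  LBP and Gabor descriptors measure.
* **Field scenes** (:func:`make_field_scene`): a brown soil background with
  multiplicative noise and darker clods, plus non-overlapping plants of both
  classes; the returned :class:`SceneTruth` records every plant's class,
  tight bounding box, pixel area and seed, and the exact vegetation mask.

All geometry and texture are defined in *canonical* 256-pixel coordinates
and merely sampled at the requested render size, so a plant rendered small
in a scene and later re-normalized to 256x256 has the same texture
statistics as a training leaf.  Leaf crops are rendered at a random native
size (160..256 px) before normalization, emulating variably sized crops.

``texture_contrast`` in [0, 1] scales every class-dependent generator
parameter toward the pooled class mean: at 1 the classes carry their full
distinct texture and shape; at 0 the two class distributions are identical
and any classifier must fall to chance — a built-in negative control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import ellipse as _draw_ellipse

from .preprocessing import normalize_size, save_image

__all__ = ["TooCrowdedError", "PlantTruth", "SceneTruth", "make_leaf",
           "make_dataset", "make_field_scene", "CLASSES"]

CLASSES = ("corn", "weed")
_CLASS_CODE = {"corn": 0, "weed": 1}

# class-conditional generator parameters (canonical 256-px units)
_CLASS_PARAMS = {
    "corn": {
        "n_blades": 2.0,      # broad blades through the center
        "length": 0.88,       # fraction of the half-side
        "width": 0.24,
        "curve": 0.25,
        "stripe_amp": 26.0,   # regular parallel vein striping
        "speckle_amp": 5.0,
        "level": 152.0,       # green-channel base intensity
        "plant_side": 205.0,  # typical render size in a field scene
    },
    "weed": {
        "n_blades": 5.0,      # thin rosette blades
        "length": 0.70,
        "width": 0.075,
        "curve": 0.45,
        "stripe_amp": 4.0,
        "speckle_amp": 30.0,  # high-frequency speckle
        "level": 142.0,
        "plant_side": 165.0,
    },
}
_COMMON = {
    "stripe_period": 9.0,   # canonical pixels between vein stripes
    "lf_amp": 12.0,         # low-frequency shading, shared by both classes
    "r_base": 0.52,         # R and B as fractions of G (greenish hue)
    "b_base": 0.34,
}

SOIL_BASE = np.array([126.0, 94.0, 64.0])  # brown; Lab a > 0


class TooCrowdedError(RuntimeError):
    """Plant placement failed after the allowed number of retries."""


def _blend_params(cls: str, contrast: float) -> dict:
    """Interpolate class parameters toward the pooled mean by 1 - contrast."""
    if cls not in _CLASS_CODE:
        raise ValueError(f"unknown class {cls!r}; expected one of {CLASSES}")
    if not 0.0 <= contrast <= 1.0:
        raise ValueError("texture_contrast must lie in [0, 1]")
    out = {}
    for key, val in _CLASS_PARAMS[cls].items():
        mid = 0.5 * (_CLASS_PARAMS["corn"][key] + _CLASS_PARAMS["weed"][key])
        out[key] = mid + contrast * (val - mid)
    out.update(_COMMON)
    return out


def _speckle_field(rng: np.random.Generator, side: int) -> np.ndarray:
    """Band-limited unit-variance noise sampled in canonical coordinates."""
    grid = ndi.gaussian_filter(rng.standard_normal((96, 96)), 1.0,
                               mode="wrap")
    grid /= grid.std() + 1e-12
    k = 256.0 / side * 96.0 / 256.0
    rows = np.arange(side) * k
    cols = np.arange(side) * k
    coords = np.meshgrid(rows, cols, indexing="ij")
    return ndi.map_coordinates(grid, coords, order=1, mode="wrap")


def _render_plant(cls: str, rng: np.random.Generator, side: int,
                  contrast: float) -> np.ndarray:
    """Render one plant on a zero background at the given side length."""
    p = _blend_params(cls, contrast)
    k = 256.0 / side                       # pixels -> canonical pixels
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    cx = side / 2 + rng.uniform(-0.04, 0.04) * side
    cy = side / 2 + rng.uniform(-0.04, 0.04) * side
    n_blades = max(1, int(round(rng.normal(p["n_blades"], 0.6))))
    base_angle = rng.uniform(0, 2 * np.pi)
    lf_phase = rng.uniform(0, 2 * np.pi)
    level = p["level"] * rng.uniform(0.88, 1.12)

    tex = np.zeros((side, side))
    mask = np.zeros((side, side), dtype=bool)
    for i in range(n_blades):
        phi = base_angle + i * 2 * np.pi / n_blades + rng.normal(0, 0.18)
        L = p["length"] * (side / 2) * rng.uniform(0.85, 1.1)
        W = max(p["width"] * (side / 2) * rng.uniform(0.8, 1.25), 1.5)
        bend = p["curve"] * rng.uniform(-1, 1)
        phase = rng.uniform(0, 2 * np.pi)
        dx = xx - cx
        dy = yy - cy
        u = (dx * np.cos(phi) + dy * np.sin(phi)) / L
        t = -dx * np.sin(phi) + dy * np.cos(phi)      # perpendicular, pixels
        t = t - bend * W * 2 * u ** 2                 # gentle curvature
        v = t / W
        envelope = np.zeros_like(u)
        inside_u = (u > 0.0) & (u < 1.0)
        uu = np.clip(u, 1e-9, 1.0)
        envelope[inside_u] = ((uu[inside_u] ** 0.25)
                              * (1.0 - uu[inside_u]) ** 0.6) / 0.6
        blade = inside_u & (np.abs(v) <= envelope)
        stripe = np.sin(2 * np.pi * (t * k) / p["stripe_period"] + phase)
        lf = np.sin(1.3 * np.pi * u + lf_phase)
        vals = p["stripe_amp"] * stripe + p["lf_amp"] * lf
        tex[blade] = vals[blade]
        mask |= blade
    if not mask.any():       # degenerate draw; guarantee at least some pixels
        mask[side // 2 - 2:side // 2 + 2, side // 2 - 2:side // 2 + 2] = True
    tex += p["speckle_amp"] * _speckle_field(rng, side)

    factor = np.clip(1.0 + tex / 170.0, 0.2, 1.9)
    g = level * factor
    img = np.zeros((side, side, 3), dtype=np.uint8)
    rgb = np.stack([p["r_base"] * g, g, p["b_base"] * g], axis=-1)
    img[mask] = np.clip(np.rint(rgb[mask]), 1, 255).astype(np.uint8)
    return img


def _tight_crop(img: np.ndarray) -> np.ndarray:
    """Crop an image to the bounding box of its nonzero content."""
    mask = img.any(axis=2) if img.ndim == 3 else img > 0
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return img[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]


def make_leaf(cls: str, seed: int, side: int = 256,
              texture_contrast: float = 1.0,
              native_side: int | None = None) -> np.ndarray:
    """One synthetic leaf crop, normalized to ``side`` x ``side``, background 0.

    The plant is rendered at a random native size (160..``side`` px, or
    ``native_side`` if given), tightly cropped to its content and then passed
    through the same zero-padded size normalization as real leaf crops — the
    identical path a detected field region takes.  Deterministic per
    (class, seed).
    """
    if cls not in _CLASS_CODE:
        raise ValueError(f"unknown class {cls!r}; expected one of {CLASSES}")
    rng = np.random.default_rng([_CLASS_CODE[cls], int(seed) & 0x7FFFFFFF,
                                 int(seed) >> 31])
    if native_side is None:
        native_side = int(rng.integers(160, side + 1))
    img = _render_plant(cls, rng, native_side, texture_contrast)
    img = _tight_crop(img)
    return normalize_size(img, side)


def make_dataset(n_pos: int, n_neg: int, seed: int = 0,
                 texture_contrast: float = 1.0, out_dir=None):
    """A labeled leaf collection: ``n_pos`` corn (+1) and ``n_neg`` weed (-1).

    Returns ``(images, labels, manifest)``; the manifest records file name,
    class and per-leaf seed.  With ``out_dir`` the PNGs and a
    ``manifest.csv`` are also written.  Fully reproducible given ``seed``.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both classes need at least one sample")
    images, labels, rows = [], [], []
    for cls, n, lab in (("corn", n_pos, 1), ("weed", n_neg, -1)):
        for i in range(n):
            leaf_seed = int(seed) * 1_000_003 + i
            images.append(make_leaf(cls, leaf_seed,
                                    texture_contrast=texture_contrast))
            labels.append(lab)
            rows.append({"file": f"leaf_{cls}_{i:04d}.png", "class": cls,
                         "label": lab, "seed": leaf_seed})
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        import os
        os.makedirs(out_dir, exist_ok=True)
        for img, row in zip(images, manifest.to_dict("records")):
            save_image(os.path.join(out_dir, row["file"]), img)
        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return images, np.array(labels), manifest


@dataclass(frozen=True)
class PlantTruth:
    """Ground truth for one planted plant."""

    cls: str
    box: tuple   # (r0, c0, r1, c1), half-open, tight around the plant
    area: int
    seed: int


@dataclass
class SceneTruth:
    """Ground truth for a synthetic field scene."""

    plants: list
    soil: dict = field(default_factory=dict)
    veg_mask: np.ndarray | None = None

    def count(self, cls: str | None = None) -> int:
        if cls is None:
            return len(self.plants)
        return sum(1 for p in self.plants if p.cls == cls)

    def to_json_dict(self) -> dict:
        return {"plants": [{"class": p.cls, "box": list(p.box),
                            "area": p.area, "seed": p.seed}
                           for p in self.plants],
                "soil": {k: (float(v) if np.isscalar(v) else list(v))
                         for k, v in self.soil.items()}}


def _boxes_overlap(a, b, margin: int) -> bool:
    return not (a[2] + margin <= b[0] or b[2] + margin <= a[0]
                or a[3] + margin <= b[1] or b[3] + margin <= a[1])


def make_field_scene(n_corn: int, n_weed: int, size=(600, 1024),
                     seed: int = 0, texture_contrast: float = 1.0,
                     max_tries: int = 200):
    """A soil-background field scene with non-overlapping plants.

    ``size`` is ``(rows, cols)``; the default matches a 1024x600 field frame.
    Returns ``(scene, truth)``; raises :class:`TooCrowdedError` when a plant
    cannot be placed within ``max_tries`` attempts.  Pixel-identical given
    the same arguments.
    """
    h, w = size
    if min(h, w) < 256:
        raise ValueError("scene must be at least 256 pixels on each side")
    rng = np.random.default_rng([7, int(seed) & 0x7FFFFFFF])

    # soil: brown base, smooth multiplicative noise, darker clods
    brightness = rng.uniform(0.9, 1.1)
    noise = ndi.gaussian_filter(rng.standard_normal((h, w)), 6.0)
    noise /= noise.std() + 1e-12
    soil = SOIL_BASE[None, None, :] * brightness * (1 + 0.06 * noise)[:, :, None]
    n_clods = int(rng.integers(12, 26))
    for _ in range(n_clods):
        r, c = rng.integers(0, h), rng.integers(0, w)
        ra, rb = rng.uniform(8, 50), rng.uniform(8, 50)
        rot = rng.uniform(0, np.pi)
        rr, cc = _draw_ellipse(r, c, ra, rb, shape=(h, w), rotation=rot)
        soil[rr, cc] *= rng.uniform(0.72, 0.92)
    scene = np.clip(np.rint(soil), 1, 255).astype(np.uint8)

    classes = ["corn"] * n_corn + ["weed"] * n_weed
    rng.shuffle(classes)
    placed_boxes, plants = [], []
    veg_mask = np.zeros((h, w), dtype=bool)
    side_cap = min(256, h - 12, w - 12)
    for cls in classes:
        params = _blend_params(cls, texture_contrast)
        s = int(np.clip(params["plant_side"] * rng.uniform(0.85, 1.15),
                        120, side_cap))
        plant_seed = int(rng.integers(0, 2 ** 31 - 1))
        prng = np.random.default_rng([_CLASS_CODE[cls], plant_seed])
        plant = _render_plant(cls, prng, s, texture_contrast)
        pmask = plant.any(axis=2)
        rows_any = np.flatnonzero(pmask.any(axis=1))
        cols_any = np.flatnonzero(pmask.any(axis=0))
        plant = plant[rows_any[0]:rows_any[-1] + 1, cols_any[0]:cols_any[-1] + 1]
        pmask = pmask[rows_any[0]:rows_any[-1] + 1, cols_any[0]:cols_any[-1] + 1]
        ph, pw = pmask.shape
        for _ in range(max_tries):
            r0 = int(rng.integers(4, h - ph - 4))
            c0 = int(rng.integers(4, w - pw - 4))
            box = (r0, c0, r0 + ph, c0 + pw)
            if not any(_boxes_overlap(box, b, margin=8) for b in placed_boxes):
                break
        else:
            raise TooCrowdedError(
                f"could not place a {cls} plant of {ph}x{pw} px after "
                f"{max_tries} tries")
        placed_boxes.append(box)
        region = scene[r0:r0 + ph, c0:c0 + pw]
        region[pmask] = plant[pmask]
        veg_mask[r0:r0 + ph, c0:c0 + pw] |= pmask
        plants.append(PlantTruth(cls=cls, box=box, area=int(pmask.sum()),
                                 seed=plant_seed))
    truth = SceneTruth(plants=plants,
                       soil={"brightness": brightness, "clods": n_clods},
                       veg_mask=veg_mask)
    return scene, truth
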