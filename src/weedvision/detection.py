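"""End-to-end weed / corn-seedling detection on field scenes.

Pipeline: convert the scene to CIE L*a*b*, cluster the green-red ``a``
channel with k-means (k=2) and take the cluster with the lower mean ``a``
as vegetation, drop 8-connected components below a minimum area, then crop
each surviving region (pixels outside the component zeroed), normalize it to
256x256 exactly like a training leaf, and classify it with a trained
:class:`~weedvision.classifier.LeafClassifier`.  Corn detections are drawn
as yellow rectangles, weeds as red.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import measure as _skmeasure
from sklearn.cluster import KMeans

from .classifier import CORN_LABEL, LeafClassifier
from .preprocessing import normalize_size, rgb_to_lab

__all__ = ["Region", "Detection", "segment_vegetation", "extract_regions",
           "classify_regions", "annotate", "detect", "default_min_area",
           "NoVegetationWarning"]

CORN_COLOR = (255, 255, 0)   # yellow
WEED_COLOR = (255, 0, 0)     # red

#: minimum separation (Lab a units) between cluster means to accept vegetation
MIN_CLUSTER_SEPARATION = 8.0


class NoVegetationWarning(UserWarning):
    """Raised (as a warning) when a scene contains no separable vegetation."""


@dataclass(frozen=True)
class Region:
    """A connected vegetation component: label, pixel area and bounding box."""

    label: int
    area: int
    box: tuple  # (r0, c0, r1, c1), half-open


@dataclass(frozen=True)
class Detection:
    """A classified region: box, predicted class, decision score, area."""

    box: tuple
    predicted_class: str  # "corn" | "weed"
    score: float
    area: int


def default_min_area(shape) -> int:
    """Default small-region threshold: 0.1% of the scene's pixels."""
    return max(1, int(0.001 * shape[0] * shape[1]))


def segment_vegetation(img: np.ndarray, seed: int = 0,
                       max_fit_samples: int = 50_000) -> np.ndarray:
    """Binary vegetation mask from k-means (k=2) on the Lab ``a`` channel.

    The cluster with the lower mean ``a`` (greener) is foreground.  If the
    channel is degenerate or the two cluster means are nearly equal (e.g. a
    pure-soil scene), an all-background mask is returned with a
    :class:`NoVegetationWarning`.  Deterministic given ``seed``.
    """
    img = np.asarray(img)
    if img.size == 0 or img.ndim != 3:
        raise ValueError("segment_vegetation expects a nonempty color image")
    a = rgb_to_lab(img)[:, :, 1]
    vals = a.reshape(-1, 1)
    if np.ptp(vals) < 1e-6:
        warnings.warn("single-valued a channel: no vegetation found",
                      NoVegetationWarning)
        return np.zeros(a.shape, dtype=bool)
    rng = np.random.default_rng(seed)
    fit_vals = vals
    if vals.shape[0] > max_fit_samples:
        fit_vals = vals[rng.choice(vals.shape[0], max_fit_samples,
                                   replace=False)]
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(fit_vals)
    means = km.cluster_centers_.ravel()
    if abs(means[0] - means[1]) < MIN_CLUSTER_SEPARATION:
        warnings.warn("cluster means nearly equal: no vegetation found",
                      NoVegetationWarning)
        return np.zeros(a.shape, dtype=bool)
    fg = int(np.argmin(means))
    labels = km.predict(vals)
    return (labels == fg).reshape(a.shape)


def extract_regions(mask: np.ndarray, min_area: int):
    """8-connected components of a mask, small ones removed.

    Returns ``(label_map, regions)`` where ``label_map`` relabels surviving
    components contiguously from 1 (0 = background) and ``regions`` is a list
    of :class:`Region` in label order.
    """
    mask = np.asarray(mask, dtype=bool)
    raw = _skmeasure.label(mask, connectivity=2)
    out = np.zeros(mask.shape, dtype=np.int32)
    regions = []
    next_label = 1
    for prop in _skmeasure.regionprops(raw):
        if prop.area < min_area:
            continue
        r0, c0, r1, c1 = prop.bbox
        out[raw == prop.label] = next_label
        regions.append(Region(label=next_label, area=int(prop.area),
                              box=(int(r0), int(c0), int(r1), int(c1))))
        next_label += 1
    return out, regions


def classify_regions(img: np.ndarray, label_map: np.ndarray, regions,
                     model: LeafClassifier):
    """Classify each region with the model bundle; one Detection per region.

    The region is cropped by its bounding box, pixels outside the component
    are zeroed (mirroring the zero-padded leaf training data), the crop is
    normalized to 256x256, featurized with the model's fusion spec, projected
    with its PCA and scored by its SVM.  Regions too small to support the
    descriptors (< 3 px a side) are skipped with a warning.
    """
    img = np.asarray(img)
    detections = []
    for reg in regions:
        r0, c0, r1, c1 = reg.box
        if r1 - r0 < 3 or c1 - c0 < 3:
            warnings.warn(f"region {reg.label} smaller than descriptor "
                          "support; skipped")
            continue
        crop = img[r0:r1, c0:c1].copy()
        crop[label_map[r0:r1, c0:c1] != reg.label] = 0
        label, score = model.predict_image(crop)
        cls = "corn" if label == CORN_LABEL else "weed"
        detections.append(Detection(box=reg.box, predicted_class=cls,
                                    score=score, area=reg.area))
    return detections


def annotate(img: np.ndarray, detections, thickness: int = 2) -> np.ndarray:
    """Copy of the scene with detection rectangles drawn on it.

    Corn boxes are yellow, weed boxes red; outlines are ``thickness`` pixels
    wide, drawn inside the box; later detections are drawn over earlier ones.
    """
    out = np.asarray(img).copy()
    for det in detections:
        r0, c0, r1, c1 = det.box
        color = CORN_COLOR if det.predicted_class == "corn" else WEED_COLOR
        t = thickness
        out[r0:min(r0 + t, r1), c0:c1] = color
        out[max(r1 - t, r0):r1, c0:c1] = color
        out[r0:r1, c0:min(c0 + t, c1)] = color
        out[r0:r1, max(c1 - t, c0):c1] = color
    return out


def detect(img: np.ndarray, model: LeafClassifier, min_area: int | None = None,
           seed: int = 0):
    """Full detection pass over a field scene.

    Returns ``(detections, label_map, mask)``.
    """
    img = np.asarray(img)
    if min_area is None:
        min_area = default_min_area(img.shape)
    mask = segment_vegetation(img, seed=seed)
    label_map, regions = extract_regions(mask, min_area)
    detections = classify_regions(img, label_map, regions, model)
    return detections, label_map, mask
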