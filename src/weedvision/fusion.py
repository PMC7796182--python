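"""Feature fusion strategies and PCA dimensionality reduction.

A fusion *strategy* is a "+"-separated, case-insensitive list of descriptor
names (e.g. ``"GGCM+RotLBP"``); the fused vector is the concatenation of the
member descriptors in the order named, so its dimension is the sum of the
member dimensions (GGCM+RotLBP: 15 + 160 = 175; HOG+Gabor: 684; the full
five-feature fusion RotLBP+HOG+Gabor+HU+GGCM: 867).

PCA is fitted once on the training feature matrix and the same mean and
projection are reapplied to every later sample (validation data and field
regions), so all data live under one mapping.  Components follow a
deterministic sign convention: the largest-magnitude loading of each
component is positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA as _SkPCA

from . import features as F
from .preprocessing import to_gray

__all__ = ["FeatureSpec", "concat_features", "PCAModel", "fit_pca",
           "apply_pca", "choose_p_by_variance", "select_retention"]


@dataclass(frozen=True)
class FeatureSpec:
    """Which descriptors are fused, in which order, with which parameters."""

    descriptors: tuple
    params: dict = field(default_factory=dict)

    @classmethod
    def parse(cls, strategy: str) -> "FeatureSpec":
        """Build a spec from a strategy string such as ``"GGCM+RotLBP"``."""
        parts = [p for p in strategy.split("+") if p.strip()]
        if not parts:
            raise ValueError("empty fusion strategy")
        names = tuple(F.canonical_name(p) for p in parts)
        params = {n: dict(F.DEFAULT_PARAMS[n]) for n in names}
        return cls(descriptors=names, params=params)

    @property
    def name(self) -> str:
        return "+".join(self.descriptors)

    @property
    def dims(self) -> tuple:
        return tuple(F.DESCRIPTOR_DIMS[n] for n in self.descriptors)

    @property
    def total_dim(self) -> int:
        return sum(self.dims)

    def extract(self, img: np.ndarray) -> np.ndarray:
        """Fused descriptor of a normalized 256x256 leaf image (RGB or gray)."""
        gray = to_gray(img) if img.ndim == 3 else np.asarray(img)
        return concat_features([F.extract(n, gray) for n in self.descriptors])

    def extract_many(self, imgs) -> np.ndarray:
        """Stack fused descriptors of an image sequence into a matrix."""
        return np.vstack([self.extract(im) for im in imgs])

    def to_json(self) -> str:
        payload = {
            "descriptors": list(self.descriptors),
            "params": {k: {kk: (list(vv) if isinstance(vv, tuple) else vv)
                           for kk, vv in v.items()}
                       for k, v in self.params.items()},
            "total_dim": self.total_dim,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FeatureSpec":
        payload = json.loads(text)
        params = {k: {kk: (tuple(vv) if isinstance(vv, list) else vv)
                      for kk, vv in v.items()}
                  for k, v in payload["params"].items()}
        return cls(descriptors=tuple(payload["descriptors"]), params=params)


def concat_features(parts) -> np.ndarray:
    """Concatenate per-sample descriptor vectors, preserving member order."""
    parts = list(parts)
    if not parts:
        raise ValueError("cannot concatenate an empty list of feature vectors")
    return np.concatenate([np.asarray(p, dtype=np.float64).ravel() for p in parts])


@dataclass
class PCAModel:
    """A fitted PCA projection: training mean + (input-dim x p) components."""

    mean: np.ndarray          # (d,)
    components: np.ndarray    # (d, p), orthonormal columns
    explained_variance: np.ndarray  # (p,)

    @property
    def p(self) -> int:
        return self.components.shape[1]

    @property
    def input_dim(self) -> int:
        return self.components.shape[0]


def fit_pca(X: np.ndarray, p: int) -> PCAModel:
    """Fit a PCA retaining ``p`` components on a samples-by-dim matrix."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("fit_pca needs a 2-D matrix with at least 2 samples")
    n, d = X.shape
    if not 1 <= p <= min(n - 1, d):
        raise ValueError(f"retained dimension p={p} out of range "
                         f"[1, {min(n - 1, d)}]")
    sk = _SkPCA(n_components=p, svd_solver="full")
    sk.fit(X)
    comps = sk.components_.T.copy()              # (d, p)
    # deterministic sign: largest-magnitude loading of each component positive
    for j in range(comps.shape[1]):
        k = np.argmax(np.abs(comps[:, j]))
        if comps[k, j] < 0:
            comps[:, j] = -comps[:, j]
    return PCAModel(mean=sk.mean_.copy(), components=comps,
                    explained_variance=sk.explained_variance_.copy())


def apply_pca(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Project new samples with a fitted PCA: ``(X - mean) @ components``."""
    X = np.asarray(X, dtype=np.float64)
    one = X.ndim == 1
    if one:
        X = X[None, :]
    if X.shape[1] != model.input_dim:
        raise ValueError(f"dimension mismatch: data has {X.shape[1]} columns, "
                         f"PCA expects {model.input_dim}")
    Z = (X - model.mean) @ model.components
    return Z[0] if one else Z


def choose_p_by_variance(X: np.ndarray, fraction: float = 0.99) -> int:
    """Smallest p whose components explain ``fraction`` of the variance."""
    X = np.asarray(X, dtype=np.float64)
    pmax = min(X.shape[0] - 1, X.shape[1])
    sk = _SkPCA(n_components=pmax, svd_solver="full")
    sk.fit(X)
    cum = np.cumsum(sk.explained_variance_ratio_)
    return int(np.searchsorted(cum, fraction) + 1)


def select_retention(X: np.ndarray, y: np.ndarray, candidates,
                     eval_fn=None, seed: int = 0):
    """Pick the retained-component count maximizing validation accuracy.

    For each candidate ``p`` the data are stratified-split 70/30, a PCA with
    ``p`` components is fitted on the training part and a standardized linear
    SVM is trained on the projections; the candidate with the highest
    validation accuracy wins, ties going to the smallest ``p``.  A custom
    ``eval_fn(p) -> accuracy`` can replace the default protocol.

    Returns ``(best_p, {p: accuracy})``.
    """
    candidates = sorted(set(int(p) for p in candidates))
    if not candidates:
        raise ValueError("no retention candidates given")
    if eval_fn is None:
        from .classifier import split_dataset, train_svm, evaluate

        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        tr, va = split_dataset(y, train_fraction=0.7, seed=seed)

        def eval_fn(p):
            model = fit_pca(X[tr], p)
            svm = train_svm(apply_pca(model, X[tr]), y[tr], seed=seed)
            _, acc = evaluate(svm, apply_pca(model, X[va]), y[va])
            return acc

    scores = {p: float(eval_fn(p)) for p in candidates}
    best = max(candidates, key=lambda p: (scores[p], -p))
    return best, scores
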