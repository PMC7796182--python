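"""SVM training, validation, and the repeated-experiment protocol.

Label convention: corn seedling = +1 (positive), weed = -1 (negative).
The training protocol mirrors the pipeline's published recipe: extract the
fused descriptor for every sample, reduce with PCA (fitted once on the full
feature matrix; strategies of 15 dimensions or fewer skip PCA by default),
shuffle and stratified-split 70/30 with an explicit seed, standardize each
dimension with training-fold statistics, train the SVM, and score the
held-out 30% with

    accuracy = (TP + TN) / (TP + FP + FN + TN).

Each experiment is repeated over a seed list (default 0..9) and the mean
accuracy is reported per strategy.
"""

from __future__ import annotations

from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .fusion import FeatureSpec, PCAModel, apply_pca, choose_p_by_variance, fit_pca
from .preprocessing import normalize_size

__all__ = [
    "CORN_LABEL", "WEED_LABEL", "ConfusionCounts", "TrainedSVM",
    "split_dataset", "train_svm", "evaluate", "LeafClassifier",
    "train_leaf_classifier", "repeat_experiment", "strategy_table",
]

CORN_LABEL = 1
WEED_LABEL = -1

#: strategies at or below this input dimension skip PCA by default
PCA_SKIP_DIM = 15


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with corn (+1) as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total


def split_dataset(y, train_fraction: float = 0.7, seed: int = 0):
    """Shuffled, stratified train/validation index split.

    Each class contributes ``train_fraction`` of its samples to the training
    set (so 700 + 700 train and 300 + 300 validation for 1000 + 1000 samples
    at 0.7).  Returns ``(train_idx, val_idx)`` integer arrays.
    """
    y = np.asarray(y)
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present to split")
    if counts.min() < 1:
        raise ValueError("each class needs at least one sample")
    idx = np.arange(y.size)
    tr, va = train_test_split(idx, train_size=train_fraction,
                              random_state=seed, shuffle=True, stratify=y)
    return np.asarray(tr), np.asarray(va)


class TrainedSVM:
    """A fitted scaler + SVM pair operating on reduced feature matrices."""

    def __init__(self, scaler: StandardScaler, svc: SVC):
        self.scaler = scaler
        self.svc = svc

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        return self.svc.predict(self.scaler.transform(X)).astype(int)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        return self.svc.decision_function(self.scaler.transform(X))


def train_svm(X, y, kernel: str = "linear", C: float = 1.0,
              gamma="scale", seed: int = 0) -> TrainedSVM:
    """Train a margin classifier on labeled (+1/-1) feature rows.

    Features are standardized per dimension with the statistics of the given
    (training) data; the same scaler is applied at prediction time.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    scaler = StandardScaler().fit(X)
    svc = SVC(kernel=kernel, C=C, gamma=gamma, random_state=seed)
    svc.fit(scaler.transform(X), y)
    return TrainedSVM(scaler, svc)


def evaluate(model, X, y) -> tuple:
    """Confusion counts and accuracy of a model on a labeled validation set."""
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("validation set is empty")
    pred = model.predict(X)
    tp = int(np.sum((pred == CORN_LABEL) & (y == CORN_LABEL)))
    fp = int(np.sum((pred == CORN_LABEL) & (y == WEED_LABEL)))
    fn = int(np.sum((pred == WEED_LABEL) & (y == CORN_LABEL)))
    tn = int(np.sum((pred == WEED_LABEL) & (y == WEED_LABEL)))
    counts = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)
    return counts, counts.accuracy


@dataclass
class LeafClassifier:
    """The full model bundle: fusion spec + PCA projection + scaler + SVM.

    The same bundle classifies normalized leaf images during validation and
    masked region crops during field detection, guaranteeing an identical
    feature mapping in both settings.
    """

    spec: FeatureSpec
    pca: PCAModel | None
    svm: TrainedSVM

    def reduce(self, X: np.ndarray) -> np.ndarray:
        return apply_pca(self.pca, X) if self.pca is not None else np.asarray(X)

    def predict_features(self, X: np.ndarray) -> np.ndarray:
        return self.svm.predict(self.reduce(X))

    def predict_image(self, img: np.ndarray) -> tuple:
        """(label, decision score) for one image, normalized to 256x256."""
        img = normalize_size(img, 256)
        x = self.reduce(self.spec.extract(img))
        label = int(self.svm.predict(x)[0])
        score = float(self.svm.decision_function(x)[0])
        return label, score

    def save(self, path) -> None:
        joblib.dump({"spec_json": self.spec.to_json(), "pca": self.pca,
                     "svm": self.svm}, path)
        # human-readable provenance of the feature mapping
        sidecar = str(path) + ".spec.json"
        with open(sidecar, "w") as fh:
            fh.write(self.spec.to_json())

    @classmethod
    def load(cls, path) -> "LeafClassifier":
        blob = joblib.load(path)
        return cls(spec=FeatureSpec.from_json(blob["spec_json"]),
                   pca=blob["pca"], svm=blob["svm"])


def train_leaf_classifier(images, labels, strategy: str = "GGCM+RotLBP",
                          pca="auto", train_fraction: float = 0.7,
                          seed: int = 0, kernel: str = "linear",
                          C: float = 1.0, features: np.ndarray | None = None):
    """Train and validate a leaf classifier end to end.

    ``pca`` may be ``"auto"`` (retain 99% variance, skipped for strategies of
    <= 15 input dimensions), ``None`` (never reduce) or an integer retained
    count.  Precomputed fused ``features`` may be passed to avoid repeated
    extraction when several seeds reuse one feature matrix.

    Returns ``(LeafClassifier, report)`` where ``report`` carries the split
    indices, confusion counts and validation accuracy.
    """
    spec = FeatureSpec.parse(strategy)
    y = np.asarray(labels)
    X = spec.extract_many(images) if features is None else np.asarray(features)
    if X.shape[1] != spec.total_dim:
        raise ValueError("feature matrix does not match the fusion strategy")

    if pca == "auto":
        p = None if spec.total_dim <= PCA_SKIP_DIM else choose_p_by_variance(X)
    else:
        p = pca
    pca_model = fit_pca(X, p) if p is not None else None
    Z = apply_pca(pca_model, X) if pca_model is not None else X

    tr, va = split_dataset(y, train_fraction=train_fraction, seed=seed)
    svm = train_svm(Z[tr], y[tr], kernel=kernel, C=C, seed=seed)
    model = LeafClassifier(spec=spec, pca=pca_model, svm=svm)
    counts, acc = evaluate(svm, Z[va], y[va])
    report = {"train_idx": tr, "val_idx": va, "counts": counts,
              "accuracy": acc, "pca_dim": p if p is not None else spec.total_dim,
              "input_dim": spec.total_dim}
    return model, report


def repeat_experiment(images, labels, strategy: str = "GGCM+RotLBP",
                      seeds=tuple(range(10)), pca="auto",
                      train_fraction: float = 0.7, kernel: str = "linear",
                      C: float = 1.0) -> pd.DataFrame:
    """Run one strategy once per seed; returns a per-run accuracy table.

    Features are extracted once and only the shuffled split (and SVM fit)
    varies across runs, matching the repeated-validation protocol.
    """
    if len(seeds) < 1:
        raise ValueError("at least one seed is required")
    spec = FeatureSpec.parse(strategy)
    X = spec.extract_many(images)
    rows = []
    for s in seeds:
        _, rep = train_leaf_classifier(images, labels, strategy=strategy,
                                       pca=pca, train_fraction=train_fraction,
                                       seed=int(s), kernel=kernel, C=C,
                                       features=X)
        rows.append({"strategy": spec.name, "seed": int(s),
                     "pca_dim": rep["pca_dim"], "input_dim": rep["input_dim"],
                     "accuracy": rep["accuracy"]})
    return pd.DataFrame(rows)


def strategy_table(images, labels, strategies, seeds=tuple(range(10)),
                   **kwargs) -> pd.DataFrame:
    """Mean-accuracy comparison table across strategies, sorted descending."""
    frames = []
    for strat in strategies:
        runs = repeat_experiment(images, labels, strategy=strat, seeds=seeds,
                                 **kwargs)
        frames.append({
            "strategy": runs["strategy"].iloc[0],
            "pca_dim": int(runs["pca_dim"].iloc[0]),
            "input_dim": int(runs["input_dim"].iloc[0]),
            "mean_accuracy": float(runs["accuracy"].mean()),
            "runs": len(runs),
        })
    table = pd.DataFrame(frames).sort_values("mean_accuracy", ascending=False)
    return table.reset_index(drop=True)
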