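"""K-nearest-neighbour classification of lesion feature vectors.

The classifier is deliberately written out in full rather than delegated:
its exact tie-breaking and vote rules are part of the contract.

* Features are z-scored with centre/scale fitted on the training rows only
  (raw features span pixel counts ~1e3 down to unit-scale indices, which
  would otherwise let area dominate the Euclidean metric).  A constant
  feature gets scale 1 and a warning.
* Prediction takes the k nearest training rows by Euclidean distance;
  ties at the k-th distance are admitted by ascending training-row index;
  the majority label wins, and a 50/50 vote (possible only with an even k
  override) falls back to the single nearest neighbour's label.
* K is chosen by the accuracy-plot method: leave-one-out accuracy over an
  odd-k grid, smallest k on ties.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import FEATURE_NAMES
from .types import ValidationError

__all__ = [
    "TrainedModel",
    "euclidean_distance",
    "fit",
    "predict",
    "select_k",
    "evaluate",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


def euclidean_distance(a, b) -> float:
    """Plain Euclidean distance sqrt(sum (a_i - b_i)^2)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("b", f"dimension mismatch {a.shape} vs {b.shape}")
    return float(np.sqrt(((a - b) ** 2).sum()))


@dataclass
class TrainedModel:
    """Standardised training matrix, labels, scaler and chosen k."""

    train_matrix: np.ndarray  # n x d, already standardised
    labels: np.ndarray  # n values in {0, 1}
    center: np.ndarray  # d
    scale: np.ndarray  # d, never 0
    k: int
    feature_order: tuple[str, ...] = field(default=FEATURE_NAMES)

    def __post_init__(self):
        self.train_matrix = np.asarray(self.train_matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.center = np.asarray(self.center, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        n, d = self.train_matrix.shape
        if self.labels.shape != (n,):
            raise ValidationError("labels", "one label per training row required")
        if not np.all(np.isin(self.labels, (0, 1))):
            raise ValidationError("labels", "labels must be 0 or 1")
        if self.center.shape != (d,) or self.scale.shape != (d,):
            raise ValidationError("scaler", "centre/scale must have one entry per feature")
        if np.any(self.scale == 0):
            raise ValidationError("scaler", "scale values must be nonzero")
        if not (1 <= self.k <= n):
            raise ValidationError("k", "k must lie in [1, n]")

    def standardize(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.center.shape[0]:
            raise ValidationError("x", "feature dimension mismatch")
        return (x - self.center) / self.scale


def _fit_scaler(features: np.ndarray):
    center = features.mean(axis=0)
    scale = features.std(axis=0)  # population std
    constant = scale == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s); scale forced to 1",
            stacklevel=3,
        )
        scale = np.where(constant, 1.0, scale)
    return center, scale


def _vote(model: TrainedModel, z: np.ndarray, exclude: int | None = None):
    """k-NN vote for one standardised point; returns (label, frac, ids)."""
    dists = np.sqrt(((model.train_matrix - z) ** 2).sum(axis=1))
    idx = np.arange(len(dists))
    if exclude is not None:
        keep = idx != exclude
        dists, idx = dists[keep], idx[keep]
    # stable order: ascending distance, ties by ascending training index
    order = np.lexsort((idx, dists))
    chosen = idx[order[: model.k]]
    votes = model.labels[chosen]
    ones = int(votes.sum())
    zeros = len(votes) - ones
    if ones > zeros:
        label = 1
    elif zeros > ones:
        label = 0
    else:  # even-k tie: defer to the single nearest neighbour
        label = int(model.labels[chosen[0]])
    frac = max(ones, zeros) / len(votes)
    return label, float(frac), chosen


def fit(features, labels, k: int | None = None, k_grid=None,
        standardize: bool = True) -> TrainedModel:
    """Fit a KNN model: z-score the features, store them, choose k.

    With ``k=None`` the value is selected by leave-one-out accuracy over
    ``k_grid`` (default odd values 1..min(15, n-1)).  ``standardize=False``
    keeps raw feature scales (centre 0, scale 1).
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels, dtype=int)
    n, d = features.shape
    if n == 0:
        raise ValidationError("features", "training set is empty")
    if labels.shape != (n,):
        raise ValidationError("labels", "one label per training row required")
    if standardize:
        center, scale = _fit_scaler(features)
    else:
        center, scale = np.zeros(d), np.ones(d)
    z = (features - center) / scale
    order = FEATURE_NAMES if d == len(FEATURE_NAMES) else tuple(
        f"f{i}" for i in range(d)
    )
    if k is None:
        if n == 1:
            k = 1
        else:
            k, _ = select_k(features, labels, k_grid, standardize=standardize)
    return TrainedModel(z, labels, center, scale, int(k), order)


def predict(model: TrainedModel, x):
    """Classify one raw feature point.

    Returns ``(label, vote_fraction, neighbor_ids)`` where vote_fraction
    is the winning share of the k votes and neighbor_ids the training-row
    indices consulted, nearest first.
    """
    z = model.standardize(np.asarray(x, dtype=float))
    if z.ndim != 1:
        raise ValidationError("x", "predict takes a single feature point")
    return _vote(model, z)


def select_k(features, labels, k_grid=None, standardize: bool = True):
    """Accuracy-plot K selection: leave-one-out accuracy over a k grid.

    Returns ``(best_k, curve)`` with ``curve`` a list of (k, accuracy)
    pairs; the smallest k wins ties.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels, dtype=int)
    n = features.shape[0]
    if n < 2:
        raise ValidationError("features", "k selection needs >= 2 rows")
    if k_grid is None:
        k_grid = list(range(1, min(15, n - 1) + 1, 2))
    k_grid = [int(k) for k in k_grid]
    if not k_grid:
        raise ValidationError("k_grid", "grid is empty")
    if any(k < 1 or k > n - 1 for k in k_grid):
        raise ValidationError("k_grid", "grid values must lie in [1, n-1]")

    if standardize:
        center, scale = _fit_scaler(features)
    else:
        center, scale = np.zeros(features.shape[1]), np.ones(features.shape[1])
    z = (features - center) / scale

    curve = []
    best_k, best_acc = None, -1.0
    for k in sorted(k_grid):
        model = TrainedModel(z, labels, np.zeros_like(center),
                             np.ones_like(scale), k)
        correct = 0
        for i in range(n):
            pred, _, _ = _vote(model, z[i], exclude=i)
            correct += pred == labels[i]
        acc = correct / n
        curve.append((k, acc))
        if acc > best_acc:
            best_k, best_acc = k, acc
    return best_k, curve


def evaluate(model: TrainedModel, test_features, test_labels):
    """Accuracy, sensitivity, specificity and the 2x2 confusion matrix.

    Melanoma (label 1) is the positive class.  The confusion matrix is
    ``[[TN, FP], [FN, TP]]`` (rows: true label 0/1, columns: predicted).
    """
    test_features = np.atleast_2d(np.asarray(test_features, dtype=float))
    test_labels = np.asarray(test_labels, dtype=int)
    if test_features.shape[0] == 0:
        raise ValidationError("test_features", "test set is empty")
    if not np.all(np.isin(test_labels, (0, 1))):
        raise ValidationError("test_labels", "labels must be 0 or 1")
    cm = np.zeros((2, 2), dtype=int)
    for x, y in zip(test_features, test_labels):
        pred, _, _ = predict(model, x)
        cm[y, pred] += 1
    tn, fp, fn, tp = cm[0, 0], cm[0, 1], cm[1, 0], cm[1, 1]
    total = cm.sum()
    accuracy = (tp + tn) / total
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")
    return float(accuracy), float(sensitivity), float(specificity), cm


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialise the model as versioned JSON (format documented in docs)."""
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "feature_order": list(model.feature_order),
        "center": model.center.tolist(),
        "scale": model.scale.tolist(),
        "train_matrix": model.train_matrix.tolist(),
        "labels": model.labels.tolist(),
        "k": int(model.k),
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_model(path: str | Path) -> TrainedModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValidationError("format_version",
                              f"unsupported model format {doc.get('format_version')}")
    return TrainedModel(
        np.asarray(doc["train_matrix"], dtype=float),
        np.asarray(doc["labels"], dtype=int),
        np.asarray(doc["center"], dtype=float),
        np.asarray(doc["scale"], dtype=float),
        int(doc["k"]),
        tuple(doc["feature_order"]),
    )
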