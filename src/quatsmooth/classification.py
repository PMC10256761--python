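"""DTW-based k-nearest-neighbour classification of quaternion series.

Dynamic time warping aligns two series by a monotone warping path and
sums a local cost over the aligned pairs; here the local cost is the
rotation-geodesic distance on :math:`H_1`, which respects the q/-q
ambiguity (a Euclidean 4-vector cost is available for sensitivity
checks).  Classification is a plurality vote of the k nearest training
series; the fraction of positive-label neighbours serves as a
probabilistic score for ROC/AUC purposes.

The DP recurrence is the classic symmetric one with unit step weights
and no warping window:

    D(i, j) = cost(i, j) + min(D(i-1, j), D(i, j-1), D(i-1, j-1))
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from numba import njit
from scipy.stats import rankdata

from .quaternions import QuaternionSeries

__all__ = [
    "LabeledDataset",
    "compute_auc",
    "cross_validate",
    "dtw_distance",
    "knn_predict",
    "pairwise_dtw",
]


@dataclass
class LabeledDataset:
    """Series with one binary class label and one identifier each."""

    series: list
    labels: np.ndarray
    ids: list

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not (len(self.series) == len(self.labels) == len(self.ids)):
            raise ValueError("series, labels and ids must have equal length")

    def __len__(self) -> int:
        return len(self.series)

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def quaternion_array(self) -> np.ndarray:
        """Stack equal-length series into an (n, N, 4) array."""
        return np.stack([np.asarray(getattr(s, "q", s), dtype=float) for s in self.series])


@njit(cache=False)
def _dtw_dp(cost: np.ndarray) -> float:
    n, m = cost.shape
    acc = np.empty((n + 1, m + 1))
    acc[:, :] = np.inf
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = acc[i - 1, j - 1]
            if acc[i - 1, j] < best:
                best = acc[i - 1, j]
            if acc[i, j - 1] < best:
                best = acc[i, j - 1]
            acc[i, j] = cost[i - 1, j - 1] + best
    return acc[n, m]


def _as_qarray(s) -> np.ndarray:
    q = np.asarray(getattr(s, "q", s), dtype=float)
    if q.ndim == 1:
        q = q[None, :]
    if q.size == 0:
        raise ValueError("DTW needs non-empty series")
    if q.shape[-1] != 4:
        raise ValueError("expected quaternion series with trailing dimension 4")
    return q


def _cost_matrix(a: np.ndarray, b: np.ndarray, metric: str) -> np.ndarray:
    if metric == "geodesic":
        dots = np.abs(a @ b.T)
        return 2.0 * np.arccos(np.minimum(1.0, dots))
    if metric == "euclidean":
        diff = a[:, None, :] - b[None, :, :]
        return np.sqrt(np.sum(diff * diff, axis=-1))
    raise ValueError(f"unknown DTW local metric {metric!r}")


def dtw_distance(a, b, *, metric: str = "geodesic") -> float:
    """DTW distance between two quaternion series (no window).

    Accepts :class:`QuaternionSeries` or raw ``(N, 4)`` arrays; the local
    cost is the geodesic distance by default.
    """
    qa, qb = _as_qarray(a), _as_qarray(b)
    return float(_dtw_dp(_cost_matrix(qa, qb, metric)))


def pairwise_dtw(series: Sequence, *, metric: str = "geodesic") -> np.ndarray:
    """Symmetric matrix of DTW distances between all series pairs."""
    arrays = [_as_qarray(s) for s in series]
    n = len(arrays)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = _dtw_dp(_cost_matrix(arrays[i], arrays[j], metric))
    return out


def _positive_label(classes: np.ndarray):
    if len(classes) != 2:
        raise ValueError(f"expected exactly two classes, got {list(classes)}")
    return classes[1]


def knn_predict(
    train: LabeledDataset,
    query,
    k: int = 5,
    *,
    distances: Optional[np.ndarray] = None,
    metric: str = "geodesic",
):
    """Plurality-vote k-NN prediction for one query series.

    Returns ``(label, score)`` where ``score`` is the fraction of the k
    nearest training series carrying the positive label (the larger of
    the two label values under sorting).  Distance ties are broken by
    training-set order (stable sort); vote ties go to the negative label.
    ``distances`` may supply precomputed query-to-train distances.
    """
    if k > len(train):
        raise ValueError(f"k={k} exceeds the training-set size {len(train)}")
    if distances is None:
        distances = np.array([dtw_distance(query, s, metric=metric) for s in train.series])
    order = np.argsort(distances, kind="stable")[:k]
    classes = train.classes
    pos = _positive_label(classes)
    score = float(np.mean(train.labels[order] == pos))
    label = pos if score > 0.5 else classes[0]
    return label, score


def compute_auc(scores, labels) -> float:
    """Area under the ROC curve by the rank (Mann–Whitney) formula.

    Tied scores receive midranks, i.e. tied positive/negative pairs count
    one half; requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("AUC needs both classes present")
    pos = labels == classes[1]
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _stratified_folds(labels: np.ndarray, ids: list, n_folds: int, seed: int) -> np.ndarray:
    """Fold assignment stratified by label, a function of (id, label) only
    so that reordering the dataset does not change the splits."""
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = idx[np.argsort(np.asarray(ids, dtype=object)[idx], kind="stable")]
        idx = idx[rng.permutation(len(idx))]
        assignment[idx] = np.arange(len(idx)) % n_folds
    return assignment


def cross_validate(
    data: LabeledDataset,
    k: int = 5,
    n_folds: int = 5,
    seed: int = 0,
    *,
    distances: Optional[np.ndarray] = None,
    metric: str = "geodesic",
) -> tuple[float, float]:
    """Stratified n-fold CV of the DTW k-NN classifier.

    Returns fold-averaged (accuracy, AUC).  The full pairwise DTW matrix
    is computed once (or taken from ``distances``) and sliced per fold.
    A test fold containing a single class has no defined AUC; it is
    dropped from the AUC average with a warning.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    classes = data.classes
    pos = _positive_label(classes)
    if distances is None:
        distances = pairwise_dtw(data.series, metric=metric)
    folds = _stratified_folds(data.labels, data.ids, n_folds, seed)

    accuracies, aucs = [], []
    for f in range(n_folds):
        test_idx = np.flatnonzero(folds == f)
        train_idx = np.flatnonzero(folds != f)
        if len(train_idx) < k:
            raise ValueError(f"fold {f}: training part smaller than k={k}")
        train_labels = data.labels[train_idx]
        preds, scores = [], []
        for i in test_idx:
            order = np.argsort(distances[i, train_idx], kind="stable")[:k]
            score = float(np.mean(train_labels[order] == pos))
            preds.append(pos if score > 0.5 else classes[0])
            scores.append(score)
        accuracies.append(float(np.mean(np.asarray(preds) == data.labels[test_idx])))
        test_labels = data.labels[test_idx]
        if len(np.unique(test_labels)) == 2:
            aucs.append(compute_auc(scores, test_labels))
        else:
            warnings.warn(
                f"fold {f} contains a single class; its AUC is undefined and "
                "excluded from the average",
                RuntimeWarning,
                stacklevel=2,
            )
    return float(np.mean(accuracies)), float(np.mean(aucs)) if aucs else float("nan")
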