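"""Wrapper feature selection: position decoding and the KNN-based fitness.

A wolf's continuous position in [0,1]^M is decoded into a binary feature
mask (threshold 0.5); the mask is scored by the weighted two-objective
fitness

    fitness = w1 * KNN_accuracy + w2 * feature_term,     w1 + w2 = 1,

with w1 = 0.9, w2 = 0.1 by default.  The feature term defaults to the
*reduction* ratio (M - |S|) / M, which rewards small subsets under
maximization; the literal ratio |S| / M is selectable.

Accuracy is measured by a k-nearest-neighbor classifier on binary data,
where squared Euclidean distance coincides with Hamming distance; ties in
the class vote are broken by the single nearest neighbor's label, and equal
distances are resolved toward the lowest training index so predictions are
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import train_test_split

__all__ = [
    "FitnessSpec",
    "binarize",
    "knn_predict",
    "fitness",
    "WrapperObjective",
]


@dataclass(frozen=True)
class FitnessSpec:
    """Weights and settings of the two-objective fitness."""

    w1: float = 0.9
    w2: float = 0.1
    k_neighbors: int = 5
    feature_term: str = "reduction"  # or "literal" = |S| / M
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if abs(self.w1 + self.w2 - 1.0) > 1e-12:
            raise ValueError("fitness weights must sum to 1")
        if self.feature_term not in ("reduction", "literal"):
            raise ValueError(f"unknown feature_term {self.feature_term!r}")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def binarize(position: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Decode a continuous position into a boolean feature mask.

    Feature j is selected iff position_j > threshold.  If nothing clears the
    threshold the single largest coordinate is selected (first index on
    ties), so a mask used for classification is never empty.
    """
    position = np.asarray(position, dtype=float)
    mask = position > threshold
    if not mask.any():
        mask = np.zeros(position.shape, dtype=bool)
        mask[int(np.argmax(position))] = True
    return mask


def knn_predict(
    train_matrix: np.ndarray,
    train_labels: np.ndarray,
    queries: np.ndarray,
    k: int,
) -> np.ndarray:
    """Majority-vote KNN on binary rows under Hamming distance.

    For binary vectors, hamming(q, t) = sum(q) + sum(t) - 2 q.t, which a
    single matrix product computes for all pairs.  Neighbors at equal
    distance are ordered by training index; an even vote split falls back to
    the nearest neighbor's label.
    """
    train_matrix = np.asarray(train_matrix)
    queries = np.atleast_2d(np.asarray(queries))
    train_labels = np.asarray(train_labels)
    n_train = train_matrix.shape[0]
    if n_train == 0:
        raise ValueError("empty training set")
    if not 1 <= k <= n_train:
        raise ValueError(f"k={k} must lie in [1, {n_train}]")

    T = train_matrix.astype(np.float64)
    Q = queries.astype(np.float64)
    dist = Q.sum(axis=1)[:, None] + T.sum(axis=1)[None, :] - 2.0 * (Q @ T.T)
    nearest = np.argsort(dist, axis=1, kind="stable")[:, :k]
    votes = train_labels[nearest]
    ones = votes.sum(axis=1)
    pred = np.where(2 * ones > k, 1, 0)
    tie = 2 * ones == k
    if tie.any():
        pred[tie] = train_labels[nearest[tie, 0]]
    return pred.astype(train_labels.dtype)


def _feature_term(mask: np.ndarray, kind: str) -> float:
    m = mask.size
    s = int(mask.sum())
    if kind == "reduction":
        return (m - s) / m
    return s / m


def fitness(
    mask: np.ndarray,
    train_X: np.ndarray,
    train_y: np.ndarray,
    val_X: np.ndarray,
    val_y: np.ndarray,
    spec: FitnessSpec = FitnessSpec(),
) -> float:
    """Score one feature mask: w1 * validation accuracy + w2 * feature term."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty feature mask; apply binarize's guard first")
    pred = knn_predict(train_X[:, mask], train_y, val_X[:, mask], spec.k_neighbors)
    acc = float(np.mean(pred == val_y))
    return spec.w1 * acc + spec.w2 * _feature_term(mask, spec.feature_term)


class WrapperObjective:
    """Callable objective mapping a wolf position to a fitness value.

    By default a validation portion (``val_fraction``, stratified, seeded)
    is held out from the supplied training data and fitness is scored
    against it, keeping the final test set untouched during the search.
    Passing an explicit ``validation=(X, y)`` pair instead scores against
    that set — e.g. the test split, reproducing protocols that tune
    directly against it (at the cost of leakage).
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        spec: FitnessSpec = FitnessSpec(),
        val_fraction: float = 0.25,
        seed: int = 0,
        validation: tuple[np.ndarray, np.ndarray] | None = None,
    ) -> None:
        X = np.asarray(X)
        y = np.asarray(y)
        self.spec = spec
        if validation is not None:
            self.train_X, self.train_y = X, y
            self.val_X, self.val_y = (np.asarray(v) for v in validation)
        else:
            self.train_X, self.val_X, self.train_y, self.val_y = train_test_split(
                X, y, test_size=val_fraction, stratify=y, random_state=seed
            )
        self.n_features = X.shape[1]

    def mask_of(self, position: np.ndarray) -> np.ndarray:
        return binarize(position, self.spec.threshold)

    def evaluate_mask(self, mask: np.ndarray) -> dict:
        mask = np.asarray(mask, dtype=bool)
        pred = knn_predict(
            self.train_X[:, mask], self.train_y, self.val_X[:, mask], self.spec.k_neighbors
        )
        acc = float(np.mean(pred == self.val_y))
        term = _feature_term(mask, self.spec.feature_term)
        return {
            "accuracy": acc,
            "feature_term": term,
            "n_selected": int(mask.sum()),
            "fitness": self.spec.w1 * acc + self.spec.w2 * term,
        }

    def __call__(self, position: np.ndarray) -> float:
        return self.evaluate_mask(self.mask_of(position))["fitness"]
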