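"""SMOTE oversampling and stratified data-splitting utilities.

All splitters are stratified so that every fold/subsample preserves the
majority:minority ratio of the full data (within integer rounding), which
keeps the class-imbalance ratio of training subsets equal to the original.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import InvalidInputError, ParameterError

__all__ = [
    "FoldPlan",
    "smote",
    "stratified_kfold",
    "loocv_indices",
    "stratified_subsample",
]


@dataclass(frozen=True)
class FoldPlan:
    """Fold index per sample for stratified k-fold cross validation."""

    assignments: np.ndarray
    n_folds: int

    def split(self):
        """Yield (train_idx, test_idx) pairs, one per fold."""
        for k in range(self.n_folds):
            test = np.flatnonzero(self.assignments == k)
            train = np.flatnonzero(self.assignments != k)
            yield train, test


def _class_indices(y):
    y = np.asarray(y)
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == -1)
    if idx_pos.size == 0 or idx_neg.size == 0:
        raise InvalidInputError("both classes (-1/+1) must be present")
    return idx_neg, idx_pos


def smote(X, y, k: int = 5, target_ratio: float = 1.0, seed=None):
    """Oversample the minority class with synthetic interpolated points.

    Each synthetic point is ``x + u * (x_nn - x)`` with ``u ~ Uniform(0, 1)``
    and ``x_nn`` one of the ``k`` nearest minority neighbors of the minority
    point ``x`` (Euclidean distance on the raw feature scale).  Enough
    synthetics are appended to bring the majority:minority ratio down to
    ``target_ratio`` (default 1.0, i.e. balanced).  Original rows are never
    modified; synthetic rows are appended after them with label +1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    idx_neg, idx_pos = _class_indices(y)
    n_min = idx_pos.size
    if not k >= 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if n_min <= k:
        raise ParameterError(
            f"minority count ({n_min}) must exceed the number of neighbors k={k}"
        )
    if target_ratio <= 0:
        raise ParameterError("target_ratio must be positive")

    n_needed = int(round(idx_neg.size / target_ratio)) - n_min
    if n_needed <= 0:
        return X.copy(), y.copy()

    rng = np.random.default_rng(seed)
    X_min = X[idx_pos]

    # k nearest minority-only neighbors of each minority point (self excluded)
    d = cdist(X_min, X_min)
    np.fill_diagonal(d, np.inf)
    nn = np.argsort(d, axis=1, kind="stable")[:, :k]

    # distribute the synthetic quota over minority points; remainders by
    # seeded random choice
    base, extra = divmod(n_needed, n_min)
    quota = np.full(n_min, base, dtype=int)
    if extra:
        quota[rng.choice(n_min, size=extra, replace=False)] += 1

    synth = np.empty((n_needed, X.shape[1]))
    row = 0
    for i in range(n_min):
        for _ in range(quota[i]):
            j = nn[i, rng.integers(k)]
            u = rng.uniform()
            synth[row] = X_min[i] + u * (X_min[j] - X_min[i])
            row += 1

    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.ones(n_needed, dtype=y.dtype)])
    return X_out, y_out


def stratified_kfold(y, n_folds: int, seed=None) -> FoldPlan:
    """Assign samples to ``n_folds`` folds, stratified by class.

    Within each class the (seeded) shuffled indices are dealt round-robin, so
    fold class counts differ by at most one and every fold's class ratio
    matches the full data within rounding.
    """
    y = np.asarray(y)
    idx_neg, idx_pos = _class_indices(y)
    if n_folds < 2:
        raise ParameterError("n_folds must be >= 2")
    for name, idx in (("minority", idx_pos), ("majority", idx_neg)):
        if idx.size < n_folds:
            raise ParameterError(
                f"{name} class has {idx.size} samples, fewer than n_folds={n_folds}"
            )
    rng = np.random.default_rng(seed)
    assignments = np.empty(y.size, dtype=int)
    for idx in (idx_neg, idx_pos):
        perm = rng.permutation(idx)
        assignments[perm] = np.arange(perm.size) % n_folds
    return FoldPlan(assignments=assignments, n_folds=n_folds)


def loocv_indices(n: int):
    """Leave-one-out splits: n pairs (train, test) with singleton test sets."""
    if n < 2:
        raise ParameterError("leave-one-out needs n >= 2")
    all_idx = np.arange(n)
    return [
        (np.concatenate([all_idx[:i], all_idx[i + 1:]]), np.array([i]))
        for i in range(n)
    ]


def stratified_subsample(y, fraction: float, seed=None) -> np.ndarray:
    """Draw ``floor(fraction * count)`` samples per class without replacement.

    Equal per-class fractions keep the subsample's imbalance ratio equal to
    the full data's.  Returns sorted sample indices.
    """
    if not 0 < fraction <= 1:
        raise ParameterError(f"fraction must be in (0, 1], got {fraction}")
    y = np.asarray(y)
    idx_neg, idx_pos = _class_indices(y)
    rng = np.random.default_rng(seed)
    chosen = []
    for name, idx in (("majority", idx_neg), ("minority", idx_pos)):
        m = int(np.floor(fraction * idx.size)) if fraction < 1 else idx.size
        if m < 1:
            raise ParameterError(
                f"fraction={fraction} draws no {name} samples "
                f"(class size {idx.size}); need fraction >= {1 / idx.size:.4f}"
            )
        chosen.append(rng.choice(idx, size=m, replace=False))
    return np.sort(np.concatenate(chosen))
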