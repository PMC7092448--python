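"""Filter baselines and alternative embedded tuning criteria.

Four univariate filters (Fisher score, Relief, per-feature ROC and PR areas)
plus accuracy- and ROC-driven grid tuning of the same sparse SVM swept by the
Hellinger-distance selector, for head-to-head comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from . import metrics, sparse_svm
from .core import TuningGrid, sweep_grid, tune_models
from .exceptions import InvalidInputError
from .sparse_svm import PenaltyConfig, SvmModel

__all__ = [
    "FeatureScores",
    "fisher_score",
    "relief_weights",
    "aucroc_filter",
    "aucprc_filter",
    "tune_by_acc",
    "tune_by_roc",
    "export_scores",
]


@dataclass(frozen=True)
class FeatureScores:
    """Per-feature relevance scores; larger means more important."""

    values: np.ndarray
    higher_is_better: bool = True
    method: str = ""

    def ranking(self) -> np.ndarray:
        v = self.values if self.higher_is_better else -self.values
        return np.argsort(-v, kind="stable")


def _split_classes(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    X0 = X[y == -1]
    X1 = X[y == 1]
    if X0.shape[0] == 0 or X1.shape[0] == 0:
        raise InvalidInputError("both classes must be present")
    return X0, X1


def fisher_score(X, y) -> FeatureScores:
    """Per-feature |mean difference| over the summed class variances.

    F_j = |mu_1j - mu_0j| / (var_1j + var_0j), with sample (unbiased)
    variances.  A zero denominator yields +inf when the class means differ
    and 0 when they coincide.
    """
    X0, X1 = _split_classes(X, y)
    if X0.shape[0] < 2 or X1.shape[0] < 2:
        raise InvalidInputError("need >= 2 samples per class for variances")
    num = np.abs(X1.mean(axis=0) - X0.mean(axis=0))
    den = X1.var(axis=0, ddof=1) + X0.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(den > 0, num / np.where(den > 0, den, 1.0),
                        np.where(num > 0, np.inf, 0.0))
    return FeatureScores(values=vals, method="fisher")


def relief_weights(X, y, m: int | None = None, seed=None) -> FeatureScores:
    """Relief: reward features that separate nearest miss from nearest hit.

    For each of ``m`` sampled points the weight of feature j is updated by
    ``- (x_j - nearhit_j)^2 + (x_j - nearmiss_j)^2`` where the nearest hit
    (same class) and miss (other class) are found by Euclidean distance.
    Default m equals n (one deterministic pass over every sample); m > n
    cycles through reshuffled passes.  Reproducible given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    for cls in (-1, 1):
        if np.sum(y == cls) < 2:
            raise InvalidInputError(
                f"class {cls:+d} needs >= 2 samples so a nearest hit exists"
            )
    if m is None:
        m = n

    d = cdist(X, X)
    np.fill_diagonal(d, np.inf)
    same = y[:, None] == y[None, :]
    d_hit = np.where(same, d, np.inf)
    d_miss = np.where(~same, d, np.inf)
    nearhit = np.argmin(d_hit, axis=1)
    nearmiss = np.argmin(d_miss, axis=1)

    rng = np.random.default_rng(seed)
    w = np.zeros(p)
    drawn = 0
    while drawn < m:
        order = rng.permutation(n)
        for i in order:
            w -= (X[i] - X[nearhit[i]]) ** 2
            w += (X[i] - X[nearmiss[i]]) ** 2
            drawn += 1
            if drawn == m:
                break
    return FeatureScores(values=w, method="relief")


def aucroc_filter(X, y) -> FeatureScores:
    """Per-feature lower-trapezoid ROC area using the raw column as score.

    Orientation-corrected to max(a, 1-a) so a feature separating classes in
    either direction scores highly.
    """
    X = np.asarray(X, dtype=float)
    vals = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        a = metrics.auc_roc_lower_trapezoid(X[:, j], y)
        vals[j] = max(a, 1.0 - a)
    return FeatureScores(values=vals, method="aucroc")


def aucprc_filter(X, y) -> FeatureScores:
    """Per-feature PR area on the raw column; the better of both
    orientations (column and negated column) is kept."""
    X = np.asarray(X, dtype=float)
    vals = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        a_up = metrics.auc_prc(X[:, j], y)
        a_dn = metrics.auc_prc(-X[:, j], y)
        vals[j] = max(a_up, a_dn)
    return FeatureScores(values=vals, method="aucprc")


def acc_criterion(scores: np.ndarray, y: np.ndarray, model: SvmModel) -> float:
    """In-sample classification accuracy of the thresholded scores."""
    pred = np.where(scores > 0, 1, -1)
    return float(np.mean(pred == np.asarray(y)))


def roc_criterion(scores: np.ndarray, y: np.ndarray, model: SvmModel) -> float:
    """In-sample lower-trapezoid ROC area of the scores."""
    if model.support_count == 0:
        return 0.5  # constant scores: the two-point chance curve
    return metrics.auc_roc_lower_trapezoid(scores, y)


def tune_by_acc(
    X, y, grid: TuningGrid | None = None, **solver_kw
) -> tuple[PenaltyConfig, SvmModel, float]:
    """Grid sweep identical to the HD tuner but maximizing training accuracy."""
    X = np.asarray(X, dtype=float)
    if grid is None:
        grid = TuningGrid.default(X, y)
    models = sweep_grid(X, y, grid, **solver_kw)
    return tune_models(models, X, y, acc_criterion)


def tune_by_roc(
    X, y, grid: TuningGrid | None = None, **solver_kw
) -> tuple[PenaltyConfig, SvmModel, float]:
    """Grid sweep identical to the HD tuner but maximizing training AUCROC."""
    X = np.asarray(X, dtype=float)
    if grid is None:
        grid = TuningGrid.default(X, y)
    models = sweep_grid(X, y, grid, **solver_kw)
    return tune_models(models, X, y, roc_criterion)


def export_scores(scores: FeatureScores, feature_names, path) -> None:
    """Write a TSV with columns feature_id, score, rank."""
    order = scores.ranking()
    names = list(feature_names)
    if len(names) != len(scores.values):
        raise InvalidInputError("feature_names length must match scores")
    with open(path, "w") as fh:
        fh.write("feature_id\tscore\trank\n")
        for rank, j in enumerate(order, start=1):
            fh.write(f"{names[j]}\t{scores.values[j]:.6g}\t{rank}\n")
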