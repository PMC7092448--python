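"""Stable sparse feature selection driven by the Hellinger distance.

The selector tunes an elastic-net SVM over a (lambda, alpha) grid by
maximizing the sample Hellinger distance between the two classes' in-sample
decision scores, repeats that tuning over many stratified subsamples, and
aggregates per-run supports into inclusion frequencies

    f_j = (1/K) * sum_k 1[beta_j^(k) != 0]

which induce the final feature ranking (most frequently included first).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import sparse_svm
from .exceptions import InvalidInputError, NoInformativeFitError, ParameterError
from .hellinger import ScoreSplit, hellinger_from_scores
from .resampling import stratified_subsample
from .sparse_svm import PenaltyConfig, SvmModel

__all__ = [
    "TuningGrid",
    "StabilityResult",
    "tune_by_hd",
    "stability_select",
    "rank_features",
    "select_top_q",
    "export_ranking",
]

DEFAULT_ALPHAS = tuple(round(0.1 * i, 1) for i in range(1, 11))  # 0.1 .. 1.0
DEFAULT_N_LAMBDAS = 30
DEFAULT_LAMBDA_MIN_RATIO = 0.01


@dataclass(frozen=True)
class TuningGrid:
    """Cross product of penalty strengths and elastic-net mixes to sweep.

    ``lambdas`` must be strictly decreasing (a path from the all-zero model
    downwards, enabling warm starts) and are anchored at alpha=1; because the
    all-zero threshold scales exactly as lambda_max(alpha) =
    lambda_max(1)/alpha, each alpha's path is swept at ``lambdas / alpha`` so
    every path spans the same relative range below its own all-zero point.
    ``alphas`` lie in (0, 1].
    """

    lambdas: tuple
    alphas: tuple

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambdas, dtype=float)
        alp = np.asarray(self.alphas, dtype=float)
        if lam.size == 0 or alp.size == 0:
            raise ParameterError("grid must contain at least one lambda and alpha")
        if (lam <= 0).any():
            raise ParameterError("lambdas must be positive")
        if lam.size > 1 and not (np.diff(lam) < 0).all():
            raise ParameterError("lambdas must be strictly decreasing")
        if ((alp <= 0) | (alp > 1)).any():
            raise ParameterError("alphas must lie in (0, 1]")
        object.__setattr__(self, "lambdas", tuple(float(v) for v in lam))
        object.__setattr__(self, "alphas", tuple(float(v) for v in alp))

    @classmethod
    def default(
        cls,
        X,
        y,
        *,
        alphas=DEFAULT_ALPHAS,
        n_lambdas: int = DEFAULT_N_LAMBDAS,
        lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
        gamma: float = sparse_svm.DEFAULT_GAMMA,
    ) -> "TuningGrid":
        """Data-driven default: log-spaced lambdas from lambda_max down to
        ``lambda_min_ratio * lambda_max`` (computed at alpha=1), crossed with
        ``alphas``."""
        lmax = sparse_svm.lambda_max(X, y, alpha=1.0, gamma=gamma)
        lambdas = np.geomspace(lmax, lambda_min_ratio * lmax, n_lambdas)
        return cls(lambdas=tuple(lambdas), alphas=tuple(alphas))


@dataclass
class StabilityResult:
    """Inclusion frequencies over K subsampling runs and the induced ranking."""

    frequencies: np.ndarray
    runs: int
    per_run_supports: list = field(default_factory=list)
    chosen_params: list = field(default_factory=list)

    @property
    def ranking(self) -> np.ndarray:
        return rank_features(self)


def sweep_grid(X, y, grid: TuningGrid, **solver_kw) -> list[SvmModel]:
    """Fit the elastic-net SVM at every grid point.

    Returns one model per (alpha, lambda) pair, warm-started along each
    alpha's lambda path.  Shared by all tuning criteria so that comparisons
    between criteria reuse identical fits.
    """
    models: list[SvmModel] = []
    lambdas = np.asarray(grid.lambdas)
    for alpha in grid.alphas:
        models.extend(
            sparse_svm.fit_path(X, y, alpha, lambdas=lambdas / alpha, **solver_kw)
        )
    return models


def cross_fit_scores(
    X, y, grid: TuningGrid, n_folds: int = 3, seed=None, **solver_kw
) -> np.ndarray:
    """Out-of-fold decision scores for every grid point.

    Fits the full warm-started grid on each fold's training complement and
    scores the held-out fold, giving honest decision scores aligned with the
    model order of :func:`sweep_grid`.  Returns an array of shape
    (n_grid_points, n_samples).
    """
    from .resampling import stratified_kfold

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    plan = stratified_kfold(y, n_folds, seed=seed)
    n_grid = len(grid.lambdas) * len(grid.alphas)
    out = np.empty((n_grid, len(y)))
    for train, test in plan.split():
        fold_models = sweep_grid(X[train], y[train], grid, **solver_kw)
        for k, m in enumerate(fold_models):
            out[k, test] = sparse_svm.decision_scores(m, X[test])
    return out


def hd_criterion(scores: np.ndarray, y: np.ndarray, model: SvmModel) -> float:
    """Hellinger distance of class-split scores; 0 for degenerate fits."""
    if model.support_count == 0:
        return 0.0
    return hellinger_from_scores(ScoreSplit.from_labels(scores, y))


def tune_models(
    models, X, y, criterion, scores_list=None, prefer: str = "sparse"
) -> tuple[PenaltyConfig, SvmModel, float]:
    """Pick the best of pre-fitted models under a criterion(scores, y, model).

    ``scores_list`` optionally supplies the score vector per model (e.g.
    cross-fitted scores); by default in-sample decision scores are used.
    With ``prefer="sparse"`` ties are broken toward fewer nonzero
    coefficients, then larger lambda, then larger alpha (parsimony first);
    ``prefer="dense"`` mirrors the rule, favouring the least-penalized model
    among ties.  Both are deterministic.
    """
    if prefer not in ("sparse", "dense"):
        raise ParameterError("prefer must be 'sparse' or 'dense'")
    sign = 1.0 if prefer == "sparse" else -1.0
    y = np.asarray(y)
    best = None
    best_key = None
    any_informative = False
    for k, model in enumerate(models):
        if scores_list is None:
            scores = sparse_svm.decision_scores(model, X)
        else:
            scores = scores_list[k]
        value = criterion(scores, y, model)
        if model.support_count > 0:
            any_informative = True
        key = (
            value,
            -sign * model.support_count,
            sign * model.penalty.lam,
            sign * model.penalty.alpha,
        )
        if best_key is None or key > best_key:
            best, best_key = model, key
    if not any_informative:
        raise NoInformativeFitError(
            "every grid point produced a degenerate (all-zero) fit; "
            "extend the lambda grid downwards"
        )
    return best.penalty, best, float(best_key[0])


def tune_by_hd(
    X,
    y,
    grid: TuningGrid | None = None,
    score_mode: str = "cv",
    cv_folds: int = 3,
    cv_seed=0,
    **solver_kw,
) -> tuple[PenaltyConfig, SvmModel, float]:
    """Grid-search (lambda, alpha) maximizing the class-split score HD.

    Fits every grid point and evaluates the plug-in Hellinger distance
    between the two classes' decision scores.  By default the scores are
    *cross-fitted* (out-of-fold predictions from ``cv_folds`` stratified
    folds): in-sample scores of any near-separating fit saturate the
    distance and reward overfitted dense models, whereas honest scores peak
    at the informative support.  ``score_mode="insample"`` evaluates the
    training-data scores of each fit instead.  Degenerate fits (beta = 0,
    constant scores) score 0 and cannot win against any informative fit.
    """
    X = np.asarray(X, dtype=float)
    if grid is None:
        grid = TuningGrid.default(X, y)
    if score_mode not in ("cv", "insample"):
        raise ParameterError("score_mode must be 'cv' or 'insample'")
    models = sweep_grid(X, y, grid, **solver_kw)
    scores_list = None
    if score_mode == "cv":
        scores_list = cross_fit_scores(
            X, y, grid, n_folds=cv_folds, seed=cv_seed, **solver_kw
        )
    return tune_models(models, X, y, hd_criterion, scores_list=scores_list)


def stability_select(
    X,
    y,
    grid: TuningGrid | None = None,
    K: int = 100,
    fraction: float = 0.5,
    seed=None,
    score_mode: str = "cv",
    cv_folds: int = 3,
    **solver_kw,
) -> StabilityResult:
    """Stability selection: re-tune on K stratified subsamples and count
    how often each feature's coefficient is nonzero.

    Every subsample draws the same fraction from each class, preserving the
    imbalance ratio.  The HD tuning inside each subsample uses cross-fitted
    scores by default (see :func:`tune_by_hd`); if a subsample's smaller
    class cannot populate ``cv_folds`` folds, in-sample scores are used for
    that run.  Fully reproducible given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if K < 1:
        raise ParameterError("K must be >= 1")
    if not 0 < fraction < 1:
        raise ParameterError(f"fraction must be in (0, 1), got {fraction}")
    n_min = int(np.sum(y == 1))
    n_maj = int(np.sum(y == -1))
    if n_min == 0 or n_maj == 0:
        raise InvalidInputError("both classes must be present")
    min_frac = 2.0 / min(n_min, n_maj)
    if int(np.floor(fraction * min(n_min, n_maj))) < 2:
        raise ParameterError(
            f"fraction={fraction} leaves fewer than 2 samples in the smaller "
            f"class; need fraction >= {min_frac:.4f}"
        )
    if grid is None:
        grid = TuningGrid.default(X, y)

    rng = np.random.default_rng(seed)
    p = X.shape[1]
    counts = np.zeros(p)
    supports: list[np.ndarray] = []
    params: list[PenaltyConfig] = []
    sub_min = int(np.floor(fraction * min(n_min, n_maj)))
    for _ in range(K):
        sub_seed = int(rng.integers(0, 2**63 - 1))
        idx = stratified_subsample(y, fraction, seed=sub_seed)
        mode = score_mode if (score_mode == "cv" and sub_min >= cv_folds >= 2) \
            else "insample"
        cfg, model, _ = tune_by_hd(
            X[idx], y[idx], grid,
            score_mode=mode, cv_folds=cv_folds, cv_seed=sub_seed,
            **solver_kw,
        )
        support = model.support
        counts[support] += 1
        supports.append(support)
        params.append(cfg)
    return StabilityResult(
        frequencies=counts / K,
        runs=K,
        per_run_supports=supports,
        chosen_params=params,
    )


def rank_features(res: StabilityResult) -> np.ndarray:
    """Feature indices sorted by decreasing inclusion frequency.

    The sort is stable, so equal frequencies fall back to index order.
    """
    return np.argsort(-np.asarray(res.frequencies), kind="stable")


def select_top_q(res: StabilityResult, q: int) -> np.ndarray:
    """The q highest-ranked feature indices."""
    p = len(res.frequencies)
    if not 1 <= q <= p:
        raise ParameterError(f"q must be in [1, {p}], got {q}")
    return rank_features(res)[:q]


def export_ranking(res: StabilityResult, feature_names, path) -> None:
    """Write a TSV with columns feature_id, inclusion_frequency, rank."""
    order = rank_features(res)
    names = list(feature_names)
    if len(names) != len(res.frequencies):
        raise InvalidInputError("feature_names length must match frequencies")
    with open(path, "w") as fh:
        fh.write("feature_id\tinclusion_frequency\trank\n")
        for rank, j in enumerate(order, start=1):
            fh.write(f"{names[j]}\t{res.frequencies[j]:.6g}\t{rank}\n")
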