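"""Linear SVM with an elastic-net penalty.

Minimizes, in the intercept ``beta0`` and coefficients ``beta``,

    sum_i max(0, 1 - y_i * (x_i . beta + beta0)) + lam * C_alpha(beta)

where ``C_alpha(beta) = 0.5*(1-alpha)*||beta||_2^2 + alpha*||beta||_1``.
The intercept is never penalized.  The solver is cyclic coordinate descent
with a majorize-minimize step on a huberized hinge (smoothing width
``gamma``, reached by warm-started continuation from a smoother loss) and
proximal soft-thresholding for the L1 part, so coefficients are exactly zero
at rest.  Features are standardized internally and coefficients reported back
on the original scale; exact zero patterns survive the back-transform.

p >> n is the intended regime; an active-set strategy makes path fits cheap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .exceptions import InvalidInputError, ParameterError

__all__ = [
    "PenaltyConfig",
    "SvmModel",
    "elastic_net_penalty",
    "hinge_objective",
    "lambda_max",
    "fit",
    "fit_path",
    "decision_scores",
    "predict",
]

DEFAULT_GAMMA = 0.5
DEFAULT_TOL = 1e-7
DEFAULT_MAX_ITER = 10_000


@dataclass(frozen=True)
class PenaltyConfig:
    """Elastic-net tuning pair: strength ``lam`` > 0, mixing ``alpha`` in [0,1]."""

    lam: float
    alpha: float

    def __post_init__(self) -> None:
        if not (self.lam > 0 and np.isfinite(self.lam)):
            raise ParameterError(f"lam must be positive and finite, got {self.lam}")
        if not (0.0 <= self.alpha <= 1.0):
            raise ParameterError(f"alpha must be in [0, 1], got {self.alpha}")


@dataclass
class SvmModel:
    """Fitted sparse SVM: original-scale coefficients and intercept."""

    beta: np.ndarray
    beta0: float
    penalty: PenaltyConfig
    converged: bool = True
    n_iter: int = 0
    # standardized-scale copy kept for warm starts along a path
    beta_std: np.ndarray | None = field(default=None, repr=False)
    beta0_std: float = field(default=0.0, repr=False)

    @property
    def support_count(self) -> int:
        return int(np.count_nonzero(self.beta))

    @property
    def support(self) -> np.ndarray:
        """Indices of features with nonzero coefficients."""
        return np.flatnonzero(self.beta)


def elastic_net_penalty(beta, alpha: float) -> float:
    """``0.5*(1-alpha)*||beta||_2^2 + alpha*||beta||_1`` (>= 0, 0 iff beta=0)."""
    if not (0.0 <= alpha <= 1.0):
        raise ParameterError(f"alpha must be in [0, 1], got {alpha}")
    beta = np.asarray(beta, dtype=float)
    return float(
        0.5 * (1.0 - alpha) * np.dot(beta, beta) + alpha * np.abs(beta).sum()
    )


def hinge_objective(X, y, beta, beta0: float, cfg: PenaltyConfig) -> float:
    """Exact (non-smoothed) value of the penalized hinge objective."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    margins = y * (X @ np.asarray(beta, dtype=float) + beta0)
    loss = np.maximum(0.0, 1.0 - margins).sum()
    return float(loss) + cfg.lam * elastic_net_penalty(beta, cfg.alpha)


# ---------------------------------------------------------------------------
# numba kernels (standardized data, huberized hinge)
# ---------------------------------------------------------------------------
# huberized hinge with width gamma:
#   l(v) = 0                    if v > 1
#        = (1-v)^2 / (2*gamma)  if 1-gamma < v <= 1
#        = 1 - v - gamma/2      if v <= 1-gamma
# l'' <= 1/gamma, so n/gamma majorizes the per-coordinate curvature on
# unit-variance columns and every sweep decreases the smoothed objective.


@njit(cache=True, inline="always")
def _huber_deriv(v: float, gamma: float) -> float:
    if v > 1.0:
        return 0.0
    if v > 1.0 - gamma:
        return (v - 1.0) / gamma
    return -1.0


@njit(cache=True, inline="always")
def _huber_loss(v: float, gamma: float) -> float:
    if v > 1.0:
        return 0.0
    if v > 1.0 - gamma:
        d = 1.0 - v
        return d * d / (2.0 * gamma)
    return 1.0 - v - 0.5 * gamma


@njit(cache=True)
def _coord_step(Xs, yf, margins, beta, j, lam, alpha, gamma):
    """Safeguarded proximal-Newton step on coordinate j.

    Curvature starts from the elbow-set (second-derivative) estimate and is
    doubled until the move does not increase the smoothed objective; the
    global bound n/gamma always satisfies the descent condition, so the loop
    terminates.  Returns the accepted coefficient change.
    """
    n = Xs.shape[0]
    curv_max = n / gamma
    g = 0.0
    h = 0.0
    for i in range(n):
        v = margins[i]
        d = _huber_deriv(v, gamma)
        if d != 0.0:
            g += d * yf[i] * Xs[i, j]
        if 1.0 - gamma < v <= 1.0:
            h += Xs[i, j] * Xs[i, j] / gamma
    thr = lam * alpha
    bj = beta[j]
    # stationarity shortcut: zero coefficient inside the soft threshold
    if bj == 0.0 and abs(g) <= thr:
        return 0.0
    if h < 1e-10:
        h = 1e-10
    while True:
        denom = h + lam * (1.0 - alpha)
        z = h * bj - g
        if z > thr:
            cand = (z - thr) / denom
        elif z < -thr:
            cand = (z + thr) / denom
        else:
            cand = 0.0
        delta = cand - bj
        if delta == 0.0:
            return 0.0
        if h >= curv_max:
            break  # MM bound: descent guaranteed, accept without checking
        dloss = 0.0
        for i in range(n):
            dloss += _huber_loss(margins[i] + yf[i] * Xs[i, j] * delta, gamma) \
                - _huber_loss(margins[i], gamma)
        dpen = lam * (0.5 * (1.0 - alpha) * (cand * cand - bj * bj)
                      + alpha * (abs(cand) - abs(bj)))
        if dloss + dpen <= 1e-12:
            break
        h *= 4.0
        if h > curv_max:
            h = curv_max
    beta[j] = cand
    for i in range(n):
        margins[i] += yf[i] * Xs[i, j] * delta
    return delta


@njit(cache=True)
def _intercept_step(yf, margins, gamma):
    """Safeguarded Newton step on the (unpenalized) intercept."""
    n = margins.shape[0]
    curv_max = n / gamma
    g = 0.0
    h = 0.0
    for i in range(n):
        v = margins[i]
        d = _huber_deriv(v, gamma)
        if d != 0.0:
            g += d * yf[i]
        if 1.0 - gamma < v <= 1.0:
            h += 1.0 / gamma
    if g == 0.0:
        return 0.0
    if h < 1e-10:
        h = 1e-10
    while True:
        delta = -g / h
        if h >= curv_max:
            break
        dloss = 0.0
        for i in range(n):
            dloss += _huber_loss(margins[i] + yf[i] * delta, gamma) \
                - _huber_loss(margins[i], gamma)
        if dloss <= 1e-12:
            break
        h *= 4.0
        if h > curv_max:
            h = curv_max
    for i in range(n):
        margins[i] += yf[i] * delta
    return delta


@njit(cache=True)
def _sweep(Xs, yf, margins, beta, active, lam, alpha, gamma, active_only):
    """One cyclic pass over coordinates (all, or the active set only) plus an
    intercept step.  Updates ``beta``, ``margins`` and ``active`` in place;
    returns the largest absolute parameter change and the intercept change.
    """
    p = Xs.shape[1]
    max_delta = 0.0
    for j in range(p):
        if active_only and not active[j]:
            continue
        delta = _coord_step(Xs, yf, margins, beta, j, lam, alpha, gamma)
        if abs(delta) > max_delta:
            max_delta = abs(delta)
        active[j] = beta[j] != 0.0
    d0 = _intercept_step(yf, margins, gamma)
    if abs(d0) > max_delta:
        max_delta = abs(d0)
    return max_delta, d0


def _huber_loss_vec(v: np.ndarray, gamma: float) -> np.ndarray:
    out = np.where(
        v > 1.0,
        0.0,
        np.where(v > 1.0 - gamma, (1.0 - v) ** 2 / (2.0 * gamma), 1.0 - v - 0.5 * gamma),
    )
    return out


def _huber_deriv_vec(v: np.ndarray, gamma: float) -> np.ndarray:
    return np.where(v > 1.0, 0.0, np.where(v > 1.0 - gamma, (v - 1.0) / gamma, -1.0))


def _prox_polish(Xs, yf, beta, beta0, lam, alpha, gamma, tol, max_iter=20000):
    """Accelerated proximal-gradient refinement of a CD solution.

    Coordinate descent can zigzag in the flat valleys the hinge kink creates
    between coupled coordinates; full-vector FISTA steps (with backtracking
    and gradient restart) close that gap.  Used for high-precision fits on
    small problems; returns (beta, beta0).
    """
    n = Xs.shape[0]

    def smooth_val(b, b0):
        v = yf * (Xs @ b + b0)
        return _huber_loss_vec(v, gamma).sum() + 0.5 * lam * (1 - alpha) * (b @ b)

    def grad(b, b0):
        v = yf * (Xs @ b + b0)
        d = _huber_deriv_vec(v, gamma) * yf
        return Xs.T @ d + lam * (1 - alpha) * b, d.sum()

    L = max(1.0, lam)
    x_b, x_b0 = beta.copy(), float(beta0)
    z_b, z_b0 = x_b.copy(), x_b0
    t_mom = 1.0
    thr = lam * alpha
    for _ in range(max_iter):
        gb, g0 = grad(z_b, z_b0)
        f_z = smooth_val(z_b, z_b0)
        while True:
            step = 1.0 / L
            cand = z_b - step * gb
            cand = np.sign(cand) * np.maximum(np.abs(cand) - step * thr, 0.0)
            cand0 = z_b0 - step * g0
            db, d0 = cand - z_b, cand0 - z_b0
            if (
                smooth_val(cand, cand0)
                <= f_z + gb @ db + g0 * d0 + 0.5 * L * (db @ db + d0 * d0) + 1e-14
            ):
                break
            L *= 2.0
            if L > 1e16:
                break
        move = max(np.max(np.abs(cand - x_b)), abs(cand0 - x_b0))
        t_next = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * t_mom * t_mom))
        mom = (t_mom - 1.0) / t_next
        # gradient restart
        if gb @ (cand - x_b) + g0 * (cand0 - x_b0) > 0:
            mom, t_next = 0.0, 1.0
        z_b = cand + mom * (cand - x_b)
        z_b0 = cand0 + mom * (cand0 - x_b0)
        x_b, x_b0 = cand, cand0
        t_mom = t_next
        L = max(L / 1.5, 1e-3)
        if move < tol:
            break
    return x_b, x_b0


def _solve_std(Xs, yf, beta, beta0, lam, alpha, gamma, tol, max_iter, polish=False):
    """Coordinate descent on standardized data at one (lam, alpha).

    Continuation: solves at decreasing smoothing widths down to ``gamma``,
    warm-starting each stage.  Returns (beta0, n_sweeps, converged); ``beta``
    is modified in place.  ``polish`` appends a FISTA refinement stage.
    """
    gammas = []
    g = DEFAULT_GAMMA
    while g > gamma * 1.0000001:
        gammas.append(g)
        g /= 10.0
    gammas.append(gamma)

    active = beta != 0.0
    margins = yf * (Xs @ beta + beta0)
    sweeps = 0
    converged = True
    for stage, gam in enumerate(gammas):
        # earlier stages only need rough solutions
        stage_tol = tol if stage == len(gammas) - 1 else max(tol, 1e-4)
        stage_conv = False
        while sweeps < max_iter:
            sweeps += 1
            max_delta, d0 = _sweep(
                Xs, yf, margins, beta, active, lam, alpha, gam, False
            )
            beta0 += d0
            if max_delta < stage_tol:
                stage_conv = True
                break
            # inner loop on the current active set
            while sweeps < max_iter:
                sweeps += 1
                max_delta, d0 = _sweep(
                    Xs, yf, margins, beta, active, lam, alpha, gam, True
                )
                beta0 += d0
                if max_delta < stage_tol:
                    break
        if not stage_conv:
            converged = False
            break
    if polish:
        # FISTA refinement with its own smoothing continuation: each stage
        # starts close to the next optimum, so even very small widths
        # converge locally.
        g_polish = max(gamma, 1e-3)
        while True:
            new_beta, beta0 = _prox_polish(
                Xs, yf, beta, beta0, lam, alpha, g_polish, tol
            )
            beta[:] = new_beta
            if g_polish <= gamma:
                break
            g_polish = max(gamma, g_polish / 10.0)
        converged = True
    return beta0, sweeps, converged


# ---------------------------------------------------------------------------
# public fitting API
# ---------------------------------------------------------------------------


class _Standardized:
    """Column-standardized view of a training matrix plus the back-transform."""

    def __init__(self, X: np.ndarray):
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0)  # ddof=0 so columns have sum of squares n exactly
        self.sd = np.where(sd > 0, sd, 1.0)
        self.Xs = np.asfortranarray((X - self.mean) / self.sd)

    def to_original(self, beta_std: np.ndarray, beta0_std: float):
        beta = beta_std / self.sd
        beta0 = beta0_std - float(np.dot(beta, self.mean))
        return beta, beta0


def _validate_xy(X, y):
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise InvalidInputError("X must be a 2-D matrix")
    if y.shape != (X.shape[0],):
        raise InvalidInputError("y length must match the number of rows of X")
    if not np.isfinite(X).all():
        raise InvalidInputError("X contains non-finite entries")
    labels = set(np.unique(y).tolist())
    if not labels <= {-1, 1}:
        raise InvalidInputError(f"labels must be in {{-1,+1}}, found {sorted(labels)}")
    if len(labels) < 2:
        raise InvalidInputError("both classes must be present in y")
    if X.shape[0] < 2:
        raise InvalidInputError("need at least 2 samples")
    return X, y.astype(float)


def lambda_max(X, y, alpha: float = 1.0, gamma: float = DEFAULT_GAMMA) -> float:
    """Smallest penalty strength at which the fitted ``beta`` is all zero.

    Computed on the standardized data from the loss gradient at the null
    model (beta = 0, intercept at its 1-D optimum).
    """
    if not (0.0 < alpha <= 1.0):
        raise ParameterError("lambda_max requires alpha in (0, 1]")
    X, yf = _validate_xy(X, y)
    std = _Standardized(X)
    b0 = _null_intercept(yf, gamma)
    d = np.array([_huber_deriv_py(v, gamma) for v in yf * b0])
    grad = (d * yf) @ std.Xs
    return float(np.abs(grad).max() / alpha)


def _huber_deriv_py(v: float, gamma: float) -> float:
    if v > 1.0:
        return 0.0
    if v > 1.0 - gamma:
        return (v - 1.0) / gamma
    return -1.0


def _null_intercept(yf: np.ndarray, gamma: float) -> float:
    """1-D minimizer of the huberized hinge loss over the intercept alone."""
    lo, hi = -2.0, 2.0

    def deriv(b0: float) -> float:
        return sum(_huber_deriv_py(v, gamma) * yi for v, yi in zip(yf * b0, yf))

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if deriv(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def fit(
    X,
    y,
    cfg: PenaltyConfig,
    *,
    gamma: float = DEFAULT_GAMMA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    warm_start: SvmModel | None = None,
    warn_on_nonconvergence: bool = True,
    polish: bool = False,
) -> SvmModel:
    """Fit the elastic-net SVM at a single penalty configuration.

    ``gamma`` is the hinge smoothing width of the final continuation stage;
    decrease it (e.g. 1e-5) and set ``polish=True`` for near-exact hinge
    solutions on small problems.  Non-convergence sets
    ``model.converged = False`` (with a warning) rather than raising.
    """
    X, yf = _validate_xy(X, y)
    std = _Standardized(X)
    p = X.shape[1]
    if warm_start is not None and warm_start.beta_std is not None:
        beta_std = warm_start.beta_std.copy()
        beta0_std = warm_start.beta0_std
    else:
        beta_std = np.zeros(p)
        beta0_std = _null_intercept(yf, gamma)
    beta0_std, sweeps, converged = _solve_std(
        std.Xs, yf, beta_std, beta0_std, cfg.lam, cfg.alpha, gamma, tol,
        max_iter, polish=polish,
    )
    if not converged and warn_on_nonconvergence:
        warnings.warn(
            f"sparse SVM did not converge in {max_iter} sweeps "
            f"(lam={cfg.lam:.4g}, alpha={cfg.alpha})",
            RuntimeWarning,
            stacklevel=2,
        )
    beta, beta0 = std.to_original(beta_std, beta0_std)
    return SvmModel(
        beta=beta,
        beta0=beta0,
        penalty=cfg,
        converged=converged,
        n_iter=sweeps,
        beta_std=beta_std,
        beta0_std=beta0_std,
    )


def fit_path(
    X,
    y,
    alpha: float,
    lambdas=None,
    *,
    n_lambdas: int = 30,
    lambda_min_ratio: float = 0.01,
    gamma: float = DEFAULT_GAMMA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> list[SvmModel]:
    """Fit a warm-started path of models at one ``alpha``.

    When ``lambdas`` is omitted, uses ``n_lambdas`` log-spaced values from
    ``lambda_max`` down to ``lambda_min_ratio * lambda_max``.  Models are
    returned in the order of the (descending) lambda sequence.
    """
    X = np.asarray(X, dtype=float)
    if lambdas is None:
        lmax = lambda_max(X, y, alpha=alpha if alpha > 0 else 1.0, gamma=gamma)
        lambdas = np.geomspace(lmax, lambda_min_ratio * lmax, n_lambdas)
    else:
        lambdas = np.asarray(lambdas, dtype=float)
    models: list[SvmModel] = []
    prev: SvmModel | None = None
    for lam in lambdas:
        model = fit(
            X,
            y,
            PenaltyConfig(lam=float(lam), alpha=alpha),
            gamma=gamma,
            tol=tol,
            max_iter=max_iter,
            warm_start=prev,
            warn_on_nonconvergence=False,
        )
        models.append(model)
        prev = model
    return models


def decision_scores(model: SvmModel, X) -> np.ndarray:
    """Decision scores ``X @ beta + beta0`` for each row of ``X``."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.beta.shape[0]:
        raise InvalidInputError(
            f"X has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"model expects {model.beta.shape[0]}"
        )
    return X @ model.beta + model.beta0


def predict(model: SvmModel, X) -> np.ndarray:
    """Class labels: +1 where the score is > 0, else -1 (ties to majority)."""
    scores = decision_scores(model, X)
    return np.where(scores > 0, 1, -1)
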