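import warnings

import numpy as np
import pytest
from scipy.optimize import minimize

from ssshd import sparse_svm as ss
from ssshd.exceptions import InvalidInputError, ParameterError
from ssshd.hellinger import ScoreSplit, hellinger_from_scores


def subgradient_oracle(X, y, lam, alpha, steps=50_000):
    """Independent minimizer of the exact penalized hinge objective:
    plain subgradient descent with a geometrically decaying step, tracking
    the best objective seen."""
    n, p = X.shape
    beta = np.zeros(p)
    b0 = 0.0
    best = np.inf
    eta = 0.5
    decay = (1e-8 / eta) ** (1.0 / steps)
    for _ in range(steps):
        margins = y * (X @ beta + b0)
        active = margins < 1
        gb = -(y[active, None] * X[active]).sum(axis=0) + lam * (
            (1 - alpha) * beta + alpha * np.sign(beta)
        )
        g0 = -(y[active]).sum()
        beta -= eta * gb
        b0 -= eta * g0
        eta *= decay
        f = np.maximum(0, 1 - y * (X @ beta + b0)).sum() + lam * (
            0.5 * (1 - alpha) * beta @ beta + alpha * np.abs(beta).sum()
        )
        best = min(best, f)
    return best


def random_instance(rng, n=6, p=3):
    X = rng.standard_normal((n, p))
    y = rng.choice([-1, 1], size=n)
    y[:2] = [1, -1]  # both classes present
    X = (X - X.mean(axis=0)) / X.std(axis=0)  # pre-standardized instance
    return X, y


class TestPenalty:
    def test_zero_beta(self):
        assert ss.elastic_net_penalty([0.0, 0.0, 0.0], 0.7) == 0.0

    def test_pure_lasso(self):
        assert ss.elastic_net_penalty([1.0, -1.0], 1.0) == 2.0

    def test_pure_ridge(self):
        assert ss.elastic_net_penalty([1.0, -1.0], 0.0) == 1.0

    def test_mixing(self):
        got = ss.elastic_net_penalty([3.0], 0.25)
        assert got == pytest.approx(0.5 * 0.75 * 9 + 0.25 * 3)

    def test_alpha_out_of_range(self):
        with pytest.raises(ParameterError):
            ss.elastic_net_penalty([1.0], 1.5)


class TestPenaltyConfig:
    @pytest.mark.parametrize("lam,alpha", [(-1, 0.5), (0, 0.5), (1, -0.1), (1, 1.1)])
    def test_invalid(self, lam, alpha):
        with pytest.raises(ParameterError):
            ss.PenaltyConfig(lam=lam, alpha=alpha)


class TestFit:
    def test_lambda_max_gives_null_model(self, rng):
        X = rng.standard_normal((40, 8))
        X[:20, 0] += 2
        y = np.array([1] * 20 + [-1] * 20)
        lmax = ss.lambda_max(X, y, alpha=1.0)
        m = ss.fit(X, y, ss.PenaltyConfig(lam=lmax * 1.0001, alpha=1.0))
        assert m.support_count == 0
        assert np.all(m.beta == 0.0)

    def test_separable_1d(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array([-1, 1])
        m = ss.fit(X, y, ss.PenaltyConfig(lam=0.01, alpha=1.0))
        assert np.array_equal(ss.predict(m, X), y)

    def test_objective_agreement_with_subgradient_oracle(self, rng):
        # reduced-size twin of the acceptance-suite check (fewer instances
        # and oracle steps keep this module's tests quick)
        for _ in range(5):
            X, y = random_instance(rng)
            lam = 10 ** rng.uniform(-0.5, 0.5)
            alpha = rng.uniform(0.1, 1.0)
            cfg = ss.PenaltyConfig(lam=lam, alpha=alpha)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = ss.fit(X, y, cfg, gamma=1e-6, tol=1e-9, max_iter=300,
                           polish=True)
            ours = ss.hinge_objective(X, y, m.beta, m.beta0, cfg)
            oracle = subgradient_oracle(X, y, lam, alpha, steps=20_000)
            assert ours == pytest.approx(oracle, rel=2e-4)

    def test_ridge_matches_smooth_qp_form(self, rng):
        """alpha=0 recovers the ridge-penalized hinge objective: compare to
        direct minimization of hinge + lam*0.5*||beta||^2 via a smoothed
        Nelder-Mead oracle."""
        X, y = random_instance(rng, n=8, p=2)
        lam = 0.7
        cfg = ss.PenaltyConfig(lam=lam, alpha=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = ss.fit(X, y, cfg, gamma=1e-5, tol=1e-10, max_iter=5000, polish=True)
        ours = ss.hinge_objective(X, y, m.beta, m.beta0, cfg)

        def obj(params):
            b, b0 = params[:2], params[2]
            return (
                np.maximum(0, 1 - y * (X @ b + b0)).sum()
                + lam * 0.5 * b @ b
            )

        best = min(
            minimize(obj, np.concatenate([m.beta, [m.beta0]]) + d,
                     method="Nelder-Mead",
                     options=dict(xatol=1e-10, fatol=1e-12, maxiter=20000)).fun
            for d in (np.zeros(3), np.full(3, 0.3), np.full(3, -0.3))
        )
        assert ours == pytest.approx(best, rel=1e-4, abs=1e-6)

    def test_qp_equivalence_small_instances(self, rng):
        """Constrained soft-margin form solved by an SLSQP oracle agrees with
        the unconstrained hinge form at alpha=0, lam = 1/(2C) scaling."""
        for _ in range(10):
            X, y = random_instance(rng, n=7, p=2)
            C = 10 ** rng.uniform(-0.5, 0.5)
            # constrained form 0.5*||b||^2 + C*sum(xi) divided by C matches
            # our objective (whose ridge term is lam*0.5*||b||^2) at lam=1/C
            lam = 1.0 / C
            cfg = ss.PenaltyConfig(lam=lam, alpha=0.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = ss.fit(X, y, cfg, gamma=1e-5, tol=1e-10, max_iter=5000,
                           polish=True)
            # our objective, rescaled to the QP parameterization
            ours = C * ss.hinge_objective(X, y, m.beta, m.beta0, cfg)

            n, p = X.shape

            def qp_obj(z):
                b = z[:p]
                return 0.5 * b @ b + C * z[p + 1:].sum()

            def qp_constraints(z):
                b, b0, xi = z[:p], z[p], z[p + 1:]
                return np.concatenate([y * (X @ b + b0) - 1 + xi, xi])

            z0 = np.concatenate([m.beta, [m.beta0],
                                 np.maximum(0, 1 - y * (X @ m.beta + m.beta0))])
            res = minimize(
                qp_obj, z0, method="SLSQP",
                constraints={"type": "ineq", "fun": qp_constraints},
                options=dict(maxiter=1000, ftol=1e-12),
            )
            assert res.success
            assert ours == pytest.approx(res.fun, rel=1e-4, abs=1e-6)

    def test_support_monotone_in_lambda_at_alpha_one(self, rng):
        X = rng.standard_normal((200, 15))
        X[:100, :3] += 1.5
        y = np.array([1] * 100 + [-1] * 100)
        models = ss.fit_path(X, y, alpha=1.0, n_lambdas=25)
        sizes = [m.support_count for m in models]
        violations = sum(b < a for a, b in zip(sizes, sizes[1:]))
        # allow one numerical-tie violation along the path
        assert violations <= 1
        assert sizes[0] <= sizes[-1]

    def test_row_permutation_invariance(self, rng):
        X = rng.standard_normal((30, 6))
        X[:15, 0] += 2
        y = np.array([1] * 15 + [-1] * 15)
        cfg = ss.PenaltyConfig(lam=5.0, alpha=0.8)
        m1 = ss.fit(X, y, cfg)
        perm = rng.permutation(30)
        m2 = ss.fit(X[perm], y[perm], cfg)
        assert np.allclose(m1.beta, m2.beta, atol=1e-6)
        assert m1.beta0 == pytest.approx(m2.beta0, abs=1e-6)

    def test_single_class_raises(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(InvalidInputError):
            ss.fit(X, np.ones(10), ss.PenaltyConfig(lam=1.0, alpha=0.5))

    def test_nonfinite_raises(self):
        X = np.array([[1.0], [np.nan]])
        with pytest.raises(InvalidInputError):
            ss.fit(X, np.array([1, -1]), ss.PenaltyConfig(lam=1.0, alpha=0.5))

    def test_nonconvergence_flags_not_raises(self, rng):
        X, y = random_instance(rng, n=10, p=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = ss.fit(X, y, ss.PenaltyConfig(lam=0.05, alpha=0.3),
                       gamma=1e-4, tol=1e-12, max_iter=3)
        assert m.converged is False

    def test_original_scale_coefficients(self, rng):
        """Scores computed from original-scale (beta, beta0) must equal the
        standardized-scale computation."""
        X = rng.standard_normal((40, 5)) * np.array([1, 10, 0.1, 5, 2]) + 3
        X[:20, 1] += 30
        y = np.array([1] * 20 + [-1] * 20)
        m = ss.fit(X, y, ss.PenaltyConfig(lam=3.0, alpha=0.9))
        Xs = (X - X.mean(0)) / X.std(0)
        direct = Xs @ m.beta_std + m.beta0_std
        assert np.allclose(ss.decision_scores(m, X), direct, atol=1e-8)


class TestDecisionAndPredict:
    def _model(self, beta, beta0):
        return ss.SvmModel(beta=np.asarray(beta, dtype=float), beta0=beta0,
                           penalty=ss.PenaltyConfig(lam=1.0, alpha=1.0))

    def test_null_model_constant_scores(self):
        m = self._model([0.0, 0.0], 3.5)
        X = np.zeros((4, 2))
        assert np.allclose(ss.decision_scores(m, X), 3.5)

    def test_single_row_arithmetic(self):
        m = self._model([1.0, 2.0], -1.0)
        assert ss.decision_scores(m, [[3.0, 4.0]])[0] == pytest.approx(10.0)

    def test_tie_maps_to_majority(self):
        m = self._model([1.0], 0.0)
        X = np.array([[0.5], [-0.2], [0.0]])
        assert np.array_equal(ss.predict(m, X), [1, -1, -1])

    def test_positive_intercept_all_positive(self):
        m = self._model([0.0], 0.25)
        assert np.array_equal(ss.predict(m, np.zeros((3, 1))), [1, 1, 1])

    def test_duplicated_rows_pointwise(self, rng):
        m = self._model([1.0, -2.0], 0.3)
        X = rng.standard_normal((5, 2))
        X2 = np.vstack([X, X[:1]])
        p1 = ss.predict(m, X)
        p2 = ss.predict(m, X2)
        assert np.array_equal(p2[:5], p1) and p2[5] == p1[0]

    def test_column_mismatch(self):
        m = self._model([1.0, 2.0], 0.0)
        with pytest.raises(InvalidInputError):
            ss.decision_scores(m, np.zeros((3, 3)))

    def test_training_scores_feed_hellinger(self, toy_two_class):
        X, y = toy_two_class
        m = ss.fit(X, y, ss.PenaltyConfig(lam=1.0, alpha=0.5))
        hd = hellinger_from_scores(
            ScoreSplit.from_labels(ss.decision_scores(m, X), y)
        )
        assert 0.0 <= hd <= np.sqrt(2.0)
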