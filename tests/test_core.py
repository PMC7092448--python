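import numpy as np
import pytest

from ssshd.core import (
    StabilityResult,
    TuningGrid,
    rank_features,
    select_top_q,
    stability_select,
    tune_by_hd,
)
from ssshd.exceptions import ParameterError


def make_result(frequencies, runs=10):
    return StabilityResult(frequencies=np.asarray(frequencies, float), runs=runs)


SMALL_GRID = dict(alphas=(0.5, 1.0), n_lambdas=8)


@pytest.fixture
def informative_data():
    """p=2 data: feature 0 separates N(0,1) vs N(4,1); feature 1 pure noise."""
    local = np.random.default_rng(321)
    n_per = 40
    X = local.standard_normal((2 * n_per, 2))
    X[n_per:, 0] += 4.0
    y = np.concatenate([-np.ones(n_per, dtype=int), np.ones(n_per, dtype=int)])
    return X, y


class TestTuningGrid:
    def test_default_grid_shape(self, informative_data):
        X, y = informative_data
        grid = TuningGrid.default(X, y)
        assert len(grid.lambdas) == 30 and len(grid.alphas) == 10
        assert grid.lambdas[-1] == pytest.approx(0.01 * grid.lambdas[0])

    def test_rejects_increasing_lambdas(self):
        with pytest.raises(ParameterError):
            TuningGrid(lambdas=(1.0, 2.0), alphas=(1.0,))

    def test_rejects_zero_alpha(self):
        with pytest.raises(ParameterError):
            TuningGrid(lambdas=(1.0,), alphas=(0.0,))

    def test_rejects_empty(self):
        with pytest.raises(ParameterError):
            TuningGrid(lambdas=(), alphas=(1.0,))


class TestTuneByHd:
    def test_informative_feature_selected(self, informative_data):
        """Oracle check: exhaustive sweep must keep the separating feature."""
        X, y = informative_data
        grid = TuningGrid.default(X, y, **SMALL_GRID)
        _, model, hd = tune_by_hd(X, y, grid)
        assert model.beta[0] != 0.0
        assert hd > 1.0

    def test_single_point_grid(self, informative_data):
        X, y = informative_data
        grid = TuningGrid(lambdas=(0.5,), alphas=(1.0,))
        cfg, _, _ = tune_by_hd(X, y, grid, score_mode="insample")
        assert cfg.lam == 0.5 and cfg.alpha == 1.0

    def test_duplicated_alphas_same_selection(self, informative_data):
        X, y = informative_data
        g1 = TuningGrid.default(X, y, **SMALL_GRID)
        g2 = TuningGrid(lambdas=g1.lambdas, alphas=g1.alphas + g1.alphas)
        cfg1, _, hd1 = tune_by_hd(X, y, g1, cv_seed=5)
        cfg2, _, hd2 = tune_by_hd(X, y, g2, cv_seed=5)
        assert (cfg1.lam, cfg1.alpha) == (cfg2.lam, cfg2.alpha)
        assert hd1 == hd2

    def test_insample_mode_available(self, informative_data):
        X, y = informative_data
        grid = TuningGrid.default(X, y, **SMALL_GRID)
        _, model, hd = tune_by_hd(X, y, grid, score_mode="insample")
        assert model.beta[0] != 0.0

    def test_bad_score_mode(self, informative_data):
        X, y = informative_data
        with pytest.raises(ParameterError):
            tune_by_hd(X, y, TuningGrid(lambdas=(1.0,), alphas=(1.0,)),
                       score_mode="bogus")


class TestStabilitySelect:
    def test_k1_frequencies_binary(self, informative_data):
        X, y = informative_data
        grid = TuningGrid.default(X, y, **SMALL_GRID)
        res = stability_select(X, y, grid, K=1, fraction=0.5, seed=0)
        assert set(np.unique(res.frequencies)) <= {0.0, 1.0}

    def test_counting_identity(self, informative_data):
        X, y = informative_data
        grid = TuningGrid.default(X, y, **SMALL_GRID)
        res = stability_select(X, y, grid, K=7, fraction=0.5, seed=1)
        total = sum(len(s) for s in res.per_run_supports)
        assert np.sum(res.frequencies * res.runs) == pytest.approx(total)
        # frequencies * K are integers (counting identity)
        counts = res.frequencies * res.runs
        assert np.allclose(counts, np.round(counts))

    def test_determinism(self, informative_data):
        X, y = informative_data
        grid = TuningGrid.default(X, y, **SMALL_GRID)
        a = stability_select(X, y, grid, K=4, fraction=0.5, seed=7)
        b = stability_select(X, y, grid, K=4, fraction=0.5, seed=7)
        assert np.array_equal(a.frequencies, b.frequencies)
        assert all(
            np.array_equal(x, z)
            for x, z in zip(a.per_run_supports, b.per_run_supports)
        )

    def test_strong_feature_high_frequency(self):
        """Simulation oracle: a 4-sigma mean-shift feature among noise must
        be included in nearly every run and rank first (3 seeds)."""
        for seed in (1, 2, 3):
            local = np.random.default_rng(seed * 101)
            X = local.standard_normal((200, 20))
            X[:100, 0] += 4.0
            y = np.array([1] * 100 + [-1] * 100)
            grid = TuningGrid.default(X, y, alphas=(1.0,), n_lambdas=8)
            res = stability_select(X, y, grid, K=30, fraction=0.5, seed=seed)
            assert res.frequencies[0] >= 0.9
            assert rank_features(res)[0] == 0

    def test_subsample_ratio_preserved(self, informative_data):
        X, y = informative_data
        from ssshd.resampling import stratified_subsample

        idx = stratified_subsample(y, 0.5, seed=3)
        assert np.sum(y[idx] == 1) / np.sum(y[idx] == -1) == pytest.approx(
            np.sum(y == 1) / np.sum(y == -1)
        )

    def test_too_small_fraction_raises(self, informative_data):
        X, y = informative_data
        with pytest.raises(ParameterError, match="fraction"):
            stability_select(X, y, K=2, fraction=0.01, seed=0)

    def test_bad_k(self, informative_data):
        X, y = informative_data
        with pytest.raises(ParameterError):
            stability_select(X, y, K=0, fraction=0.5)


class TestRanking:
    def test_tie_break_by_index(self):
        res = make_result([0.2, 0.9, 0.9, 0.1])
        assert rank_features(res)[:2].tolist() == [1, 2]

    def test_all_equal_identity_order(self):
        res = make_result([0.5] * 5)
        assert rank_features(res).tolist() == [0, 1, 2, 3, 4]

    def test_invariant_to_duplicated_runs(self):
        supports = [np.array([0, 2]), np.array([2])]
        a = StabilityResult(frequencies=np.array([0.5, 0.0, 1.0]), runs=2,
                            per_run_supports=supports)
        b = StabilityResult(frequencies=np.array([0.5, 0.0, 1.0]), runs=4,
                            per_run_supports=supports * 2)
        assert np.array_equal(rank_features(a), rank_features(b))

    def test_select_top_q_all(self):
        res = make_result([0.1, 0.4, 0.3])
        assert sorted(select_top_q(res, 3).tolist()) == [0, 1, 2]

    def test_select_top_one_is_argmax(self):
        res = make_result([0.1, 0.8, 0.3])
        assert select_top_q(res, 1).tolist() == [1]

    def test_nested_property(self):
        res = make_result([0.3, 0.9, 0.1, 0.5, 0.5])
        for q in range(1, 5):
            assert set(select_top_q(res, q)) <= set(select_top_q(res, q + 1))

    def test_q_out_of_range(self):
        res = make_result([0.5, 0.5])
        with pytest.raises(ParameterError):
            select_top_q(res, 3)
        with pytest.raises(ParameterError):
            select_top_q(res, 0)


class TestExport:
    def test_tsv_roundtrip(self, tmp_path):
        from ssshd.core import export_ranking

        res = make_result([0.2, 0.9, 0.5])
        path = tmp_path / "ranking.tsv"
        export_ranking(res, ["f0", "f1", "f2"], path)
        lines = path.read_text().strip().split("\n")
        assert lines[0] == "feature_id\tinclusion_frequency\trank"
        assert lines[1].split("\t") == ["f1", "0.9", "1"]
        assert len(lines) == 4
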