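"""BOSS selector: sampling, weighting, shrinkage loop and recovery."""

import itertools

import numpy as np
import pytest

from bosspls.boss import (
    BossConfig,
    BossPLS,
    SubModel,
    draw_subsets,
    fit_submodels,
    next_n_draws,
    run_boss,
    select_top,
    update_weights,
)
from bosspls.pls import CVConfig, make_folds, rmsecv


def _submodel(indices, cv_rmse, b=None):
    idx = np.asarray(indices, dtype=int)
    if b is None:
        b = np.full(idx.size, 1.0 / np.sqrt(idx.size))
    return SubModel(idx, cv_rmse, np.abs(np.asarray(b, dtype=float)), 1)


class TestDrawSubsets:
    def test_one_hot_weights_always_yield_that_singleton(self, rng):
        w = np.zeros(8)
        w[3] = 2.0
        for subset in draw_subsets(8, w, 20, 5, rng):
            np.testing.assert_array_equal(subset, [3])

    def test_zero_weight_variables_never_drawn(self, rng):
        w = np.ones(30)
        w[[2, 9, 17]] = 0.0
        drawn = np.concatenate(draw_subsets(30, w, 50, 30, rng))
        assert not set(drawn) & {2, 9, 17}

    def test_uniform_bootstrap_coverage_is_632(self, rng):
        # plain bootstrap keeps ~1 - (1 - 1/P)^P of the variable space
        P = 100
        subsets = draw_subsets(P, np.ones(P), 10_000, P, rng)
        mean_frac = np.mean([len(s) for s in subsets]) / P
        assert mean_frac == pytest.approx(1 - (1 - 1 / P) ** P, abs=0.01)

    def test_all_zero_weights_rejected(self, rng):
        with pytest.raises(ValueError, match="zero"):
            draw_subsets(5, np.zeros(5), 10, 3, rng)


class TestFitSubmodels:
    def test_informative_subset_cross_validates_to_zero(self, rng):
        X = rng.standard_normal((20, 10))
        y = X[:, 2] - 0.5 * X[:, 7]
        subs = fit_submodels(X, y, [np.array([2, 7])], CVConfig(n_folds=5, seed=0))
        assert subs[0].rmsecv <= 1e-6

    def test_single_variable_coefficient_is_unit(self, rng):
        X = rng.standard_normal((15, 4))
        y = X[:, 1] + 0.1 * rng.standard_normal(15)
        subs = fit_submodels(X, y, [np.array([1])], CVConfig(n_folds=5, seed=0))
        np.testing.assert_allclose(subs[0].b_normalized, [1.0])

    def test_normalized_coefficients_have_unit_length_and_are_absolute(self, rng):
        X = rng.standard_normal((25, 12))
        y = X @ rng.standard_normal(12) + 0.2 * rng.standard_normal(25)
        subsets = [np.array([0, 3, 5, 9]), np.array([1, 2, 4, 6, 8, 11])]
        for sm in fit_submodels(X, y, subsets, CVConfig(n_folds=5, seed=1)):
            assert np.linalg.norm(sm.b_normalized) == pytest.approx(1.0, abs=1e-10)
            assert np.all(sm.b_normalized >= 0)

    def test_duplicate_subsets_give_identical_results(self, rng):
        X = rng.standard_normal((18, 6))
        y = X[:, 0] + 0.3 * rng.standard_normal(18)
        s = np.array([0, 2, 5])
        a, b = fit_submodels(X, y, [s, s], CVConfig(n_folds=5, seed=3))
        assert a.rmsecv == b.rmsecv
        np.testing.assert_array_equal(a.b_normalized, b.b_normalized)

    def test_out_of_range_subset_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValueError, match="out-of-range"):
            fit_submodels(X, rng.standard_normal(10), [np.array([5])], CVConfig())


class TestSelectTop:
    def test_top_of_ten_at_ten_percent_is_the_single_best(self):
        subs = [_submodel([i], 1.0 + i) for i in range(10)]
        top = select_top(subs, 0.10)
        assert len(top) == 1 and top[0] is subs[0]

    def test_ties_prefer_fewer_variables_then_input_order(self):
        subs = [
            _submodel([0, 1, 2], 1.0),
            _submodel([3], 1.0),
            _submodel([4], 1.0),
        ]
        top = select_top(subs, 0.5)
        assert [sm.variable_indices.tolist() for sm in top] == [[3], [4]]

    def test_selected_dominate_unselected(self, rng):
        subs = [_submodel([i], float(r)) for i, r in enumerate(rng.random(40))]
        top = select_top(subs, 0.25)
        cut = {id(sm) for sm in top}
        rest = [sm for sm in subs if id(sm) not in cut]
        assert max(sm.rmsecv for sm in top) <= min(sm.rmsecv for sm in rest)


class TestUpdateWeights:
    def test_single_submodel_scatters_its_coefficients(self):
        top = [_submodel([2, 5], 0.5, b=[0.6, 0.8])]
        np.testing.assert_allclose(
            update_weights(top, 6), [0, 0, 0.6, 0, 0, 0.8]
        )

    def test_two_identical_submodels_double_the_weights(self):
        sm = _submodel([1, 3], 0.5, b=[0.6, 0.8])
        np.testing.assert_allclose(
            update_weights([sm, sm], 4), 2 * update_weights([sm], 4)
        )

    def test_total_weight_bounded_by_cauchy_schwarz(self, rng):
        # each unit-l2 coefficient vector contributes l1 mass <= sqrt(|subset|)
        for _ in range(20):
            top = []
            for _ in range(rng.integers(1, 8)):
                size = int(rng.integers(1, 12))
                b = rng.standard_normal(size)
                b /= np.linalg.norm(b)
                idx = rng.choice(20, size=size, replace=False)
                top.append(_submodel(np.sort(idx), 1.0, b=np.abs(b)))
            w = update_weights(top, 20)
            bound = sum(np.sqrt(sm.n_variables) for sm in top)
            assert w.sum() <= bound + 1e-9
            assert np.all(w >= 0)


class TestNextNDraws:
    def test_mean_of_sizes(self):
        assert next_n_draws([_submodel(range(s), 1.0) for s in (10, 12, 14)]) == 12

    def test_all_singletons_give_one(self):
        assert next_n_draws([_submodel([0], 1.0), _submodel([1], 1.0)]) == 1

    def test_round_half_up(self):
        assert next_n_draws([_submodel([0], 1.0), _submodel([0, 1], 1.0)]) == 2


class TestRunBoss:
    def test_informative_column_always_beats_pure_noise(self):
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            x = rng.standard_normal(20)
            X = np.column_stack([x, rng.standard_normal(20)])
            y = 2.0 * x
            res = run_boss(X, y, BossConfig(n_subsets=10, seed=seed))
            assert res.selected_indices.tolist() == [0]

    def test_reproducible_for_identical_config(self, rng):
        X = rng.standard_normal((20, 15))
        y = X[:, 3] + 0.5 * rng.standard_normal(20)
        config = BossConfig(n_subsets=20, seed=9)
        r1 = run_boss(X, y, config)
        r2 = run_boss(X, y, config)
        assert r1.chosen_iteration == r2.chosen_iteration
        np.testing.assert_array_equal(r1.selected_indices, r2.selected_indices)
        np.testing.assert_array_equal(r1.final_weights, r2.final_weights)
        for a, b in zip(r1.trajectory, r2.trajectory):
            assert a.best_rmsecv == b.best_rmsecv
            assert a.n_draws == b.n_draws

    def test_weight_support_never_regrows(self, rng):
        X = rng.standard_normal((25, 30))
        y = X[:, [1, 4, 9]] @ np.ones(3) + 0.3 * rng.standard_normal(25)
        res = run_boss(X, y, BossConfig(n_subsets=30, seed=2))
        prev = None
        for rec in res.trajectory:
            support = set(np.flatnonzero(rec.weights))
            if prev is not None:
                assert support <= prev
            prev = support

    def test_draw_counts_shrink_to_one(self, rng):
        X = rng.standard_normal((20, 20))
        y = X[:, 0] + 0.2 * rng.standard_normal(20)
        res = run_boss(X, y, BossConfig(n_subsets=15, seed=5))
        draws = [rec.n_draws for rec in res.trajectory]
        assert draws[-1] == 1
        assert all(b < a for a, b in zip(draws, draws[1:]))

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            run_boss(np.ones((10, 4)), np.arange(10.0), BossConfig(n_subsets=10))

    def test_chosen_subset_near_exhaustive_optimum_on_tiny_problem(self, rng):
        # P=8: enumerate every non-empty subset for the attainable minimum
        n, p = 24, 8
        X = rng.standard_normal((n, p))
        y = X[:, 2] + 0.5 * X[:, 6]  # noise-free planted signal
        config = BossConfig(n_subsets=30, seed=13)
        res = run_boss(X, y, config)
        folds = make_folds(n, config.cv.n_folds, 0)
        best = min(
            rmsecv(X[:, list(s)], y, min(len(s), config.cv.max_factors), config.cv,
                   folds=folds)
            for r in range(1, p + 1)
            for s in itertools.combinations(range(p), r)
        )
        assert res.rmsecv_at_choice >= best - 1e-12
        assert res.rmsecv_at_choice <= 1.1 * best + 1e-8


class TestBossPLSEstimator:
    def test_fit_predict_roundtrip_and_sklearn_contract(self, rng):
        X = rng.standard_normal((30, 12))
        y = X[:, 1] - X[:, 7] + 0.1 * rng.standard_normal(30)
        est = BossPLS(n_subsets=15, random_state=0)
        assert est.get_params()["n_subsets"] == 15
        est.fit(X, y)
        assert est.selected_indices_.size >= 1
        assert est.predict(X).shape == (30,)
        assert est.score(X, y) > 0.9
        np.testing.assert_array_equal(
            est.transform(X), X[:, est.selected_indices_]
        )

    def test_clone_and_refit_reproduces(self, rng):
        from sklearn.base import clone

        X = rng.standard_normal((25, 10))
        y = X[:, 0] + 0.2 * rng.standard_normal(25)
        a = BossPLS(n_subsets=12, random_state=3).fit(X, y)
        b = clone(a).fit(X, y)
        np.testing.assert_array_equal(a.selected_indices_, b.selected_indices_)
        np.testing.assert_allclose(a.predict(X), b.predict(X))
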