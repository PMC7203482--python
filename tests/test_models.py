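"""Ridge closed form, boosting contract, tuning and feature elimination."""

import numpy as np
import pytest
from scipy.optimize import minimize

from affectlearn.errors import InsufficientDataError, InvalidArgumentError
from affectlearn.models import (
    BoostingRegressor,
    ModelSpec,
    RidgeRegressor,
    fit_ridge,
    rfecv,
    tune,
)


def ridge_loss_minimizer(X, y, alpha):
    """Independent numeric minimizer of the penalized loss on the
    standardized design (BFGS), returning predictions on X."""
    mu, sd = X.mean(axis=0), X.std(axis=0)
    scale = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / scale
    Z[:, sd == 0] = 0.0

    def loss(wb):
        w, b = wb[:-1], wb[-1]
        r = y - Z @ w - b
        return r @ r + alpha * (w @ w)

    res = minimize(loss, np.zeros(X.shape[1] + 1), method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 5000})
    w, b = res.x[:-1], res.x[-1]
    return Z @ w + b


class TestRidge:
    def test_zero_penalty_recovers_ols(self, rng):
        X = rng.standard_normal((30, 4))
        beta = np.array([1.0, -2.0, 0.5, 3.0])
        y = X @ beta + 0.7
        model = RidgeRegressor(alpha=0.0).fit(X, y)
        assert model.predict(X) == pytest.approx(y, abs=1e-8)

    def test_huge_penalty_shrinks_to_mean(self, rng):
        X = rng.standard_normal((25, 3))
        y = rng.standard_normal(25)
        model = RidgeRegressor(alpha=1e12).fit(X, y)
        assert np.linalg.norm(model.coef_) < 1e-9
        assert model.predict(X) == pytest.approx(np.full(25, y.mean()), abs=1e-6)

    def test_matches_numeric_minimizer(self, rng):
        X = rng.standard_normal((20, 5))
        y = X @ rng.standard_normal(5) + rng.standard_normal(20)
        model = RidgeRegressor(alpha=1.0).fit(X, y)
        assert model.predict(X) == pytest.approx(
            ridge_loss_minimizer(X, y, 1.0), abs=1e-6
        )

    def test_dual_and_primal_agree(self, rng):
        # p > n exercises the kernel form; compare against explicit primal
        X = rng.standard_normal((10, 40))
        y = rng.standard_normal(10)
        model = RidgeRegressor(alpha=2.0).fit(X, y)
        mu, sd = X.mean(axis=0), X.std(axis=0)
        Z = (X - mu) / np.where(sd > 0, sd, 1.0)
        w = np.linalg.solve(Z.T @ Z + 2.0 * np.eye(40), Z.T @ (y - y.mean()))
        assert model.std_coef_ == pytest.approx(w, abs=1e-8)

    def test_affine_rescaling_invariance(self, rng):
        X = rng.standard_normal((30, 5))
        y = rng.standard_normal(30)
        a = rng.uniform(0.1, 10, 5)
        b = rng.uniform(-5, 5, 5)
        m1 = RidgeRegressor(alpha=3.0).fit(X, y)
        m2 = RidgeRegressor(alpha=3.0).fit(X * a + b, y)
        assert m1.predict(X) == pytest.approx(m2.predict(X * a + b), abs=1e-8)

    def test_constant_column_handled(self, rng):
        X = np.column_stack([rng.standard_normal(20), np.full(20, 7.0)])
        y = rng.standard_normal(20)
        model = RidgeRegressor(alpha=1.0).fit(X, y)
        assert model.coef_[1] == 0.0

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            RidgeRegressor(alpha=1.0).fit([[np.inf], [1.0]], [0.0, 1.0])

    def test_wrapper_equivalent(self, rng):
        X = rng.standard_normal((15, 3))
        y = rng.standard_normal(15)
        assert fit_ridge(X, y, 2.0).predict(X) == pytest.approx(
            RidgeRegressor(alpha=2.0).fit(X, y).predict(X)
        )


class TestBoosting:
    def test_constant_target_predicted_exactly(self, rng):
        X = rng.standard_normal((20, 3))
        y = np.full(20, 4.2)
        model = BoostingRegressor(n_estimators=20).fit(X, y)
        assert model.predict(X) == pytest.approx(y, abs=1e-6)

    def test_step_function_capacity(self):
        X = np.linspace(0, 1, 200).reshape(-1, 1)
        y = (X[:, 0] > 0.5).astype(float)
        model = BoostingRegressor(max_depth=3, n_estimators=300,
                                  learning_rate=0.3).fit(X, y)
        rmse = np.sqrt(np.mean((model.predict(X) - y) ** 2))
        assert rmse < 0.01

    def test_same_seed_is_bit_identical(self, rng):
        X = rng.standard_normal((50, 8))
        y = rng.standard_normal(50)
        p1 = BoostingRegressor(subsample=0.7, random_state=5).fit(X, y).predict(X)
        p2 = BoostingRegressor(subsample=0.7, random_state=5).fit(X, y).predict(X)
        assert np.array_equal(p1, p2)

    def test_exposes_importances(self, rng):
        X = rng.standard_normal((60, 4))
        y = 3 * X[:, 2] + 0.1 * rng.standard_normal(60)
        model = BoostingRegressor(n_estimators=50).fit(X, y)
        w = model.feature_weights_
        assert w.shape == (4,) and w.argmax() == 2


class TestTune:
    def test_single_candidate_space(self, rng):
        X = rng.standard_normal((12, 3))
        y = rng.standard_normal(12)
        spec = ModelSpec(family="ridge", space={"log10_alpha": (1.0, 1.0)}, seed=0)
        best, log = tune(spec, X, y, budget=3)
        assert best == {"log10_alpha": 1.0}
        assert len(log) == 3

    def test_grid_prefers_informative_penalty(self, rng):
        # strongly linear data: lambda = 0.01 must beat lambda = 1e6
        X = rng.standard_normal((30, 3))
        y = X @ np.array([2.0, -1.0, 0.5])
        spec = ModelSpec(family="ridge", seed=0)
        best, log = tune(
            spec, X, y,
            candidates=[{"log10_alpha": -2.0}, {"log10_alpha": 6.0}],
        )
        assert best == {"log10_alpha": -2.0}
        assert len(log) == 2 and all("cv_rmse" in e for e in log)

    def test_search_log_reproducible_from_seed(self, rng):
        X = rng.standard_normal((12, 3))
        y = rng.standard_normal(12)
        spec = ModelSpec(family="ridge", seed=3)
        _, log1 = tune(spec, X, y, budget=5)
        _, log2 = tune(spec, X, y, budget=5)
        assert log1 == log2

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            tune(ModelSpec(family="ridge"), rng.standard_normal((4, 2)),
                 rng.standard_normal(4))

    def test_zero_budget_rejected(self, rng):
        with pytest.raises(InvalidArgumentError):
            tune(ModelSpec(family="ridge"), rng.standard_normal((10, 2)),
                 rng.standard_normal(10), budget=0)

    def test_grouped_folds_never_leak(self):
        # every candidate is scored on held-out probands only
        from affectlearn.models import _cv_folds

        groups = np.repeat(np.arange(6), 4)
        rng = np.random.default_rng(0)
        for tr, va in _cv_folds(len(groups), groups, 3, rng):
            assert not set(tr) & set(va)
            assert not set(groups[tr]) & set(groups[va])


class TestRFECV:
    def test_planted_support_recovered(self):
        hits = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 60
            informative = [f"inf_{i}" for i in range(5)]
            noise = [f"noise_{i}" for i in range(50)]
            X = rng.standard_normal((n, 55))
            beta = np.array([3.0, -2.5, 2.0, -1.5, 1.0])
            y = X[:, :5] @ beta + 0.3 * rng.standard_normal(n)
            spec = ModelSpec(family="ridge", seed=seed)
            kept = rfecv(spec, X, y, informative + noise,
                         params={"log10_alpha": 0.0}, seed=seed)
            hits.append(len(set(kept) & set(informative)))
        assert np.median(hits) >= 4

    def test_identical_copies_tie_broken_by_name(self, rng):
        x = rng.standard_normal(30)
        X = np.column_stack([x, x, x])
        y = 2 * x
        spec = ModelSpec(family="ridge", seed=0)
        kept = rfecv(spec, X, y, ["a", "b", "c"],
                     params={"log10_alpha": -10.0}, seed=0)
        assert len(kept) == 1

    def test_single_feature_is_identity(self, rng):
        X = rng.standard_normal((20, 1))
        y = rng.standard_normal(20)
        spec = ModelSpec(family="ridge", seed=0)
        assert rfecv(spec, X, y, ["only"], seed=0) == ["only"]
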