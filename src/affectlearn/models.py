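"""Regression models and model selection.

Two regressor families are used to probe the predictive value of the sensor
features: an l2-regularized linear model (ridge regression, closed form)
and gradient-boosted trees (XGBoost backend). Both are scikit-learn-style
estimators (``fit`` / ``predict`` / ``get_params``) so they compose with
pipelines and the cross-validation machinery in :mod:`affectlearn.evaluation`.

Feature standardization is part of the ridge estimator itself: column means
and standard deviations are computed on the training rows only and frozen
for prediction, so no information from held-out rows leaks into the fit.

Hyperparameters are tuned per training set with a seeded random search over
a fixed space, scored by threefold cross-validated RMSE (folds grouped by
proband where rows are nested within probands). Feature selection, when
enabled, uses recursive feature elimination with cross-validation: the 10%
of features with the smallest absolute weight/importance are dropped per
iteration and the subset with the best CV RMSE wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import GroupKFold, KFold
from sklearn.utils.validation import check_is_fitted, validate_data

from .errors import InsufficientDataError, InvalidArgumentError

#: Default hyperparameter search spaces (log10-lambda for ridge).
RIDGE_SPACE: dict[str, tuple[float, float]] = {"log10_alpha": (-4.0, 6.0)}
BOOSTING_SPACE: dict[str, tuple[float, float]] = {
    "max_depth": (2, 8),           # int
    "learning_rate": (0.01, 0.3),  # log-uniform
    "n_estimators": (50, 500),     # int
    "subsample": (0.5, 1.0),
}

DEFAULT_TUNE_BUDGET = 50


class RidgeRegressor(RegressorMixin, BaseEstimator):
    """l2-regularized linear regression with built-in standardization.

    Minimizes ``||y - Xw - b||^2 + alpha * ||w||^2`` with an unpenalized
    intercept ``b``, in closed form, on column-standardized features
    (training mean 0, sd 1; constant columns are zeroed rather than
    divided by zero). For ``alpha > 0`` the solution is unique; ``alpha=0``
    falls back to the minimum-norm least-squares solution.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Weights on the *raw* (unstandardized) feature scale.
    intercept_ : float
    """

    def __init__(self, alpha: float = 1.0, standardize: bool = True):
        self.alpha = alpha
        self.standardize = standardize

    def fit(self, X, y):
        X, y = validate_data(self, X, y, y_numeric=True)
        if self.alpha < 0:
            raise InvalidArgumentError("alpha must be >= 0")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise InvalidArgumentError("non-finite values in X or y")
        n, p = X.shape
        if self.standardize:
            mu = X.mean(axis=0)
            sd = X.std(axis=0, ddof=0)
            scale = np.where(sd > 0, sd, 1.0)
        else:
            mu = np.zeros(p)
            sd = np.ones(p)
            scale = sd
        Z = (X - mu) / scale
        if self.standardize:
            Z[:, sd == 0] = 0.0
        y_mean = y.mean()
        yc = y - y_mean

        if self.alpha == 0:
            w, *_ = np.linalg.lstsq(Z, yc, rcond=None)
        elif p <= n:
            A = Z.T @ Z + self.alpha * np.eye(p)
            w = np.linalg.solve(A, Z.T @ yc)
        else:  # dual form: cheaper when features outnumber rows
            K = Z @ Z.T + self.alpha * np.eye(n)
            w = Z.T @ np.linalg.solve(K, yc)

        self.scale_ = scale
        self.coef_ = w / scale
        self.intercept_ = float(y_mean - mu @ self.coef_)
        self.std_coef_ = w  # weights on the standardized scale
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return X @ self.coef_ + self.intercept_

    @property
    def feature_weights_(self) -> np.ndarray:
        """Standardized-scale weights, comparable across features."""
        check_is_fitted(self)
        return self.std_coef_


class BoostingRegressor(RegressorMixin, BaseEstimator):
    """Gradient-boosted regression trees (XGBoost backend).

    Deterministic given ``random_state`` (single-threaded training), and
    exposes per-feature importance weights — the number of times a feature
    is used to split, normalized — for importance tables.
    """

    def __init__(
        self,
        max_depth: int = 3,
        learning_rate: float = 0.1,
        n_estimators: int = 100,
        subsample: float = 1.0,
        random_state: int = 0,
    ):
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.n_estimators = n_estimators
        self.subsample = subsample
        self.random_state = random_state

    def fit(self, X, y):
        import xgboost as xgb

        X, y = validate_data(self, X, y, y_numeric=True)
        self.booster_ = xgb.XGBRegressor(
            max_depth=int(self.max_depth),
            learning_rate=self.learning_rate,
            n_estimators=int(self.n_estimators),
            subsample=self.subsample,
            random_state=int(self.random_state),
            n_jobs=1,
            tree_method="hist",
            importance_type="weight",
        )
        self.booster_.fit(X, y)
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.booster_.predict(X).astype(float)

    @property
    def feature_weights_(self) -> np.ndarray:
        check_is_fitted(self)
        imp = self.booster_.feature_importances_
        return np.asarray(imp, dtype=float)


@dataclass
class ModelSpec:
    """A model family plus its tuning configuration."""

    family: str = "ridge"  # 'ridge' | 'boosting'
    space: dict[str, tuple[float, float]] | None = None
    standardize: bool = True
    seed: int = 0
    budget: int = DEFAULT_TUNE_BUDGET
    select_features: bool = False  # run RFECV on each training set

    def __post_init__(self) -> None:
        if self.family not in ("ridge", "boosting"):
            raise InvalidArgumentError("family must be 'ridge' or 'boosting'")
        if self.space is None:
            self.space = dict(RIDGE_SPACE if self.family == "ridge" else BOOSTING_SPACE)
        for k, (lo, hi) in self.space.items():
            if not (np.isfinite(lo) and np.isfinite(hi)):
                raise InvalidArgumentError(f"search bounds for {k} must be finite")

    def make(self, params: dict[str, Any] | None = None):
        """Instantiate the estimator with tuned (or default) parameters."""
        params = params or {}
        if self.family == "ridge":
            alpha = 10.0 ** params.get("log10_alpha", 0.0)
            return RidgeRegressor(alpha=alpha, standardize=self.standardize)
        return BoostingRegressor(random_state=self.seed, **params)

    def sample_params(self, rng: np.random.Generator) -> dict[str, Any]:
        """Draw one candidate from the search space."""
        if self.family == "ridge":
            lo, hi = self.space["log10_alpha"]
            return {"log10_alpha": float(rng.uniform(lo, hi))}
        d_lo, d_hi = self.space["max_depth"]
        r_lo, r_hi = self.space["n_estimators"]
        l_lo, l_hi = self.space["learning_rate"]
        s_lo, s_hi = self.space["subsample"]
        return {
            "max_depth": int(rng.integers(int(d_lo), int(d_hi) + 1)),
            "learning_rate": float(np.exp(rng.uniform(np.log(l_lo), np.log(l_hi)))),
            "n_estimators": int(rng.integers(int(r_lo), int(r_hi) + 1)),
            "subsample": float(rng.uniform(s_lo, s_hi)),
        }


def fit_ridge(X, y, alpha: float, standardize: bool = True) -> RidgeRegressor:
    """Fit the closed-form ridge model; thin wrapper over the estimator."""
    return RidgeRegressor(alpha=alpha, standardize=standardize).fit(X, y)


def fit_boosting(X, y, hyperparams: dict | None = None, seed: int = 0) -> BoostingRegressor:
    """Fit gradient-boosted trees; thin wrapper over the estimator."""
    return BoostingRegressor(random_state=seed, **(hyperparams or {})).fit(X, y)


def _cv_folds(n: int, groups, n_splits: int, rng: np.random.Generator):
    """Threefold (or fewer) CV splits; grouped by proband when given."""
    if groups is not None:
        groups = np.asarray(groups)
        n_groups = len(np.unique(groups))
        k = min(n_splits, n_groups)
        if k < 2:
            raise InsufficientDataError("need >= 2 groups for grouped CV")
        yield from GroupKFold(n_splits=k).split(np.empty((n, 1)), groups=groups)
    else:
        k = min(n_splits, n)
        if k < 2:
            raise InsufficientDataError("need >= 2 rows for CV")
        kf = KFold(n_splits=k, shuffle=True, random_state=int(rng.integers(2**31)))
        yield from kf.split(np.empty((n, 1)))


def _cv_rmse(spec: ModelSpec, params, X, y, groups, rng) -> float:
    errs = []
    for tr, va in _cv_folds(len(y), groups, 3, rng):
        est = spec.make(params).fit(X[tr], y[tr])
        resid = est.predict(X[va]) - y[va]
        errs.append(np.sqrt(np.mean(resid**2)))
    return float(np.mean(errs))


def tune(
    spec: ModelSpec,
    X,
    y,
    groups=None,
    budget: int | None = None,
    seed: int | None = None,
    candidates: Sequence[dict[str, Any]] | None = None,
) -> tuple[dict[str, Any], list[dict[str, Any]]]:
    """Hyperparameter tuning with threefold CV.

    By default a seeded random search over ``spec.space``; pass
    ``candidates`` to evaluate an explicit list (grid) instead. Returns
    ``(best_params, log)`` where ``log`` records every candidate and its CV
    RMSE in evaluation order (reproducible from the seed). Fold assignments
    are fixed before the search, so every candidate is scored on the same
    splits and never on rows it trained on.
    """
    budget = spec.budget if budget is None else budget
    if budget < 1:
        raise InvalidArgumentError("budget must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < 6:
        raise InsufficientDataError("need >= 6 rows to tune with threefold CV")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    folds = list(_cv_folds(len(y), groups, 3, rng))

    if candidates is None:
        candidates = [spec.sample_params(rng) for _ in range(budget)]
    log: list[dict[str, Any]] = []
    best_params, best_score = None, np.inf
    for params in candidates:
        errs = []
        for tr, va in folds:
            est = spec.make(params).fit(X[tr], y[tr])
            resid = est.predict(X[va]) - y[va]
            errs.append(float(np.sqrt(np.mean(resid**2))))
        score = float(np.mean(errs))
        log.append({"params": params, "cv_rmse": score})
        if score < best_score:
            best_params, best_score = params, score
    return best_params, log


def rfecv(
    spec: ModelSpec,
    X,
    y,
    feature_names: Sequence[str],
    groups=None,
    step: float = 0.1,
    params: dict[str, Any] | None = None,
    seed: int | None = None,
) -> list[str]:
    """Recursive feature elimination with cross-validation.

    Repeatedly fits the model on all rows, drops the ``step`` fraction of
    features with the smallest absolute weight/importance (ties broken by
    feature-name order), and scores each candidate subset by threefold CV
    RMSE; the best-scoring subset is returned. Fewer than two features are
    returned unchanged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    names = list(feature_names)
    if X.shape[1] != len(names):
        raise InvalidArgumentError("feature_names length must match X columns")
    if len(names) < 2:
        return names
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    active = list(range(len(names)))
    best_subset, best_score = None, np.inf
    while True:
        score = _cv_rmse(spec, params, X[:, active], y, groups, np.random.default_rng(rng.integers(2**31)))
        # prefer smaller subsets when CV scores tie within numerical noise
        tol = 1e-9 * max(1.0, abs(best_score) if np.isfinite(best_score) else 1.0)
        if best_subset is None or score < best_score - tol:
            best_subset, best_score = list(active), score
        elif abs(score - best_score) <= tol and len(active) < len(best_subset):
            best_subset, best_score = list(active), score
        if len(active) == 1:
            break
        est = spec.make(params).fit(X[:, active], y)
        w = np.abs(est.feature_weights_)
        n_drop = max(1, int(np.floor(step * len(active))))
        # sort by (|weight|, name) ascending: smallest weights go, name order
        # breaks exact ties deterministically
        order = sorted(range(len(active)), key=lambda j: (w[j], names[active[j]]))
        drop = set(order[:n_drop])
        active = [a for j, a in enumerate(active) if j not in drop]
    return [names[i] for i in best_subset]
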