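"""Cross-validated evaluation against mean-of-others baselines.

Outcome scores (one label per proband) are evaluated with leave-one-out
cross-validation (LOO); the 13 experience samples nested within each
proband are evaluated with leave-one-proband-out cross-validation (LOPO),
where all of a proband's rows are held out together and the inner tuning
folds are likewise grouped by proband, so a model can never profit from
having seen the held-out person.

Each model is compared against a sensor-free baseline that predicts the
mean label of all *other* probands:

* LOO:  ``yhat_i = mean(y \\ {y_i})`` — note this makes the baseline's
  prediction a strictly decreasing affine function of the held-out label,
  so its label-prediction correlation is exactly -1 for any non-constant
  label vector, and its RMSE equals ``n/(n-1)`` times the population
  standard deviation of the labels.
* LOPO: a constant per held-out proband — the grand mean of every other
  proband's valid samples.

Errors are summarized as RMSE and MAE plus the label-prediction
correlation (LPC, Pearson r between held-out predictions and true labels).
Model and baseline are compared with a paired two-sided Student's t-test on
per-proband absolute errors; the effect size is Cohen's d for paired data,
``mean(diff)/sd(diff)`` with ``diff = baseline error - model error`` (so
positive d means the model beats the baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, InvalidArgumentError
from .models import ModelSpec, rfecv, tune


# ---------------------------------------------------------------------------
# baselines and metrics
# ---------------------------------------------------------------------------

def loo_baseline(y) -> np.ndarray:
    """Mean-of-others predictions for every position of ``y``.

    >>> loo_baseline([1, 2, 3])
    array([2.5, 2. , 1.5])
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2:
        raise InvalidArgumentError("need >= 2 labels for the LOO baseline")
    return (y.sum() - y) / (n - 1)


def lopo_baseline(Y: pd.DataFrame) -> pd.DataFrame:
    """Mean-of-others predictions for proband-nested labels.

    ``Y`` is a probands x samples frame (NaN = missing). Each proband's
    prediction is the single grand mean of all other probands' non-missing
    entries, repeated across that proband's samples. Probands with no valid
    label at all are excluded (all-NaN predictions) with a warning.
    """
    if Y.shape[0] < 2:
        raise InvalidArgumentError("need >= 2 probands for the LOPO baseline")
    vals = Y.to_numpy(dtype=float)
    out = np.full_like(vals, np.nan)
    for i in range(vals.shape[0]):
        # mean over the other probands' entries only, so the prediction is
        # exactly independent of the held-out labels
        others = np.delete(vals, i, axis=0)
        n_others = np.sum(~np.isnan(others))
        if n_others == 0:
            continue
        out[i, :] = np.nansum(others) / n_others
    return pd.DataFrame(out, index=Y.index, columns=Y.columns)


@dataclass
class Metrics:
    rmse: float
    mae: float
    lpc: float  # NaN when either side is constant

    def as_dict(self) -> dict[str, float]:
        return {"rmse": self.rmse, "mae": self.mae, "lpc": self.lpc}


def metrics(pred, true) -> Metrics:
    """RMSE, MAE and label-prediction correlation of a prediction vector."""
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape:
        raise InvalidArgumentError("pred and true must have equal length")
    ok = ~(np.isnan(pred) | np.isnan(true))
    pred, true = pred[ok], true[ok]
    if len(pred) == 0:
        return Metrics(float("nan"), float("nan"), float("nan"))
    resid = pred - true
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    if len(pred) >= 2 and np.std(pred) > 0 and np.std(true) > 0:
        lpc = float(np.corrcoef(pred, true)[0, 1])
    else:
        lpc = float("nan")
    return Metrics(rmse, mae, lpc)


@dataclass
class Comparison:
    t: float
    p: float  # NaN when the difference vector has zero variance
    d: float
    zero_variance: bool = False

    def as_dict(self) -> dict[str, float]:
        return {"t": self.t, "p": self.p, "d": self.d}


def compare_to_baseline(model_errors, baseline_errors) -> Comparison:
    """Paired two-sided t-test of per-fold absolute errors vs. the baseline.

    ``diff = baseline - model``; positive ``d = mean(diff)/sd(diff)`` means
    the model's errors are smaller. Zero-variance differences are flagged
    and reported with ``p`` missing and ``d = 0``.
    """
    m = np.asarray(model_errors, dtype=float)
    b = np.asarray(baseline_errors, dtype=float)
    if m.shape != b.shape:
        raise InvalidArgumentError("error vectors must have equal length")
    diff = b - m
    sd = np.std(diff, ddof=1) if len(diff) > 1 else 0.0
    if sd == 0:
        # identical errors: no difference at all -> p = 1; a constant
        # non-zero difference leaves the t statistic undefined -> p missing
        p = 1.0 if np.all(diff == 0) else float("nan")
        return Comparison(t=0.0, p=p, d=0.0, zero_variance=True)
    t_stat, p_val = stats.ttest_rel(b, m)
    d = float(np.mean(diff) / sd)
    return Comparison(t=float(t_stat), p=float(p_val), d=d)


def cronbach_alpha(items) -> float:
    """Cronbach's alpha of a probands x items response matrix.

    ``alpha = k/(k-1) * (1 - sum(var_j) / var(total))`` with sample
    variances (n-1).
    """
    mat = np.asarray(items, dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 2 or mat.shape[0] < 3:
        raise InvalidArgumentError("need >= 3 probands and >= 2 items")
    if np.any(np.isnan(mat)):
        raise InvalidArgumentError("missing item responses are not supported")
    k = mat.shape[1]
    item_vars = mat.var(axis=0, ddof=1)
    total_var = mat.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise InvalidArgumentError("total score has zero variance")
    return float(k / (k - 1) * (1 - item_vars.sum() / total_var))


# ---------------------------------------------------------------------------
# cross-validation drivers
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Held-out predictions and summary statistics of one CV experiment."""

    scheme: str  # 'loo' | 'lopo'
    predictions: pd.DataFrame  # proband_id, sample_index, y_true, y_pred, y_baseline
    model_metrics: Metrics
    baseline_metrics: Metrics
    comparison: Comparison
    importance: pd.Series  # mean |weight| per feature over folds
    per_fold: pd.DataFrame = field(default_factory=pd.DataFrame)

    def recompute_metrics(self) -> tuple[Metrics, Metrics]:
        """Re-aggregate metrics from the stored predictions (audit hook)."""
        if self.scheme == "loo":
            return (
                metrics(self.predictions["y_pred"], self.predictions["y_true"]),
                metrics(self.predictions["y_baseline"], self.predictions["y_true"]),
            )
        return _lopo_aggregate(self.predictions)


def _prepare(data: pd.DataFrame):
    feature_cols = [c for c in data.columns if c not in ("proband_id", "sample_index", "y")]
    X = data[feature_cols].to_numpy(dtype=float)
    y = data["y"].to_numpy(dtype=float)
    return feature_cols, X, y


def loo_cv(data: pd.DataFrame, spec: ModelSpec) -> CVResult:
    """Leave-one-out CV for outcome-level data (one row per proband).

    For each proband the model is tuned (threefold CV) and fit on the
    remaining rows, then predicts the held-out row; metrics are computed on
    the pooled prediction vector and compared against the mean-of-others
    baseline with a paired t-test on absolute errors.
    """
    if (data["sample_index"] != 0).any():
        raise InvalidArgumentError("loo_cv expects outcome-level rows (sample_index 0)")
    if data["proband_id"].duplicated().any():
        raise InvalidArgumentError("one row per proband required")
    n = len(data)
    if n < 5:
        raise InsufficientDataError("need >= 5 probands for LOO-CV")
    feature_cols, X, y = _prepare(data)
    y_baseline = loo_baseline(y)

    preds = np.empty(n)
    importances = np.zeros(len(feature_cols))
    imp_counts = np.zeros(len(feature_cols))
    for i in range(n):
        tr = np.arange(n) != i
        Xtr, ytr = X[tr], y[tr]
        cols = list(range(len(feature_cols)))
        if spec.select_features:
            kept = rfecv(
                spec, Xtr, ytr, feature_cols, seed=spec.seed + 7 * i
            )
            cols = [feature_cols.index(c) for c in kept]
        params, _ = tune(spec, Xtr[:, cols], ytr, seed=spec.seed + i)
        est = spec.make(params).fit(Xtr[:, cols], ytr)
        preds[i] = est.predict(X[i : i + 1, cols])[0]
        w = np.abs(est.feature_weights_)
        importances[cols] += w
        imp_counts[cols] += 1

    predictions = pd.DataFrame(
        {
            "proband_id": data["proband_id"].to_numpy(),
            "sample_index": 0,
            "y_true": y,
            "y_pred": preds,
            "y_baseline": y_baseline,
        }
    )
    with np.errstate(invalid="ignore"):
        importance = pd.Series(
            np.where(imp_counts > 0, importances / np.maximum(imp_counts, 1), 0.0),
            index=feature_cols,
        ).sort_values(ascending=False)
    return CVResult(
        scheme="loo",
        predictions=predictions,
        model_metrics=metrics(preds, y),
        baseline_metrics=metrics(y_baseline, y),
        comparison=compare_to_baseline(np.abs(preds - y), np.abs(y_baseline - y)),
        importance=importance,
    )


def _lopo_aggregate(predictions: pd.DataFrame) -> tuple[Metrics, Metrics]:
    """Average per-proband metrics, the LOPO aggregation rule."""
    rows_m, rows_b = [], []
    for _, g in predictions.groupby("proband_id", sort=False):
        rows_m.append(metrics(g["y_pred"], g["y_true"]))
        rows_b.append(metrics(g["y_baseline"], g["y_true"]))

    def _avg(rows: list[Metrics]) -> Metrics:
        return Metrics(
            rmse=float(np.nanmean([r.rmse for r in rows])),
            mae=float(np.nanmean([r.mae for r in rows])),
            lpc=(
                float(np.nanmean([r.lpc for r in rows]))
                if not np.all(np.isnan([r.lpc for r in rows]))
                else float("nan")
            ),
        )

    return _avg(rows_m), _avg(rows_b)


def lopo_cv(data: pd.DataFrame, spec: ModelSpec, pooled_lpc: bool = False) -> CVResult:
    """Leave-one-proband-out CV for process-level data (13 rows/proband).

    All rows of the held-out proband are predicted by a model tuned and fit
    on every other proband's rows (inner folds grouped by proband). Metrics
    are computed per proband and averaged; set ``pooled_lpc`` to compute the
    correlation on the pooled prediction vector instead.
    """
    if (data["sample_index"] == 0).any():
        raise InvalidArgumentError("lopo_cv expects process-level rows (sample_index >= 1)")
    # invalid (missing) process labels: those proband-sample pairs are
    # excluded from training and evaluation alike
    data = data.dropna(subset=["y"])
    probands = data["proband_id"].unique()
    if len(probands) < 5:
        raise InsufficientDataError("need >= 5 probands for LOPO-CV")
    feature_cols, X, y = _prepare(data)
    groups = data["proband_id"].to_numpy()

    Y_wide = data.pivot_table(
        index="proband_id", columns="sample_index", values="y", sort=False
    )
    B_wide = lopo_baseline(Y_wide)

    frames = []
    importances = np.zeros(len(feature_cols))
    imp_counts = np.zeros(len(feature_cols))
    for k, pid in enumerate(probands):
        held = groups == pid
        tr = ~held
        Xtr, ytr, gtr = X[tr], y[tr], groups[tr]
        cols = list(range(len(feature_cols)))
        if spec.select_features:
            kept = rfecv(spec, Xtr, ytr, feature_cols, groups=gtr, seed=spec.seed + 7 * k)
            cols = [feature_cols.index(c) for c in kept]
        params, _ = tune(spec, Xtr[:, cols], ytr, groups=gtr, seed=spec.seed + k)
        est = spec.make(params).fit(Xtr[:, cols], ytr)
        yhat = est.predict(X[held][:, cols])
        sample_idx = data.loc[held, "sample_index"].to_numpy()
        frames.append(
            pd.DataFrame(
                {
                    "proband_id": pid,
                    "sample_index": sample_idx,
                    "y_true": y[held],
                    "y_pred": yhat,
                    "y_baseline": B_wide.loc[pid, sample_idx].to_numpy(),
                }
            )
        )
        w = np.abs(est.feature_weights_)
        importances[cols] += w
        imp_counts[cols] += 1

    predictions = pd.concat(frames, ignore_index=True)
    model_m, base_m = _lopo_aggregate(predictions)
    if pooled_lpc:
        model_m = Metrics(
            model_m.rmse,
            model_m.mae,
            metrics(predictions["y_pred"], predictions["y_true"]).lpc,
        )
        base_m = Metrics(
            base_m.rmse,
            base_m.mae,
            metrics(predictions["y_baseline"], predictions["y_true"]).lpc,
        )

    per_prob_model = predictions.groupby("proband_id", sort=False).apply(
        lambda g: float(np.mean(np.abs(g["y_pred"] - g["y_true"]))),
        include_groups=False,
    )
    per_prob_base = predictions.groupby("proband_id", sort=False).apply(
        lambda g: float(np.mean(np.abs(g["y_baseline"] - g["y_true"]))),
        include_groups=False,
    )
    importance = pd.Series(
        np.where(imp_counts > 0, importances / np.maximum(imp_counts, 1), 0.0),
        index=feature_cols,
    ).sort_values(ascending=False)
    return CVResult(
        scheme="lopo",
        predictions=predictions,
        model_metrics=model_m,
        baseline_metrics=base_m,
        comparison=compare_to_baseline(per_prob_model.to_numpy(), per_prob_base.to_numpy()),
        importance=importance,
    )


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def report(results: dict[str, dict[str, CVResult]]) -> pd.DataFrame:
    """Result table: one block per target scale, rows per method + baseline.

    ``results`` maps target scale -> {method name -> CVResult}; the methods
    of one scale must share their baseline. Column ``marker`` carries ``+``
    when the method's RMSE is below the baseline's and ``*`` when the paired
    test against the baseline has p < 0.05.
    """
    rows = []
    for scale, by_method in results.items():
        baseline_m = None
        for method, res in by_method.items():
            m = res.model_metrics
            c = res.comparison
            marker = ""
            if m.rmse < res.baseline_metrics.rmse:
                marker += "+"
            if np.isfinite(c.p) and c.p < 0.05:
                marker += "*"
            rows.append(
                {
                    "scale": scale,
                    "method": method,
                    "RMSE": m.rmse,
                    "MAE": m.mae,
                    "r": m.lpc,
                    "p": c.p,
                    "d": c.d,
                    "marker": marker,
                }
            )
            baseline_m = res.baseline_metrics
        if baseline_m is not None:
            rows.append(
                {
                    "scale": scale,
                    "method": "baseline",
                    "RMSE": baseline_m.rmse,
                    "MAE": baseline_m.mae,
                    "r": baseline_m.lpc,
                    "p": float("nan"),
                    "d": float("nan"),
                    "marker": "",
                }
            )
    columns = ["scale", "method", "RMSE", "MAE", "r", "p", "d", "marker"]
    return pd.DataFrame(rows, columns=columns)


def write_report(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def importance_table(result: CVResult, top: int = 10) -> pd.DataFrame:
    """Top features by mean absolute weight over CV folds, descending."""
    s = result.importance.head(top)
    return pd.DataFrame({"feature": s.index, "weight": s.to_numpy()})
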