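"""Baselines, metrics, CV drivers, reliability, and report tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from affectlearn.errors import InsufficientDataError, InvalidArgumentError
from affectlearn.evaluation import (
    compare_to_baseline,
    cronbach_alpha,
    loo_baseline,
    loo_cv,
    lopo_baseline,
    lopo_cv,
    metrics,
    report,
    write_report,
)
from affectlearn.models import ModelSpec


class TestLooBaseline:
    def test_three_values(self):
        assert loo_baseline([1, 2, 3]) == pytest.approx([2.5, 2.0, 1.5])

    def test_constant_labels(self):
        pred = loo_baseline([4.0, 4.0, 4.0])
        assert pred == pytest.approx([4.0, 4.0, 4.0])
        assert np.isnan(metrics(pred, [4.0, 4.0, 4.0]).lpc)

    def test_single_label_rejected(self):
        with pytest.raises(InvalidArgumentError):
            loo_baseline([1.0])

    @given(
        st.lists(st.floats(-100, 100), min_size=3, max_size=30).filter(
            lambda v: max(v) - min(v) > 1e-6
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_lpc_is_exactly_minus_one(self, y):
        # the prediction is a strictly decreasing affine function of the
        # held-out label, so the correlation is -1 analytically
        m = metrics(loo_baseline(y), y)
        assert m.lpc == pytest.approx(-1.0, abs=1e-9)

    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=30).filter(
            lambda v: max(v) - min(v) > 1e-9
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_rmse_identity(self, y):
        # LOO-baseline RMSE = n/(n-1) * population sd of the labels
        y = np.asarray(y)
        n = len(y)
        m = metrics(loo_baseline(y), y)
        assert m.rmse == pytest.approx(n / (n - 1) * y.std(ddof=0), rel=1e-9)


class TestLopoBaseline:
    def test_two_probands(self):
        Y = pd.DataFrame([np.zeros(13), np.full(13, 4.0)], index=["a", "b"])
        pred = lopo_baseline(Y)
        assert (pred.loc["a"] == 4.0).all()
        assert (pred.loc["b"] == 0.0).all()

    def test_constant_cohort_rmse_zero(self):
        Y = pd.DataFrame(np.full((3, 13), 2.5))
        pred = lopo_baseline(Y)
        assert metrics(pred.to_numpy().ravel(), Y.to_numpy().ravel()).rmse == 0.0

    def test_matches_brute_force_grand_mean(self, rng):
        Y = pd.DataFrame(rng.standard_normal((3, 13)))
        pred = lopo_baseline(Y)
        for i in range(3):
            others = np.delete(Y.to_numpy(), i, axis=0).ravel()
            assert pred.iloc[i].to_numpy() == pytest.approx(others.mean())

    def test_missing_entries_excluded_from_mean(self):
        Y = pd.DataFrame([[1.0, np.nan], [3.0, 5.0]], index=["a", "b"])
        pred = lopo_baseline(Y)
        assert (pred.loc["a"] == 4.0).all()
        assert (pred.loc["b"] == 1.0).all()


class TestMetrics:
    def test_perfect_prediction(self):
        m = metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (m.rmse, m.mae, m.lpc) == (0.0, 0.0, pytest.approx(1.0))

    def test_constant_offset(self):
        m = metrics([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert (m.rmse, m.mae) == (1.0, 1.0)
        assert m.lpc == pytest.approx(1.0)

    def test_hand_computed_case(self):
        m = metrics([0.0, 0.0, 1.0, 1.0], [0.0, 1.0, 0.0, 1.0])
        assert m.rmse == pytest.approx(np.sqrt(0.5))
        assert m.mae == 0.5
        assert m.lpc == pytest.approx(0.0)


class TestCompareToBaseline:
    def test_identical_errors(self):
        c = compare_to_baseline([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (c.t, c.p, c.d) == (0.0, 1.0, 0.0)
        assert c.zero_variance

    def test_constant_nonzero_difference_flagged(self):
        c = compare_to_baseline([0.0, 0.0, 0.0, 0.0], [1.0, 1.0, 1.0, 1.0])
        assert c.zero_variance and np.isnan(c.p) and c.d == 0.0

    def test_textbook_t_statistic(self):
        # diffs [1, 2, 3]: t = 2 / (1/sqrt(3)) = 3.464, p ~ 0.0742 (df=2)
        c = compare_to_baseline([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
        assert c.t == pytest.approx(2 * np.sqrt(3), rel=1e-6)
        assert c.p == pytest.approx(0.0742, abs=5e-4)
        assert c.d == pytest.approx(2.0, rel=1e-9)


class TestCronbachAlpha:
    def test_identical_items(self, rng):
        col = rng.standard_normal(50)
        mat = np.column_stack([col] * 4)
        assert cronbach_alpha(mat) == pytest.approx(1.0)

    def test_independent_items_near_zero(self, rng):
        mat = rng.standard_normal((10000, 5))
        assert abs(cronbach_alpha(mat)) < 0.1

    def test_spearman_brown_two_items(self, rng):
        # two unit-variance items with correlation exactly 0.5 -> alpha 2/3
        raw = rng.standard_normal((400, 2))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        z1, z2 = q[:, 0], q[:, 1]
        x1 = z1
        x2 = 0.5 * z1 + np.sqrt(0.75) * z2
        assert cronbach_alpha(np.column_stack([x1, x2])) == pytest.approx(2 / 3)

    def test_input_validation(self):
        with pytest.raises(InvalidArgumentError):
            cronbach_alpha(np.ones((2, 5)))


def _outcome_frame(X, y):
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    df.insert(0, "proband_id", [f"P{i}" for i in range(len(y))])
    df.insert(1, "sample_index", 0)
    df["y"] = y
    return df


def _process_frame(X, y, groups, samples):
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    df.insert(0, "proband_id", groups)
    df.insert(1, "sample_index", samples)
    df["y"] = y
    return df


class TestLooCV:
    def test_recoverable_linear_signal(self, rng):
        n = 30
        X = rng.standard_normal((n, 5))
        y = 2 * X[:, 0] - 3 * X[:, 1]
        spec = ModelSpec(family="ridge", seed=0, budget=10)
        res = loo_cv(_outcome_frame(X, y), spec)
        assert res.model_metrics.lpc >= 0.95
        assert res.model_metrics.rmse < res.baseline_metrics.rmse

    def test_pure_noise_rarely_significant(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            X = rng.standard_normal((20, 10))
            y = rng.standard_normal(20)
            spec = ModelSpec(family="ridge", seed=seed, budget=8)
            res = loo_cv(_outcome_frame(X, y), spec)
            c = res.comparison
            if np.isfinite(c.p) and c.p < 0.05 and c.d > 0:
                wins += 1
        assert wins <= 2

    def test_too_few_probands_rejected(self, rng):
        X = rng.standard_normal((2, 3))
        with pytest.raises(InsufficientDataError):
            loo_cv(_outcome_frame(X, [0.0, 1.0]), ModelSpec(family="ridge"))

    def test_predictions_reaggregate_bit_exactly(self, rng):
        X = rng.standard_normal((12, 4))
        y = X[:, 0] + 0.1 * rng.standard_normal(12)
        res = loo_cv(_outcome_frame(X, y), ModelSpec(family="ridge", budget=5))
        model_m, base_m = res.recompute_metrics()
        assert model_m == res.model_metrics
        assert base_m == res.baseline_metrics


class TestLopoCV:
    def _planted(self, rng, n_probands=20, shared_gain=2.0, offset_sd=0.0):
        rows_X, rows_y, groups, samples = [], [], [], []
        for i in range(n_probands):
            x = rng.standard_normal((13, 3))
            offset = offset_sd * rng.standard_normal()
            y = shared_gain * x[:, 0] + offset + 0.2 * rng.standard_normal(13)
            rows_X.append(x)
            rows_y.append(y)
            groups += [f"P{i}"] * 13
            samples += list(range(1, 14))
        return _process_frame(
            np.vstack(rows_X), np.concatenate(rows_y), groups, samples
        )

    def test_shared_signal_beats_baseline(self, rng):
        df = self._planted(rng, shared_gain=2.0)
        res = lopo_cv(df, ModelSpec(family="ridge", seed=0, budget=8))
        assert res.model_metrics.rmse < res.baseline_metrics.rmse

    def test_proband_offsets_only_not_significant(self, rng):
        df = self._planted(rng, shared_gain=0.0, offset_sd=2.0)
        res = lopo_cv(df, ModelSpec(family="ridge", seed=0, budget=8))
        c = res.comparison
        assert not (np.isfinite(c.p) and c.p < 0.05 and c.d > 0)

    def test_constant_labels_zero_rmse(self, rng):
        df = self._planted(rng, shared_gain=0.0, offset_sd=0.0)
        df["y"] = 3.0
        res = lopo_cv(df, ModelSpec(family="ridge", seed=0, budget=4))
        assert res.model_metrics.rmse == pytest.approx(0.0, abs=1e-9)
        assert res.baseline_metrics.rmse == 0.0

    def test_heldout_labels_cannot_influence_own_prediction(self, rng):
        df = self._planted(rng, n_probands=6)
        spec = ModelSpec(family="ridge", seed=1, budget=4)
        res1 = lopo_cv(df, spec)
        df2 = df.copy()
        mask = df2["proband_id"] == "P0"
        df2.loc[mask, "y"] = df2.loc[mask, "y"] + 100.0
        res2 = lopo_cv(df2, spec)
        p1 = res1.predictions.query("proband_id == 'P0'")["y_pred"].to_numpy()
        p2 = res2.predictions.query("proband_id == 'P0'")["y_pred"].to_numpy()
        b1 = res1.predictions.query("proband_id == 'P0'")["y_baseline"].to_numpy()
        b2 = res2.predictions.query("proband_id == 'P0'")["y_baseline"].to_numpy()
        assert np.array_equal(p1, p2)
        assert np.array_equal(b1, b2)

    def test_missing_labels_excluded(self, rng):
        df = self._planted(rng, n_probands=6)
        df.loc[df.index[::13], "y"] = np.nan
        res = lopo_cv(df, ModelSpec(family="ridge", seed=0, budget=4))
        assert res.predictions["y_true"].notna().all()
        assert len(res.predictions) == df["y"].notna().sum()


class TestReport:
    def _fake_result(self, rmse, base_rmse, p):
        from affectlearn.evaluation import Comparison, CVResult, Metrics

        return CVResult(
            scheme="loo",
            predictions=pd.DataFrame(),
            model_metrics=Metrics(rmse, rmse * 0.8, 0.5),
            baseline_metrics=Metrics(base_rmse, base_rmse * 0.8, -1.0),
            comparison=Comparison(2.0, p, 0.4),
            importance=pd.Series(dtype=float),
        )

    def test_markers(self):
        table = report(
            {
                "scale_a": {
                    "ridge": self._fake_result(0.9, 1.0, 0.01),
                    "boosting": self._fake_result(1.1, 1.0, 0.5),
                }
            }
        )
        ridge = table[table.method == "ridge"].iloc[0]
        boosting = table[table.method == "boosting"].iloc[0]
        baseline = table[table.method == "baseline"].iloc[0]
        assert ridge.marker == "+*"
        assert boosting.marker == ""
        assert baseline.r == -1.0

    def test_empty_results_header_only(self, tmp_path):
        table = report({})
        path = tmp_path / "report.tsv"
        write_report(table, path)
        parsed = pd.read_csv(path, sep="\t")
        assert list(parsed.columns) == [
            "scale", "method", "RMSE", "MAE", "r", "p", "d", "marker",
        ]
        assert parsed.empty

    def test_round_trip(self, tmp_path):
        table = report({"s": {"ridge": self._fake_result(0.9, 1.0, 0.2)}})
        path = tmp_path / "report.tsv"
        write_report(table, path)
        parsed = pd.read_csv(path, sep="\t", keep_default_na=False)
        assert parsed.shape[0] == 2
        assert parsed.loc[0, "RMSE"] == pytest.approx(0.9)
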