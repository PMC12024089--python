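"""GSI regression, prediction metrics, and the abbreviation sweep."""

import numpy as np
import pytest
from scipy.stats import spearmanr
from sklearn.base import clone

import shortscale as ss
from shortscale.core import ValidationError


class TestFitGsiRegressor:
    def test_full_scale_recovers_the_mean_exactly(self, bifactor_1200):
        r = bifactor_1200
        y = ss.gsi_scores(r)
        model = ss.fit_gsi_regressor(r, r.item_ids, y, method="ols")
        np.testing.assert_allclose(model.coefficients, np.full(90, 1 / 90), atol=1e-10)
        assert model.intercept == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(model.predict(r), y, atol=1e-10)

    def test_single_predictor_identity(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(1, 6, size=(50, 1))
        r = ss.ResponseMatrix(vals, ["a"])
        model = ss.fit_gsi_regressor(r, ["a"], vals[:, 0].astype(float), "ols")
        assert model.coefficients[0] == pytest.approx(1.0, abs=1e-10)
        assert model.intercept == pytest.approx(0.0, abs=1e-9)

    def test_ols_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        vals = rng.integers(1, 6, size=(50, 3))
        y = rng.normal(size=50)
        r = ss.ResponseMatrix(vals, ["a", "b", "c"])
        model = ss.fit_gsi_regressor(r, ["a", "b", "c"], y, "ols")
        # oracle: solve X'X beta = X'y directly
        X = np.column_stack([np.ones(50), vals.astype(float)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert model.intercept == pytest.approx(beta[0], abs=1e-8)
        np.testing.assert_allclose(model.coefficients, beta[1:], atol=1e-8)

    def test_rank_deficient_design_suggests_ridge(self):
        vals = np.array([[1, 1], [2, 2], [3, 3], [4, 4], [5, 5]])
        r = ss.ResponseMatrix(vals, ["a", "b"])
        with pytest.raises(ValidationError, match="ridge"):
            ss.fit_gsi_regressor(r, ["a", "b"], np.arange(5.0), "ols")

    def test_robust_and_ridge_fit(self, tiny_responses):
        y = ss.gsi_scores(tiny_responses)
        for method in ("robust", "ridge"):
            model = ss.fit_gsi_regressor(tiny_responses, ["item_1", "item_2"], y, method)
            assert model.method == method
            assert model.predict(tiny_responses).shape == (30,)
        assert model.ridge_penalty in ss.abbreviate.RIDGE_PENALTY_GRID


class TestPredictionMetrics:
    def test_perfect_prediction(self):
        m = ss.prediction_metrics([1.0, 2, 3], [1.0, 2, 3])
        assert (m.rmse, m.r2, m.pearson_r) == (0.0, 1.0, pytest.approx(1.0))

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([1.0, 2, 3, 4])
        with pytest.raises(ValidationError, match="constant predictions"):
            ss.prediction_metrics(y, np.full(4, y.mean()))
        m = ss.prediction_metrics(y, np.full(4, y.mean()) + [0, 1e-9, 0, -1e-9])
        assert m.r2 == pytest.approx(0.0, abs=1e-6)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(11)
        y, yhat = rng.normal(size=40), rng.normal(size=40)
        m = ss.prediction_metrics(y, yhat)
        assert m.rmse == pytest.approx(np.sqrt(np.sum((y - yhat) ** 2) / 40), abs=1e-12)
        assert m.r2 == pytest.approx(
            1 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2), abs=1e-12
        )
        assert m.pearson_r == pytest.approx(np.corrcoef(y, yhat)[0, 1], abs=1e-12)

    def test_constant_target_is_explicit_error(self):
        with pytest.raises(ValidationError, match="constant target"):
            ss.prediction_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


@pytest.fixture(scope="module")
def split_1200(bifactor_1200):
    return ss.split_train_test(bifactor_1200, 0.2, seed=11)


class TestSweep:
    def test_tiny_stop_r_selects_k1(self, split_1200):
        train, test = split_1200
        scale, trace = ss.sweep_and_select(train, test, stop_r=1e-9, k_max=10)
        assert scale.k == 1 and scale.met_threshold
        assert len(trace.table) == 1

    def test_full_scale_saturates(self, split_1200):
        train, test = split_1200
        sub_train = train.subset(list(range(1, 13)))
        sub_test = test.subset(list(range(1, 13)))
        scale, trace = ss.sweep_and_select(sub_train, sub_test, stop_r=1.0, k_max=12)
        last = trace.table.iloc[-1]
        assert last["k"] == 12
        assert last["pearson_r"] == pytest.approx(1.0, abs=1e-10)
        assert last["rmse"] <= 1e-8

    def test_trend_and_minimality(self, split_1200):
        train, test = split_1200
        scale, trace = ss.sweep_and_select(train, test, stop_r=0.93, k_max=25)
        assert scale.met_threshold
        t = trace.table
        # selected k is minimal among entries meeting the threshold
        met = t[t["pearson_r"] >= 0.93]
        assert scale.k == met["k"].min()
        assert spearmanr(t["k"], t["pearson_r"]).statistic > 0.8

    def test_determinism(self, split_1200):
        train, test = split_1200
        s1, t1 = ss.sweep_and_select(train, test, stop_r=0.9, k_max=15)
        s2, t2 = ss.sweep_and_select(train, test, stop_r=0.9, k_max=15)
        assert s1.item_ids == s2.item_ids
        assert t1.table.equals(t2.table)

    def test_validation(self, split_1200):
        train, test = split_1200
        with pytest.raises(ValidationError):
            ss.sweep_and_select(train, test, stop_r=1.5)
        with pytest.raises(ValidationError):
            ss.sweep_and_select(train, test, k_max=0)


class TestModelComparison:
    def test_ols_beats_robust_and_ridge_under_gaussian_noise(self):
        """With Gaussian errors, OLS is the efficient estimator: averaged over
        seeds its held-out RMSE should not exceed Huber or ridge."""
        rmse = {"ols": [], "robust": [], "ridge": []}
        spec = ss.BlockSpec(block_sizes=(4, 4), within_r=0.5, between_r=0.1)
        for seed in range(20):
            r = ss.generate_block_responses(spec, 5000, seed=seed)
            train, test = ss.split_train_test(r, 0.2, seed=seed)
            rng = np.random.default_rng(seed)
            beta = rng.normal(size=8)
            y_train = train.values @ beta + rng.normal(scale=1.0, size=train.n)
            y_test = test.values @ beta + rng.normal(scale=1.0, size=test.n)
            for method in rmse:
                model = ss.fit_gsi_regressor(train, train.item_ids, y_train, method)
                m = ss.evaluate_prediction(model, test, train.item_ids, y_test)
                rmse[method].append(m.rmse)
        mean = {k: np.mean(v) for k, v in rmse.items()}
        # ridge with a CV-chosen penalty tends to OLS as the penalty -> 0, so
        # allow ties up to a 0.1% relative band; OLS must never lose by more
        assert mean["ols"] <= mean["robust"] * 1.001
        assert mean["ols"] <= mean["ridge"] * 1.001


class TestPredictSubscales:
    def test_superset_of_subscale_items_is_exact(self, bank, bifactor_1200):
        train, test = ss.split_train_test(bifactor_1200, 0.2, seed=1)
        hos_items = bank.items_in("HOS")
        table = ss.predict_subscales(train, test, hos_items, bank)
        row = table[table["subscale"] == "HOS"].iloc[0]
        assert row["rmse"] == pytest.approx(0.0, abs=1e-10)
        assert row["pearson_r"] == pytest.approx(1.0, abs=1e-10)

    def test_ten_rows_match_direct_oracle(self, bank, bifactor_1200):
        train, test = ss.split_train_test(bifactor_1200, 0.2, seed=1)
        items = [8, 9, 16, 30, 33, 45, 52, 63, 66, 70, 85]
        table = ss.predict_subscales(train, test, items, bank)
        assert len(table) == 10
        # oracle: refit one subscale by explicit normal equations
        target_train = ss.compute_scores(train, bank).subscale_scores["DEP"].to_numpy()
        target_test = ss.compute_scores(test, bank).subscale_scores["DEP"].to_numpy()
        X = np.column_stack([np.ones(train.n),
                             train.values[:, train.column_index(items)]])
        beta = np.linalg.lstsq(X, target_train, rcond=None)[0]
        Xt = np.column_stack([np.ones(test.n),
                              test.values[:, test.column_index(items)]])
        pred = Xt @ beta
        expected_rmse = np.sqrt(np.mean((target_test - pred) ** 2))
        row = table[table["subscale"] == "DEP"].iloc[0]
        assert row["rmse"] == pytest.approx(expected_rmse, abs=1e-8)

    def test_uncorrelated_items_have_no_signal(self, bank):
        rng = np.random.default_rng(0)
        vals = rng.integers(1, 6, size=(3000, 90))
        r = ss.ResponseMatrix(vals, list(range(1, 91)))
        train, test = ss.split_train_test(r, 0.3, seed=0)
        som = bank.items_in("SOM")
        other = [i for i in range(1, 91) if i not in som][:10]
        table = ss.predict_subscales(train, test, other, bank)
        row = table[table["subscale"] == "SOM"].iloc[0]
        assert abs(row["r2"]) < 0.05


class TestScaleAbbreviatorEstimator:
    def test_fit_transform_predict(self, bifactor_1200):
        est = ss.ScaleAbbreviator(stop_r=0.9, k_max=15, random_state=3)
        assert clone(est).get_params()["stop_r"] == 0.9
        est.fit(bifactor_1200)
        assert est.k_ == len(est.item_ids_)
        Xt = est.transform(bifactor_1200)
        assert Xt.shape == (1200, est.k_)
        pred = est.predict(bifactor_1200)
        assert pred.shape == (1200,)
        assert est.met_threshold_

    def test_explicit_test_split(self, bifactor_1200):
        train, test = ss.split_train_test(bifactor_1200, 0.2, seed=0)
        est = ss.ScaleAbbreviator(stop_r=0.9, k_max=15).fit(train, X_test=test)
        assert est.metrics_.pearson_r >= 0.9
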