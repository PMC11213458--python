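"""Correlation, stepwise regression and prediction-error statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hamqc.errors import DegenerateDataError, InputError
from hamqc.stats import (
    RegressionModel,
    Term,
    build_terms,
    correlation_matrix,
    evaluate_model,
    fit_ols_model,
    loo_rmse,
    pearson_with_p,
    prediction_error,
    printed_model,
    stepwise_regression,
)


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        res = pearson_with_p(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(0.0, abs=1e-12)

    def test_null_pair_is_uncorrelated(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(10_000), rng.standard_normal(10_000)
        res = pearson_with_p(x, y)
        assert abs(res.r) < 0.03
        assert res.p_value > 0.001  # not spuriously significant

    def test_p_value_matches_t_transform_by_hand(self):
        # r = 0.5, n = 6 -> t = 0.5*sqrt(4/0.75) = 1.1547, two-sided vs t_4
        t = 0.5 * np.sqrt(4 / 0.75)
        expected_p = 2 * sps.t.sf(t, df=4)
        # construct a 6-point sample with r very close to 0.5 via scipy oracle
        rng = np.random.default_rng(3)
        for _ in range(200):
            x, y = rng.standard_normal(6), rng.standard_normal(6)
            r_sp, p_sp = sps.pearsonr(x, y)
            res = pearson_with_p(x, y)
            assert res.r == pytest.approx(r_sp, abs=1e-12)
            assert res.p_value == pytest.approx(p_sp, rel=1e-9)
        assert expected_p == pytest.approx(0.3125, abs=5e-4)  # t-table anchor

    def test_r_squared_pct_consistency(self):
        # a correlation of -0.461 explains 21.25% of variance (~the 21% headline)
        res = pearson_with_p([0, 1, 2, 3.0], [0, 1, 2, 3.0])
        assert res.r_squared_pct == pytest.approx(100.0)
        assert (-0.461) ** 2 * 100 == pytest.approx(21.25, abs=0.01)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(InputError):
            pearson_with_p([1, 2, 3], [1, 2, 3])
        with pytest.raises(DegenerateDataError):
            pearson_with_p([1, 1, 1, 1], [1, 2, 3, 4])


class TestCorrelationMatrix:
    def test_pair_count(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.standard_normal((20, 5)), columns=list("abcde"))
        assert len(correlation_matrix(df, list("abcde"))) == 10

    def test_missing_variable_named(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4.0], "b": [2, 1, 4, 3.0]})
        with pytest.raises(InputError, match="ph_u"):
            correlation_matrix(df, ["a", "ph_u"])


class TestBuildTerms:
    def test_full_expansion_count(self):
        terms = build_terms(list("abcde"), True, True)
        assert len(terms) == 5 + 5 + 10

    def test_single_variable_squares(self):
        terms = build_terms(["x"], include_squares=True)
        assert [t.name for t in terms] == ["x", "x^2"]

    def test_two_variables_interactions(self):
        terms = build_terms(["x", "y"], include_interactions=True)
        assert [t.name for t in terms] == ["x", "y", "x*y"]


def _ols_pvalues_numpy(y, X):
    """Independent OLS inference: raw linear algebra, no statsmodels."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n, p = X.shape
    sigma2 = float(resid @ resid) / (n - p)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    return beta, 2 * sps.t.sf(np.abs(t), df=n - p)


def brute_force_stepwise(df, response, candidates, alpha_enter, alpha_remove):
    """Greedy forward-backward stepwise, refitting every candidate model
    from scratch with raw numpy OLS. Mirrors the documented enter/remove
    rules; serves as the independent oracle."""
    y = df[response].to_numpy(dtype=float)
    n = len(y)
    cols = {t: np.asarray(t.value(df), dtype=float) for t in candidates}

    def X_for(terms):
        return np.column_stack([np.ones(n)] + [cols[t] for t in terms])

    included = []
    seen = set()
    while True:
        state = tuple(t.name for t in included)
        if state in seen:
            break
        seen.add(state)
        changed = False
        best_p, best_t = None, None
        for t in candidates:
            if t in included:
                continue
            X = X_for(included + [t])
            if np.linalg.matrix_rank(X) < X.shape[1]:
                continue
            _, pv = _ols_pvalues_numpy(y, X)
            if best_p is None or pv[-1] < best_p:
                best_p, best_t = pv[-1], t
        if best_t is not None and best_p < alpha_enter:
            included.append(best_t)
            changed = True
        while included:
            _, pv = _ols_pvalues_numpy(y, X_for(included))
            worst = int(np.argmax(pv[1:]))
            if pv[1:][worst] > alpha_remove:
                included.pop(worst)
                changed = True
            else:
                break
        if not changed:
            break
    return included


class TestStepwise:
    def test_recovers_exact_single_predictor(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x1": rng.standard_normal(100), "x2": rng.standard_normal(100)})
        df["y"] = 2.0 * df["x1"] + rng.standard_normal(100) * 1e-8
        cands = build_terms(["x1", "x2"], include_squares=True)
        model = stepwise_regression(df, "y", cands)
        assert [t.name for t in model.terms] == ["x1"]
        assert model.coefficients[1] == pytest.approx(2.0, abs=1e-6)

    def test_pure_noise_rarely_admits_terms(self):
        # under the global null, entries are chance admissions at alpha=0.15
        n_terms = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(
                rng.standard_normal((200, 5)), columns=["a", "b", "c", "d", "e"]
            )
            df["y"] = rng.standard_normal(200)
            cands = build_terms(["a", "b", "c", "d", "e"], True, True)
            model = stepwise_regression(df, "y", cands)
            n_terms.append(len(model.terms))
        assert np.mean(n_terms) < 4.0  # near-empty on average
        assert min(n_terms) == 0  # intercept-only happens

    def test_intercept_only_model_flagged(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"x": rng.standard_normal(50)})
        df["y"] = np.ones(50) + rng.standard_normal(50) * 1e-3
        model = stepwise_regression(df, "y", build_terms(["x"]), alpha_enter=1e-9)
        assert model.intercept_only
        assert len(model.coefficients) == 1

    def test_selected_model_beats_best_single_predictor(self, cohort_5000):
        df = cohort_5000.to_frame().head(400)
        cands = build_terms(
            ["py_ad", "ph_u", "l_star", "a_star", "b_star"], True, True
        )
        model = stepwise_regression(df, "des_avg", cands)
        best_single = min(
            fit_ols_model(df, "des_avg", [t]).prediction_error
            for t in build_terms(["py_ad", "ph_u", "l_star", "a_star", "b_star"])
        )
        assert model.prediction_error <= best_single + 1e-12

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 51))
        df = pd.DataFrame(rng.standard_normal((n, 3)), columns=["u", "v", "w"])
        beta = rng.normal(0, 1, 3)
        df["y"] = df[["u", "v", "w"]].to_numpy() @ beta + rng.standard_normal(n)
        cands = build_terms(["u", "v", "w"], True, True)[:8]
        mine = stepwise_regression(df, "y", cands)
        oracle = brute_force_stepwise(df, "y", cands, 0.15, 0.15)
        assert [t.name for t in mine.terms] == [t.name for t in oracle]

    def test_n_too_small_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2, 3], "y": [1.0, 2, 3]})
        with pytest.raises(InputError):
            stepwise_regression(df, "y", build_terms(["x"], True, True))


class TestPrintedModel:
    def test_structure(self):
        m = printed_model()
        assert len(m.terms) == 10
        assert len(m.coefficients) == 11
        assert m.intercept == -82.0
        assert m.n == 136

    def test_lstar_py_interaction_coefficient(self):
        m = printed_model()
        idx = [t.name for t in m.terms].index("l_star*py_ad")
        assert m.coefficients[idx + 1] == 0.0034

    def test_origin_returns_intercept(self):
        vals = {v: 0.0 for v in ("ph_u", "l_star", "a_star", "b_star", "py_ad")}
        assert evaluate_model(printed_model(), vals) == pytest.approx(-82.0)

    def test_probe_point_hand_arithmetic(self):
        vals = dict(ph_u=5.5, l_star=50.0, a_star=8.0, b_star=5.0, py_ad=40.0)
        # off-scale outside the fitted manifold: documented behavior of the raw equation
        assert evaluate_model(printed_model(), vals) == pytest.approx(66.087, abs=1e-9)

    def test_clamping_flag(self):
        vals = dict(ph_u=5.5, l_star=50.0, a_star=8.0, b_star=5.0, py_ad=40.0)
        assert evaluate_model(printed_model(), vals, clamp=True) == 3.0


class TestEvaluateModel:
    def test_identity_single_term(self):
        m = RegressionModel("y", [Term("linear", ("x",))], [0.0, 1.0], n=5)
        assert evaluate_model(m, {"x": 3.0}) == pytest.approx(3.0)

    def test_missing_variable_named(self):
        with pytest.raises(InputError, match="py_ad"):
            evaluate_model(printed_model(), dict(ph_u=5.5, l_star=50, a_star=8, b_star=5))

    def test_linear_in_each_variable_per_term_structure(self):
        m = printed_model()
        base = dict(ph_u=5.6, l_star=50.0, a_star=8.0, b_star=4.0, py_ad=45.0)
        # b* appears only linearly: second difference must vanish
        def at(b):
            return evaluate_model(m, dict(base, b_star=b))
        second_diff = at(6.0) - 2 * at(5.0) + at(4.0)
        assert second_diff == pytest.approx(0.0, abs=1e-9)
        # L* has square and interaction terms: second difference is 2*c(L*^2)
        def at_l(l):
            return evaluate_model(m, dict(base, l_star=l))
        second_l = at_l(52.0) - 2 * at_l(51.0) + at_l(50.0)
        assert second_l == pytest.approx(2 * 0.0054, abs=1e-9)


class TestPredictionError:
    def test_perfect_predictions(self):
        m = RegressionModel("y", [Term("linear", ("x",))], [0.0, 1.0], n=4)
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [1.0, 2, 3, 4]})
        errs = prediction_error(m, df)
        assert errs.rmse == pytest.approx(0.0, abs=1e-12)

    def test_constant_prediction_hand_arithmetic(self):
        m = RegressionModel("y", [], [5.0], n=2)  # predicts 5 always
        df = pd.DataFrame({"y": [4.0, 6.0]})
        assert prediction_error(m, df).rmse == pytest.approx(1.0)

    def test_known_residuals(self):
        m = RegressionModel("y", [Term("linear", ("x",))], [0.0, 1.0], n=4)
        df = pd.DataFrame({"x": [1.0, 2, 3, 4]})
        df["y"] = df["x"] - np.array([0.5, -0.5, 1.0, -1.0])
        assert prediction_error(m, df).rmse == pytest.approx(np.sqrt(2.5 / 4))
        assert prediction_error(m, df).mae == pytest.approx(0.75)

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            prediction_error(printed_model(), pd.DataFrame())

    def test_in_sample_rmse_bounded_by_response_sd(self, cohort_5000):
        df = cohort_5000.to_frame().head(300)
        cands = build_terms(["py_ad", "ph_u"], True, True)
        model = stepwise_regression(df, "des_avg", cands)
        errs = prediction_error(model, df)
        assert errs.rmse <= np.std(df["des_avg"].to_numpy()) + 1e-12


class TestOlsSanity:
    def test_noiseless_coefficients_recovered(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.standard_normal((50, 2)), columns=["x1", "x2"])
        df["y"] = 1.5 + 2.0 * df["x1"] - 3.0 * df["x2"]
        terms = build_terms(["x1", "x2"])
        model = fit_ols_model(df, "y", terms)
        assert model.coefficients == pytest.approx([1.5, 2.0, -3.0], abs=1e-8)

    def test_loo_rmse_matches_explicit_refits(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"x": rng.standard_normal(15)})
        df["y"] = 2 * df["x"] + rng.standard_normal(15)
        terms = build_terms(["x"])
        fast = loo_rmse(df, "y", terms)
        errs = []
        for i in range(len(df)):
            train = df.drop(index=i)
            m = fit_ols_model(train, "y", terms)
            pred = evaluate_model(m, df.iloc[[i]])
            errs.append(float(np.asarray(pred)[0]) - df["y"].iloc[i])
        assert fast == pytest.approx(float(np.sqrt(np.mean(np.square(errs)))), rel=1e-9)
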