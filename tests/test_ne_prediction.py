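"""Correlation, OLS metrics, stepwise/best-subset selection, equation application."""

import math

import numpy as np
import pandas as pd
import pytest

from swinecal.ne_prediction import (
    RSM_NE_EQUATIONS,
    SamplePanelRow,
    apply_equation,
    best_subset,
    fit_ols,
    pearson_matrix,
    stepwise_select,
)


def _normal_equations(y, X):
    # independent oracle: solve (A'A) b = A'y directly
    A = np.column_stack([np.ones(len(y)), np.asarray(X, dtype=float)])
    return np.linalg.solve(A.T @ A, A.T @ np.asarray(y, dtype=float))


class TestPearson:
    def test_exact_linear_relations(self):
        x = np.arange(10, dtype=float)
        df = pd.DataFrame({"x": x, "up": 2 * x + 1, "down": -x})
        r, p = pearson_matrix(df)
        assert r.loc["x", "up"] == pytest.approx(1.0)
        assert r.loc["x", "down"] == pytest.approx(-1.0)
        assert p.loc["x", "up"] < 1e-10

    def test_hand_computed_half(self):
        df = pd.DataFrame({"x": [1, 2, 3], "y": [1, 3, 2]})
        r, _ = pearson_matrix(df)
        assert r.loc["x", "y"] == pytest.approx(0.5)

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"x": [1, 2, 3], "c": [4, 4, 4]})
        with pytest.raises(ValueError, match="constant"):
            pearson_matrix(df)


class TestFitOls:
    def test_exact_line(self):
        m = fit_ols([0, 2, 4, 6], pd.DataFrame({"x": [0, 1, 2, 3]}))
        assert m.coefficients["x"] == pytest.approx(2.0)
        assert m.intercept == pytest.approx(0.0, abs=1e-10)
        assert m.r2 == pytest.approx(1.0)
        assert m.rmse == pytest.approx(0.0, abs=1e-7)
        assert m.aic < -100  # -inf up to float round-off in the residual

    def test_three_point_closed_form(self):
        # (1,1),(2,2),(3,2): slope 1/2, intercept 2/3, R^2 = 3/4, SSE = 1/6
        m = fit_ols([1, 2, 2], pd.DataFrame({"x": [1, 2, 3]}))
        assert m.coefficients["x"] == pytest.approx(0.5)
        assert m.intercept == pytest.approx(2 / 3)
        assert m.r2 == pytest.approx(0.75)
        assert m.rmse == pytest.approx(math.sqrt((1 / 6) / 1))
        assert m.aic == pytest.approx(3 * math.log(1 / 18) + 4, abs=1e-6)  # ~ -4.671

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n, p = 12, 3
            X = pd.DataFrame(rng.normal(size=(n, p)), columns=list("abc"))
            y = rng.normal(size=n)
            m = fit_ols(y, X)
            beta = _normal_equations(y, X)
            assert m.intercept == pytest.approx(beta[0], abs=1e-8)
            for j, c in enumerate("abc"):
                assert m.coefficients[c] == pytest.approx(beta[j + 1], abs=1e-8)

    def test_r2_never_decreases_with_added_predictor(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        y = X["a"] * 2 + rng.normal(size=30)
        r2 = [fit_ols(y, X[list("abcd")[: k + 1]]).r2 for k in range(4)]
        assert all(r2[k + 1] >= r2[k] - 1e-12 for k in range(3))

    def test_rank_deficiency_reported(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        with pytest.raises(ValueError, match="rank deficient"):
            fit_ols([1, 2, 3, 4], X)


class TestStepwise:
    def test_planted_single_predictor_found(self):
        rng = np.random.default_rng(3)
        n = 50
        X = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"))
        y = 5.0 * X["c"] + rng.normal(scale=0.5, size=n)
        m = stepwise_select(y, X, alpha_enter=0.05, alpha_stay=0.05)
        assert m.predictors == ("c",)

    def test_metrics_consistent_with_fit_ols(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        y = X["a"] - 2 * X["b"] + rng.normal(scale=0.3, size=40)
        m = stepwise_select(y, X)
        refit = fit_ols(y, X[list(m.predictors)])
        assert m.r2 == pytest.approx(refit.r2)
        assert m.aic == pytest.approx(refit.aic)

    def test_no_qualifying_predictor_gives_intercept_only(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        y = np.ones(30) + rng.normal(scale=1e-3, size=30)
        with pytest.warns(UserWarning, match="intercept-only"):
            m = stepwise_select(y, X, alpha_enter=1e-6, alpha_stay=1e-6)
        assert m.predictors == ()
        assert m.intercept == pytest.approx(float(np.mean(y)))

    def test_never_beats_best_subset_and_matches_with_strong_signals(self):
        rng = np.random.default_rng(13)
        n = 60
        X = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        # every predictor carries real signal: the full model is AIC-optimal
        y = 3 * X["a"] - 2 * X["b"] + 1.5 * X["c"] + 1.2 * X["d"] + rng.normal(scale=0.4, size=n)
        exhaustive = best_subset(y, X)
        loose = stepwise_select(y, X, alpha_enter=0.9, alpha_stay=0.95)
        assert loose.aic >= exhaustive.aic - 1e-9
        assert loose.aic == pytest.approx(exhaustive.aic)
        assert set(loose.predictors) == set(exhaustive.predictors)

    def test_stepwise_aic_bounded_below_by_exhaustive_on_noise(self):
        rng = np.random.default_rng(17)
        X = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("abcd"))
        y = X["a"] + rng.normal(scale=0.8, size=25)
        assert stepwise_select(y, X).aic >= best_subset(y, X).aic - 1e-9


class TestBestSubset:
    def test_single_predictor_equals_fit_ols(self):
        rng = np.random.default_rng(19)
        X = pd.DataFrame({"x": rng.normal(size=20)})
        y = 2 * X["x"] + rng.normal(scale=0.2, size=20)
        assert best_subset(y, X).aic == pytest.approx(fit_ols(y, X).aic)

    def test_planted_pair_recovered(self):
        rng = np.random.default_rng(23)
        X = pd.DataFrame(rng.normal(size=(60, 5)), columns=list("abcde"))
        y = 4 * X["b"] - 3 * X["e"] + rng.normal(scale=0.3, size=60)
        m = best_subset(y, X, max_terms=3)
        assert set(m.predictors) == {"b", "e"}

    def test_enumeration_limit(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 40)))
        X.columns = [f"x{i}" for i in range(40)]
        with pytest.raises(ValueError, match="enumeration limit"):
            best_subset(np.zeros(5), X)


SAMPLE = dict(de=15.78, me=14.04, ge=21.35, cp=37.70, ee=11.27, ash=7.49)


class TestApplyEquation:
    def test_all_zero_inputs_return_intercept(self):
        m = RSM_NE_EQUATIONS[0]
        zeros = {k: 0.0 for k in SAMPLE}
        assert apply_equation(m, zeros) == pytest.approx(m.intercept)

    def test_published_de_cp_equation(self):
        # 1.14*15.78 + 0.46*37.70 - 25.24 = 10.09 MJ/kg DM
        assert apply_equation(RSM_NE_EQUATIONS[0], SAMPLE) == pytest.approx(10.09, abs=0.005)

    def test_published_me_equation(self):
        # 0.85*14.04 - 1.48 = 10.45 MJ/kg DM
        assert apply_equation(RSM_NE_EQUATIONS[1], SAMPLE) == pytest.approx(10.45, abs=0.005)

    def test_missing_field_named(self):
        with pytest.raises(KeyError, match="de"):
            apply_equation(RSM_NE_EQUATIONS[0], {"cp": 37.7})

    def test_mapping_form(self):
        assert apply_equation({"me": 0.85, "intercept": -1.48}, {"me": 14.04}) == pytest.approx(
            10.454
        )


def test_coefficient_recovery_coverage():
    """95% CIs on a DE+CP model cover the truth at roughly nominal rate.

    Panels of n = 8 with residual sd 0.36 (matching the best published
    equation's RMSE) are simulated from a known linear truth; the fraction
    of replicates whose t-based intervals cover the true DE slope should be
    near 0.95.
    """
    rng = np.random.default_rng(29)
    true = {"de": 1.14, "cp": 0.46, "intercept": -25.24}
    covered = 0
    reps = 400
    tcrit = 2.5706  # t(0.975, df=5)
    for _ in range(reps):
        de = rng.uniform(11.5, 16.0, size=8)
        cp = rng.uniform(36.0, 43.0, size=8)
        y = true["intercept"] + true["de"] * de + true["cp"] * cp + rng.normal(0, 0.36, size=8)
        X = np.column_stack([np.ones(8), de, cp])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s2 = resid @ resid / 5
        se = math.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        if abs(beta[1] - true["de"]) <= tcrit * se:
            covered += 1
    assert 0.91 <= covered / reps <= 0.985
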