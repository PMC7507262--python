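"""Lasso refinement, the iterative selection loop, baselines, OLS inference."""

import numpy as np
import pytest
from scipy import stats

from isirs import (
    NumericalError,
    SelectionConfig,
    ValidationError,
    fit_ols,
    generate_hidden_predictor,
    generate_linear,
    isirs_select,
    predict,
    run_lasso,
    sirs_select,
    stf_select,
    SimulationScenario,
    compute_omega,
    rank_features,
)
from conftest import make_xy, ols_oracle, soft_threshold, standardize_cols


def _orthonormal_design(rng, n, p):
    """Columns orthogonal with sum x^2 = n, mean 0 (1/n-standardized)."""
    q, _ = np.linalg.qr(rng.normal(size=(n, p + 1)))
    q = q - q.mean(axis=0)
    q, _ = np.linalg.qr(q)
    cols = q[:, :p] * np.sqrt(n)
    return cols


class TestRunLasso:
    def test_huge_penalty_gives_null_model(self, rng):
        Xv = standardize_cols(rng.normal(size=(40, 6)))
        y = rng.normal(size=40) + 5.0
        X, Y = make_xy(Xv, y)
        lam = 2.0 * np.abs(Xv.T @ y).max() + 10.0
        fit = run_lasso(X, Y, {"fixed": lam})
        assert fit.coefficients == {}
        assert fit.intercept == pytest.approx(y.mean(), abs=1e-10)

    def test_zero_penalty_matches_ols(self, rng):
        Xv = standardize_cols(rng.normal(size=(50, 4)))
        y = rng.normal(size=50)
        X, Y = make_xy(Xv, y)
        fit = run_lasso(X, Y, {"fixed": 0.0})
        oracle = ols_oracle(Xv, y)
        beta = np.array([fit.coefficients.get(k, 0.0) for k in range(4)])
        np.testing.assert_allclose(beta, oracle["beta"][1:], atol=1e-6)

    def test_orthogonal_design_soft_threshold_closed_form(self, rng):
        n, p = 60, 5
        Xv = _orthonormal_design(rng, n, p)
        y = rng.normal(size=n) + Xv[:, 0] * 2.0
        X, Y = make_xy(Xv, y)
        lam = 20.0
        fit = run_lasso(X, Y, {"fixed": lam})
        yc = y - y.mean()
        for k in range(p):
            expected = soft_threshold(float(Xv[:, k] @ yc), lam / 2.0) / n
            assert fit.coefficients.get(k, 0.0) == pytest.approx(expected, abs=1e-6)

    def test_objective_not_worse_than_null_or_ols(self, rng):
        Xv = standardize_cols(rng.normal(size=(30, 5)))
        y = rng.normal(size=30)
        X, Y = make_xy(Xv, y)
        lam = 8.0
        fit = run_lasso(X, Y, {"fixed": lam})
        yc = y - y.mean()
        null_obj = float(yc @ yc)  # all-zero slopes, intercept = mean
        ols = ols_oracle(Xv, y)
        ols_obj = float(ols["resid"] @ ols["resid"]) + lam * np.abs(ols["beta"][1:]).sum()
        assert fit.objective <= null_obj + 1e-8
        assert fit.objective <= ols_obj + 1e-8

    def test_objective_consistent_with_solution(self, rng):
        Xv = standardize_cols(rng.normal(size=(40, 3)))
        y = rng.normal(size=40)
        X, Y = make_xy(Xv, y)
        fit = run_lasso(X, Y, {"fixed": 5.0})
        beta = np.array([fit.coefficients.get(k, 0.0) for k in range(3)])
        resid = y - fit.intercept - Xv @ beta
        expected = float(resid @ resid) + 5.0 * np.abs(beta).sum()
        assert fit.objective == pytest.approx(expected, abs=1e-8)

    def test_bad_inputs_rejected(self, rng):
        X, Y = make_xy(standardize_cols(rng.normal(size=(10, 3))), rng.normal(size=10))
        with pytest.raises(ValidationError):
            run_lasso(X, Y, {"fixed": -1.0})
        with pytest.raises(ValidationError):
            run_lasso(X, Y, candidates=[])


class TestIsirsSelect:
    def test_terminates_on_pure_noise(self, rng):
        Xv = rng.normal(size=(100, 200))
        y = rng.normal(size=100)
        X, Y = make_xy(Xv, y, standardized=False)
        trace = isirs_select(X, Y, 10, SelectionConfig(seed=0))
        assert trace.stop_reason in {"size_unchanged", "reached_d"}
        assert len(trace.iterations) <= 50

    def test_final_set_bounded_by_d_and_screened(self, rng):
        sc = SimulationScenario(n=120, p=150, seed=7)
        X, Y, _ = generate_linear(sc)
        trace = isirs_select(X, Y, 8, SelectionConfig(seed=7))
        assert len(trace.final_set) <= 8
        seen = set()
        for rec in trace.iterations:
            seen.update(rec.screened)
        assert set(trace.final_set) <= seen

    def test_fresh_screens_exclude_working_set(self, rng):
        X, Y, _ = generate_linear(SimulationScenario(n=100, p=120, seed=3))
        trace = isirs_select(X, Y, 10, SelectionConfig(seed=3))
        for prev, cur in zip(trace.iterations, trace.iterations[1:]):
            assert not (set(cur.screened) & set(prev.retained))

    def test_initial_screen_size_is_two_thirds_d(self, rng):
        X, Y, _ = generate_linear(SimulationScenario(n=80, p=100, seed=1))
        for d, k1 in [(10, 6), (9, 6), (50, 33)]:
            trace = isirs_select(X, Y, d, SelectionConfig(seed=1))
            assert trace.k1 == k1 == (2 * d) // 3
            assert len(trace.iterations[0].screened) == k1

    def test_reached_d_in_one_pass_when_first_lasso_keeps_d(self):
        # strong orthogonal signals with the screen widened to d: the first
        # lasso retains all d, so the stop triggers immediately
        rng = np.random.default_rng(5)
        n, d = 80, 4
        Xv = _orthonormal_design(rng, n, 6)
        y = Xv[:, :d] @ np.array([3.0, -3.0, 2.5, 2.0]) + 0.1 * rng.normal(size=n)
        X, Y = make_xy(Xv, y)
        trace = isirs_select(X, Y, d, SelectionConfig(seed=5, k1=d))
        assert trace.stop_reason == "reached_d"
        assert len(trace.iterations) == 1
        assert set(trace.final_set) == {0, 1, 2, 3}

    def test_d_larger_than_p_rejected(self, rng):
        X, Y = make_xy(standardize_cols(rng.normal(size=(30, 5))), rng.normal(size=30))
        with pytest.raises(ValidationError):
            isirs_select(X, Y, 6)

    def test_recovers_active_features_in_sparse_linear_model(self):
        hits = 0
        for seed in range(20):
            X, Y, truth = generate_linear(
                SimulationScenario(n=200, p=1000, seed=seed))
            trace = isirs_select(X, Y, 10, SelectionConfig(seed=seed))
            hits += set(truth.active_set) <= set(trace.final_set)
        assert hits >= 18  # >= 90%

    def test_recruits_hidden_predictor_where_stf_cannot(self):
        isirs_hits = stf_hits = 0
        for seed in range(10):
            X, Y, truth = generate_hidden_predictor(200, 500, beta=2.0, rho=0.5,
                                                    sigma=1.0, seed=seed)
            hidden = truth.hidden[0]
            isirs_hits += hidden in isirs_select(X, Y, 10, SelectionConfig(seed=seed)).final_set
            stf_hits += hidden in stf_select(X, Y, 10)
        assert isirs_hits >= 8
        assert stf_hits <= 2


class TestBaselines:
    def test_stf_is_top_d_by_omega(self, rng):
        X, Y, _ = generate_linear(SimulationScenario(n=80, p=60, seed=2))
        from isirs import standardize_features
        Xs = standardize_features(X)
        expected = tuple(int(i) for i in rank_features(compute_omega(Xs, Y), 7))
        assert stf_select(X, Y, 7) == expected

    def test_stf_d_larger_than_p_rejected(self, rng):
        X, Y = make_xy(standardize_cols(rng.normal(size=(20, 4))), rng.normal(size=20))
        with pytest.raises(ValidationError):
            stf_select(X, Y, 5)

    def test_sirs_returns_strong_orthogonal_signals_exactly(self):
        rng = np.random.default_rng(11)
        n, d = 100, 5
        Xv = np.column_stack([_orthonormal_design(rng, n, d),
                              standardize_cols(rng.normal(size=(n, 40)))])
        y = Xv[:, :d].sum(axis=1) * 3.0 + 0.2 * rng.normal(size=n)
        X, Y = make_xy(Xv, y)
        assert sirs_select(X, Y, d, SelectionConfig(seed=0)) == tuple(range(d))

    def test_sirs_subset_of_screened_set_and_deterministic(self, rng):
        X, Y, _ = generate_linear(SimulationScenario(n=90, p=80, seed=4))
        from isirs import standardize_features
        Xs = standardize_features(X)
        screened = set(int(i) for i in rank_features(compute_omega(Xs, Y), 8))
        got = sirs_select(X, Y, 8, SelectionConfig(seed=4))
        assert set(got) <= screened
        assert got == sirs_select(X, Y, 8, SelectionConfig(seed=4))


class TestFitOls:
    def test_exact_interpolation_flags_tests_undefined(self):
        X, Y = make_xy(np.array([[-1.0], [0.0], [1.0]]), [0.0, 1.0, 2.0])
        model = fit_ols(X, Y)
        assert model.intercept == pytest.approx(1.0, abs=1e-10)
        assert model.coefficients[0] == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(model.residuals, 0.0, atol=1e-10)
        assert model.r_squared == pytest.approx(1.0)
        assert not model.tests_defined
        assert np.isnan(model.t_stats[0])
        assert model.significant_at_001 == frozenset()

    def test_matches_normal_equations_oracle(self, rng):
        Xv = rng.normal(size=(50, 3))
        y = Xv @ np.array([1.0, -2.0, 0.5]) + rng.normal(size=50)
        X, Y = make_xy(Xv, y)
        model = fit_ols(X, Y)
        oracle = ols_oracle(Xv, y)
        assert model.intercept == pytest.approx(oracle["beta"][0], abs=1e-8)
        for k in range(3):
            assert model.coefficients[k] == pytest.approx(oracle["beta"][k + 1], abs=1e-8)
            assert model.std_errors[k] == pytest.approx(oracle["se"][k + 1], abs=1e-8)
            assert model.t_stats[k] == pytest.approx(oracle["t"][k + 1], abs=1e-8)
            assert model.p_values[k] == pytest.approx(oracle["p"][k + 1], abs=1e-8)
        assert np.abs(model.residuals.sum()) < 1e-8

    def test_t_stat_is_coefficient_over_se_and_significance_set(self, rng):
        Xv = rng.normal(size=(60, 4))
        y = 3.0 * Xv[:, 0] + rng.normal(size=60)
        X, Y = make_xy(Xv, y)
        model = fit_ols(X, Y)
        for k in model.features:
            assert model.t_stats[k] == pytest.approx(
                model.coefficients[k] / model.std_errors[k], rel=1e-12)
        assert model.significant_at_001 == frozenset(
            k for k in model.features if model.p_values[k] < 0.01)
        assert 0 in model.significant_at_001

    def test_collinear_design_rejected_with_culprits(self, rng):
        a = rng.normal(size=30)
        Xv = np.column_stack([a, rng.normal(size=30), 2.0 * a])
        X, Y = make_xy(Xv, rng.normal(size=30))
        with pytest.raises(NumericalError, match="collinear"):
            fit_ols(X, Y)

    def test_too_many_features_rejected(self, rng):
        X, Y = make_xy(rng.normal(size=(5, 4)), rng.normal(size=5))
        with pytest.raises(ValidationError):
            fit_ols(X, Y)

    def test_noise_coefficient_type_one_error_near_nominal(self):
        # appended pure-noise feature should be declared significant at the
        # 0.01 level in about 1% of replicates
        reps = 400
        false_pos = 0
        for seed in range(reps):
            g = np.random.default_rng(seed)
            Xv = g.normal(size=(40, 3))
            y = Xv[:, 0] - Xv[:, 1] + g.normal(size=40)  # feature 2 is noise
            X, Y = make_xy(Xv, y)
            false_pos += 2 in fit_ols(X, Y).significant_at_001
        lo, hi = stats.binom.ppf([0.005, 0.995], reps, 0.01)
        assert lo <= false_pos <= hi


class TestPredict:
    def _model(self, rng):
        Xv = rng.normal(size=(40, 3))
        y = Xv @ np.array([1.0, 2.0, -1.0]) + rng.normal(size=40)
        X, Y = make_xy(Xv, y)
        return fit_ols(X, Y), X, Y

    def test_training_rows_give_fitted_values(self, rng):
        model, X, Y = self._model(rng)
        fitted = Y.values - model.residuals
        np.testing.assert_allclose(predict(model, X).values, fitted, atol=1e-10)

    def test_zero_row_predicts_intercept(self, rng):
        model, X, _ = self._model(rng)
        X0, _ = make_xy(np.zeros((1, 3)), [0.0])
        assert predict(model, X0).values[0] == pytest.approx(model.intercept)

    def test_affine_in_the_features(self, rng):
        model, X, _ = self._model(rng)
        x1, x2 = X.values[0], X.values[1]
        a, b = 0.7, -1.3
        combo, _ = make_xy((a * x1 + b * x2)[None, :], [0.0])
        X1, _ = make_xy(x1[None, :], [0.0])
        X2, _ = make_xy(x2[None, :], [0.0])
        lhs = predict(model, combo).values[0]
        rhs = (a * predict(model, X1).values[0] + b * predict(model, X2).values[0]
               - (a + b - 1) * model.intercept)
        assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_missing_feature_column_rejected(self, rng):
        model, _, _ = self._model(rng)
        Xsmall, _ = make_xy(np.zeros((2, 2)), [0.0, 0.0])
        with pytest.raises(ValidationError):
            predict(model, Xsmall)
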