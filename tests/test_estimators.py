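"""Estimator contracts: OLS, quantile regression, boosted trees, predict."""

import itertools

import numpy as np
import pytest

from ipboot.errors import SchemaError, SingularFitError
from ipboot.estimators import (
    EstimatorSpec,
    check_loss,
    fit_brt,
    fit_ols,
    fit_quantile,
    predict,
)

from conftest import make_sample


class TestOLS:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        s = make_sample(2 * x + 1, x)
        c = fit_ols(s).coefficients
        assert c["intercept"] == pytest.approx(1.0, abs=1e-10)
        assert c["x1"] == pytest.approx(2.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        s = make_sample(y, X)
        beta = fit_ols(s).coef_vector()
        A = np.column_stack([np.ones(30), X])
        oracle = np.linalg.solve(A.T @ A, A.T @ y)
        assert np.allclose(beta, oracle, atol=1e-8, rtol=1e-8)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 2))
        y = 0.5 + X @ [1.0, -2.0] + rng.normal(size=40)
        ours = fit_ols(make_sample(y, X)).coef_vector()
        theirs = sm.OLS(y, sm.add_constant(X)).fit().params
        assert np.allclose(ours, theirs, atol=1e-8)

    def test_singular_design_raises(self):
        X = np.column_stack([np.ones(10), np.ones(10)])  # collinear
        with pytest.raises(SingularFitError):
            fit_ols(make_sample(np.arange(10), X))
        with pytest.raises(SingularFitError):  # more params than rows
            fit_ols(make_sample([1.0, 2.0], np.random.default_rng(0).normal(size=(2, 3))))


class TestQuantile:
    def test_median_intercept_only(self):
        s = make_sample([1, 2, 3, 4, 5])
        c = fit_quantile(s, EstimatorSpec("quantile", tau=0.5)).coefficients
        assert c["intercept"] == pytest.approx(3.0, abs=1e-9)

    def test_upper_tail_order_statistic_convention(self):
        # n*tau integral: the optimum is the interval [y_(95), y_(96)]; the
        # pinned convention returns the lower order statistic
        s = make_sample(np.arange(1.0, 101.0))
        c = fit_quantile(s, EstimatorSpec("quantile", tau=0.95)).coefficients
        assert c["intercept"] == pytest.approx(95.0, abs=1e-9)

    @pytest.mark.parametrize("seed,n,tau", [(0, 10, 0.95), (1, 12, 0.5), (2, 8, 0.9), (3, 11, 0.75)])
    def test_achieves_brute_force_optimal_check_loss(self, seed, n, tau):
        # with one covariate, some optimal fit interpolates two data points
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        c = fit_quantile(make_sample(y, x), EstimatorSpec("quantile", tau=tau)).coefficients
        ours = check_loss(tau, y - c["intercept"] - c["x1"] * x)
        best = np.inf
        for i, j in itertools.combinations(range(n), 2):
            if x[i] == x[j]:
                continue
            slope = (y[i] - y[j]) / (x[i] - x[j])
            icpt = y[i] - slope * x[i]
            best = min(best, check_loss(tau, y - icpt - slope * x))
        assert ours <= best + 1e-9

    def test_two_covariates_beats_statsmodels_objective(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 2))
        y = 1.0 + X @ [0.5, -1.0] + rng.standard_t(df=4, size=60)
        tau = 0.95
        c = fit_quantile(make_sample(y, X), EstimatorSpec("quantile", tau=tau))
        ours = check_loss(tau, y - c.coefficients["intercept"] - X @ c.coef_vector()[1:])
        m = sm.QuantReg(y, sm.add_constant(X)).fit(q=tau)
        theirs = check_loss(tau, y - sm.add_constant(X) @ m.params)
        assert ours <= theirs + 1e-6

    def test_tau_validation(self):
        with pytest.raises(SchemaError):
            EstimatorSpec("quantile", tau=1.0)


class TestBRT:
    def test_constant_response_predicts_constant(self):
        rng = np.random.default_rng(0)
        s = make_sample(np.full(30, 4.2), rng.normal(size=(30, 2)))
        est = fit_brt(s, EstimatorSpec("brt"))
        assert predict(est, {"x1": 10.0, "x2": -3.0}) == pytest.approx(4.2)

    def test_training_loss_monotone_per_stage(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 2))
        y = np.sin(X[:, 0]) + 0.5 * X[:, 1] + rng.normal(scale=0.2, size=80)
        spec = EstimatorSpec("brt", n_trees=60, subsample=1.0, learning_rate=0.1)
        est = fit_brt(make_sample(y, X), spec)
        score = est.model.train_score_
        assert (np.diff(score) <= 1e-12).all()

    def test_single_stump_recovers_step_function(self):
        # one depth-1 tree at learning rate 1 on a clean step: predictions are
        # the two leaf means, split found by exhaustive search
        x = np.array([0.0, 1.0, 2.0, 3.0, 10.0, 11.0, 12.0, 13.0] * 3)
        y = np.where(x < 5, 1.0, 5.0)
        spec = EstimatorSpec("brt", n_trees=1, max_depth=1, learning_rate=1.0, subsample=1.0)
        est = fit_brt(make_sample(y, x), spec)
        assert predict(est, [[2.5]]) == pytest.approx(1.0)
        assert predict(est, [[10.5]]) == pytest.approx(5.0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 2))
        y = X[:, 0] + rng.normal(size=60)
        s = make_sample(y, X)
        spec = EstimatorSpec("brt", n_trees=30, subsample=0.5, seed=99)
        a = predict(fit_brt(s, spec), X)
        b = predict(fit_brt(s, spec), X)
        assert np.array_equal(a, b)


class TestPredict:
    def test_linear_predictor(self):
        s = make_sample([1.0, 3.0, 5.0], [0.0, 1.0, 2.0])
        est = fit_ols(s)
        assert predict(est, {"x1": 3.0}) == pytest.approx(7.0)
        assert predict(est, [[3.0]]) == pytest.approx(7.0)

    def test_quantile_predictor_is_dot_product(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 2))
        y = rng.normal(size=20)
        est = fit_quantile(make_sample(y, X), EstimatorSpec("quantile", tau=0.5))
        row = {"x1": 0.3, "x2": -1.2}
        b = est.coefficients
        want = b["intercept"] + 0.3 * b["x1"] - 1.2 * b["x2"]
        assert predict(est, row) == pytest.approx(want, abs=1e-12)

    def test_missing_covariate_is_schema_error(self):
        est = fit_ols(make_sample([1.0, 2.0, 3.0], [0.0, 1.0, 2.0]))
        with pytest.raises(SchemaError):
            predict(est, {"x2": 1.0})
        with pytest.raises(SchemaError):
            predict(est, [[1.0, 2.0]])
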