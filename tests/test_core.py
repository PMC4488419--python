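"""IPB weights, resampling, iterated runs, and inflated sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ipboot.core import (
    inflated_ipb_sample,
    inverse_probability_weights,
    ipb_resample,
    iteration_rng,
    run_ipb,
)
from ipboot.errors import FailureBudgetExceeded, SchemaError, SingularFitError
from ipboot.estimators import EstimatorSpec

from conftest import make_sample


class TestWeights:
    def test_uniform_sample_gives_uniform_weights(self):
        s = make_sample(np.arange(4), p=np.full(4, 0.25))
        w = inverse_probability_weights(s)
        assert np.allclose(w.weights, 0.25)

    def test_four_strata_of_25_hand_values(self):
        # 2 rows @ P=.08, 3 @ .12, 6 @ .24, 9 @ .36; sum(1/P) = 100
        p = np.repeat([0.08, 0.12, 0.24, 0.36], [2, 3, 6, 9])
        s = make_sample(np.zeros(20), p=p)
        assert np.isclose((1 / p).sum(), 100.0)
        w = inverse_probability_weights(s).weights
        want = np.repeat([0.125, 1 / 12, 1 / 24, 1 / 36], [2, 3, 6, 9])
        assert np.allclose(w, want)

    def test_single_row(self):
        s = make_sample([1.0], p=[0.1])
        assert inverse_probability_weights(s).weights == pytest.approx([1.0])

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.floats(1e-4, 1.0), min_size=1, max_size=40))
    def test_normalization_and_proportionality(self, probs):
        s = make_sample(np.zeros(len(probs)), p=probs)
        w = inverse_probability_weights(s)
        assert w.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert (w.weights > 0).all()
        prod = w.weights * np.asarray(probs)
        assert np.ptp(prod) <= 1e-12 * prod.max()


class TestResample:
    def test_degenerate_single_row(self):
        s = make_sample([3.0], p=[0.2])
        r = ipb_resample(s, size=5, rng=0)
        assert r.n == 5 and (r.response == 3.0).all()

    def test_multinomial_law_two_rows(self):
        # w = (2/3, 1/3): row-1 frequency over 30k single-draw resamples
        s = make_sample([0.0, 1.0], p=[0.1, 0.2])
        w = inverse_probability_weights(s)
        assert np.allclose(w.weights, [2 / 3, 1 / 3])
        rng = np.random.default_rng(5)
        reps = 30_000
        hits = sum(ipb_resample(s, w, size=1, rng=rng).unit_id[0] == 1 for _ in range(reps))
        se = np.sqrt((2 / 3) * (1 / 3) / reps)
        assert abs(hits / reps - 2 / 3) < 3 * se

    def test_input_sample_unchanged(self):
        s = make_sample(np.arange(6, dtype=float), p=np.linspace(0.1, 0.6, 6))
        before = (s.response.copy(), s.inclusion_prob.copy(), s.unit_id.copy())
        ipb_resample(s, size=100, rng=1)
        assert np.array_equal(s.response, before[0])
        assert np.array_equal(s.inclusion_prob, before[1])
        assert np.array_equal(s.unit_id, before[2])

    def test_rejects_bad_size_and_foreign_weights(self):
        s = make_sample([1.0, 2.0], p=[0.5, 0.5])
        with pytest.raises(SchemaError):
            ipb_resample(s, size=0, rng=0)
        other = inverse_probability_weights(make_sample([1.0] * 3, p=[0.2] * 3))
        with pytest.raises(SchemaError):
            ipb_resample(s, weights=other, rng=0)


class TestRunIPB:
    def _uniform_regression_sample(self, n=80, seed=3):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = 1.0 + 2.0 * x + rng.normal(scale=0.5, size=n)
        return make_sample(y, x, p=np.full(n, 0.25))

    def test_uniform_probabilities_reduce_to_ordinary_bootstrap(self):
        from ipboot.estimators import fit_ols

        s = self._uniform_regression_sample()
        res = run_ipb(s, EstimatorSpec("ols"), n_iter=400, seed=11)
        direct = fit_ols(s).coefficients
        for name in ("intercept", "x1"):
            assert abs(res.mean_estimate[name] - direct[name]) < 2 * res.se_estimate[name]

    def test_single_iteration_flags_se_invalid(self):
        s = self._uniform_regression_sample()
        res = run_ipb(s, EstimatorSpec("ols"), n_iter=1, seed=0)
        assert res.n_iter == 1 and not res.se_valid and res.se_estimate is None
        assert res.mean_estimate.equals(res.per_iteration.iloc[0])

    def test_mean_recomputes_from_iterations(self):
        s = self._uniform_regression_sample()
        res = run_ipb(s, EstimatorSpec("ols"), n_iter=50, seed=2)
        assert np.allclose(res.mean_estimate, res.recompute_mean())

    def test_deterministic_given_seed(self):
        s = self._uniform_regression_sample()
        a = run_ipb(s, EstimatorSpec("ols"), n_iter=25, seed=7)
        b = run_ipb(s, EstimatorSpec("ols"), n_iter=25, seed=7)
        assert a.per_iteration.equals(b.per_iteration)

    def test_iteration_streams_independent_of_order(self):
        # the counter-based scheme lets any iteration be reproduced alone
        a = iteration_rng(9, 3).integers(2**31)
        _ = iteration_rng(9, 2).integers(2**31)
        b = iteration_rng(9, 3).integers(2**31)
        assert a == b

    def test_failure_budget(self):
        class AlwaysFails:
            family = "stub"

            def fit_coefficients(self, sample):
                raise SingularFitError("stub")

        s = self._uniform_regression_sample(n=10)
        with pytest.raises(FailureBudgetExceeded):
            run_ipb(s, AlwaysFails(), n_iter=20, seed=0)

    def test_isolated_failures_dropped_with_warning(self):
        class Flaky:
            family = "stub"

            def fit_coefficients(self, sample):
                # degenerate resamples (few distinct rows) fail to "fit"
                if len(np.unique(sample.unit_id)) < 4:
                    raise SingularFitError("degenerate")
                return {"theta": float(sample.response.mean())}

        s = make_sample(np.arange(5, dtype=float), p=[0.1, 0.2, 0.3, 0.4, 0.5])
        with pytest.warns(UserWarning, match="dropped"):
            res = run_ipb(s, Flaky(), n_iter=200, seed=1, max_fail_frac=0.9)
        assert res.n_failed > 0
        assert len(res.per_iteration) == 200 - res.n_failed

    def test_se_does_not_shrink_with_more_iterations(self):
        # bootstrap SE estimates the estimator's sampling SD: a property of
        # the sample size, not of the iteration count
        s = self._uniform_regression_sample(n=40)
        se_small = run_ipb(s, EstimatorSpec("ols"), n_iter=500, seed=3).se_estimate
        se_large = run_ipb(s, EstimatorSpec("ols"), n_iter=5000, seed=4).se_estimate
        for name in ("intercept", "x1"):
            assert 0.8 < se_large[name] / se_small[name] < 1.25


class TestInflated:
    def test_factor_one_equals_plain_resample(self):
        s = make_sample(np.arange(8, dtype=float), p=np.linspace(0.1, 0.8, 8))
        a = inflated_ipb_sample(s, 1.0, rng=13)
        b = ipb_resample(s, size=s.n, rng=13)
        assert np.array_equal(a.unit_id, b.unit_id)
        assert not a.inflated

    def test_factor_100_origin_frequencies(self):
        p = np.repeat([0.08, 0.12, 0.24, 0.36], [2, 3, 6, 9])
        s = make_sample(np.zeros(20), p=p)
        r = inflated_ipb_sample(s, 100.0, rng=21)
        assert r.n == 2000 and r.inflated
        w = inverse_probability_weights(s).weights
        counts = np.bincount(
            np.searchsorted(s.unit_id, r.unit_id), minlength=20
        )
        se = np.sqrt(r.n * w * (1 - w))
        assert (np.abs(counts - r.n * w) < 3.5 * se).all()

    def test_inflated_fit_unbiased_but_se_understated(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        n = 60
        x = rng.normal(size=n)
        y = 1.0 + 2.0 * x + rng.normal(scale=0.7, size=n)
        s = make_sample(y, x, p=np.full(n, 0.3))  # uniform design
        r = inflated_ipb_sample(s, 100.0, rng=3)

        direct = sm.OLS(y, sm.add_constant(x)).fit()
        blown = sm.OLS(r.response, sm.add_constant(r.covariates[:, 0])).fit()
        for k in range(2):
            assert abs(blown.params[k] - direct.params[k]) < 2 * direct.bse[k]
        # apparent n is 100x: reported SEs shrink by ~sqrt(100)
        ratio = blown.bse / direct.bse
        assert (ratio < 0.2).all() and (ratio > 0.05).all()

    def test_invalid_factor(self):
        s = make_sample([1.0], p=[0.5])
        for bad in (0.5, np.nan, np.inf):
            with pytest.raises(SchemaError):
                inflated_ipb_sample(s, bad, rng=0)
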