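import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gcredist.causes import CAUSE_IDS
from gcredist.model import (
    FitResult,
    ModelParameters,
    PriorConfig,
    class_probabilities,
    fit_map,
    format_rrr_table,
    linear_predictor,
    log_likelihood,
    log_prior,
    rrr_table,
)

from conftest import make_dataset

J = len(CAUSE_IDS)


def params_zero(U, S=1, P=1, R=1, sigma=None):
    return ModelParameters.zeros(U, J, S, P, R, sigma=sigma)


class TestLinearPredictor:
    def test_all_zero_params_give_zero_theta(self):
        p = params_zero(3)
        theta = linear_predictor(p, [0.0], np.zeros((1, J)), [0], [0], [0])
        np.testing.assert_array_equal(theta, np.zeros((1, 3)))

    def test_intercept_only(self):
        p = params_zero(2)
        p.alpha[1] = 1.0
        theta = linear_predictor(p, [0.0], np.zeros((1, J)), [0], [0], [0])
        np.testing.assert_allclose(theta, [[0.0, 1.0]])

    def test_linearity_in_indicators(self):
        p = params_zero(2)
        jstar = 5
        p.alpha[1] = 0.25
        p.gamma[1, jstar] = 0.5
        M = np.zeros((1, J))
        M[0, jstar] = 1
        theta = linear_predictor(p, [0.0], M, [0], [0], [0])
        np.testing.assert_allclose(theta, [[0.0, 0.75]])

    def test_reference_column_zero_with_random_effects(self):
        p = params_zero(3, S=2)
        p.pi_state[1:, :] = 0.7
        theta = linear_predictor(p, [1.0], np.zeros((2, J)), [0, 1], [0, 0], [0, 0])
        np.testing.assert_array_equal(theta[:, 0], 0.0)

    def test_unseen_level_contributes_zero(self):
        p = params_zero(2, S=2)
        p.pi_state[1, :] = 3.0
        theta = linear_predictor(p, [0.0], np.zeros((1, J)), [5], [0], [0])
        np.testing.assert_allclose(theta, [[0.0, 0.0]])

    def test_identifiability_shift_invariance(self):
        # adding a constant to every target's predictor leaves softmax unchanged
        rng = np.random.default_rng(0)
        theta = rng.normal(size=(4, 3))
        shifted = theta + 1.7
        np.testing.assert_allclose(
            class_probabilities(theta), class_probabilities(shifted), atol=1e-12
        )


class TestClassProbabilities:
    def test_uniform(self):
        np.testing.assert_allclose(class_probabilities(np.zeros(3)), np.full(3, 1 / 3))

    def test_analytic_two_class(self):
        p = class_probabilities(np.array([0.0, math.log(2.0)]))
        np.testing.assert_allclose(p, [1 / 3, 2 / 3], atol=1e-12)

    def test_extreme_values_do_not_overflow(self):
        p = class_probabilities(np.array([0.0, 1000.0]))
        assert np.isfinite(p).all()
        np.testing.assert_allclose(p, [0.0, 1.0], atol=1e-300)

    def test_non_finite_raises(self):
        with pytest.raises(ValueError):
            class_probabilities(np.array([0.0, np.inf]))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=6))
    def test_rows_sum_to_one(self, theta):
        p = class_probabilities(np.array(theta))
        assert abs(p.sum() - 1.0) < 1e-12
        assert (p >= 0).all()


class TestLogLikelihood:
    def test_single_observation_uniform(self):
        ds = make_dataset([0])
        assert log_likelihood(params_zero(2), ds) == pytest.approx(math.log(0.5))

    def test_matches_bruteforce_enumeration(self):
        # 3 observations, U=2, one binary covariate; oracle multiplies
        # per-record softmax terms explicitly in pure python
        jstar = CAUSE_IDS.index("B.4")
        M = np.zeros((3, J))
        M[0, jstar] = 1
        M[2, jstar] = 1
        y = [0, 1, 1]
        ds = make_dataset(y, M=M)
        p = params_zero(2)
        p.alpha[1] = 0.3
        p.gamma[1, jstar] = -0.8

        expected = 0.0
        for i in range(3):
            theta = [0.0, 0.3 + (-0.8) * M[i, jstar]]
            denom = sum(math.exp(t) for t in theta)
            expected += math.log(math.exp(theta[y[i]]) / denom)
        assert log_likelihood(p, ds) == pytest.approx(expected, abs=1e-12)

    def test_duplication_doubles_loglik(self):
        jstar = 3
        M = np.zeros((2, J))
        M[1, jstar] = 1
        ds1 = make_dataset([0, 1], M=M)
        ds2 = make_dataset([0, 1, 0, 1], M=np.vstack([M, M]))
        p = params_zero(2)
        p.alpha[1] = -0.4
        p.gamma[1, jstar] = 1.1
        assert log_likelihood(p, ds2) == pytest.approx(2 * log_likelihood(p, ds1))

    def test_out_of_range_outcome_raises(self):
        ds = make_dataset([5])
        with pytest.raises(ValueError):
            log_likelihood(params_zero(2), ds)


class TestLogPrior:
    def test_closed_form_at_zero(self):
        # independent oracle: scipy.stats densities summed explicitly
        U, S, P, R = 3, 2, 2, 2
        p = params_zero(U, S, P, R, sigma={"state": 1.0, "place": 1.0, "race": 1.0})
        prior = PriorConfig(fixed_scale=2.5, sigma_scale=1.0)
        K = U - 1
        expected = (
            stats.norm.logpdf(0, scale=2.5) * (K + K + K * J)
            + stats.norm.logpdf(0, scale=1.0) * (K * (S + P + R))
            + stats.halfnorm.logpdf(1.0, scale=1.0) * 3
        )
        assert log_prior(p, prior) == pytest.approx(expected, abs=1e-10)

    def test_wider_prior_penalizes_nonzero_value_less(self):
        p0 = params_zero(2)
        p = params_zero(2)
        p.gamma[1, 0] = 2.0
        narrow, wide = PriorConfig(fixed_scale=0.5), PriorConfig(fixed_scale=5.0)
        penalty_narrow = log_prior(p0, narrow) - log_prior(p, narrow)
        penalty_wide = log_prior(p0, wide) - log_prior(p, wide)
        assert penalty_wide < penalty_narrow

    def test_exchangeable_under_level_permutation(self):
        p = params_zero(2, S=3)
        p.pi_state[1] = np.array([0.3, -0.9, 0.6])
        prior = PriorConfig()
        lp = log_prior(p, prior)
        p.pi_state[1] = np.array([-0.9, 0.6, 0.3])
        assert log_prior(p, prior) == pytest.approx(lp)

    def test_invalid_sigma_raises(self):
        with pytest.raises(ValueError):
            params_zero(2, sigma={"state": -1.0, "place": 1.0, "race": 1.0})


class TestFitMap:
    def test_intercept_only_recovers_empirical_proportions(self):
        rng = np.random.default_rng(1)
        y = rng.choice(3, size=3000, p=[0.5, 0.3, 0.2])
        ds = make_dataset(y, targets=("B.2", "B.3.1", "B.3.2"))
        fit = fit_map(ds, PriorConfig(fixed_scale=100.0, map_sigma={"state": 100.0, "place": 100.0, "race": 100.0}))
        probs = class_probabilities(
            linear_predictor(fit.params, [0.0], np.zeros((1, J)), [0], [0], [0])
        )[0]
        empirical = np.bincount(y, minlength=3) / len(y)
        np.testing.assert_allclose(probs, empirical, atol=1e-3)

    def test_duplicated_dataset_same_estimate(self):
        rng = np.random.default_rng(2)
        jstar = 4
        M = np.zeros((200, J))
        M[:100, jstar] = 1
        y = rng.integers(0, 2, 200)
        ds1 = make_dataset(y, M=M)
        ds2 = make_dataset(np.tile(y, 2), M=np.vstack([M, M]))
        f1 = fit_map(ds1)
        f2 = fit_map(ds2)
        # prior weight halves relative to data, so allow small drift
        np.testing.assert_allclose(f2.params.alpha, f1.params.alpha, atol=0.05)

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 100)
        ds = make_dataset(y)
        f1 = fit_map(ds, seed=0)
        f2 = fit_map(ds, seed=0)
        np.testing.assert_array_equal(f1.params.alpha, f2.params.alpha)

    def test_unfittable_raises(self):
        ds = make_dataset([0, 0, 0], targets=("B.2",))
        ds.unfittable_reason = "fewer than 2 surviving targets (1)"
        with pytest.raises(ValueError, match="unfittable"):
            fit_map(ds)


class TestRrrTable:
    def _fit(self):
        p = params_zero(3)
        p.gamma[1, 0] = math.log(2.0)
        p.gamma[2, 1] = math.log(0.05)
        p.gamma[2, 2] = math.log(50.0)
        return FitResult(
            mode="MAP", stratum_key="s", targets=("B.2", "B.3.1", "B.3.2"),
            params=p, seed=0,
        )

    def test_reference_column_all_ones(self):
        table = rrr_table(self._fit())
        np.testing.assert_array_equal(table.iloc[:, 0].values, 1.0)

    def test_zero_coefficient_gives_unit_rrr(self):
        table = rrr_table(self._fit())
        assert table.iloc[5, 1] == pytest.approx(1.0)

    def test_raw_values_preserved_formatting_clips(self):
        table = rrr_table(self._fit())
        assert table.iloc[0, 1] == pytest.approx(2.0)
        formatted = format_rrr_table(table)
        assert formatted.iloc[0, 1] == "2.00x"
        assert formatted.iloc[1, 2] == "≤0.1x"
        assert formatted.iloc[2, 2] == "≥10x"
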