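"""Cumulative link model math, checked against direct logistic-CDF oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

import varclm as v
from varclm.io import Dataset, VariantRecord


def _record(score, cls):
    return VariantRecord(variant_id=f"id:{score}:{cls}", score=score, expert_class=cls)


class TestParameters:
    def test_theta_must_increase(self):
        with pytest.raises(ValueError):
            v.CLMParameters(theta=[0.0, -1.0], beta=[0.0])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            v.CLMParameters(theta=[0.0, np.inf], beta=[0.0])


class TestCumulativeProbs:
    def test_two_class_midpoint(self):
        params = v.CLMParameters(theta=[0.0], beta=[0.0])
        assert np.allclose(v.cumulative_probs(params, [3.7]), [0.5, 1.0])

    def test_matches_logistic_cdf(self, simple_params):
        gamma = v.cumulative_probs(simple_params, [0.0])
        expected = np.append(expit([-2.0, -1.0, 1.0, 2.0]), 1.0)
        np.testing.assert_allclose(gamma, expected, atol=1e-12)

    def test_large_score_empties_lower_classes(self):
        params = v.CLMParameters(theta=[-2.0, -1.0, 1.0, 2.0], beta=[1.0])
        gamma = v.cumulative_probs(params, [1e4])
        assert np.all(gamma[:-1] < 1e-10) and gamma[-1] == 1.0

    def test_non_finite_covariate_rejected(self, simple_params):
        with pytest.raises(ValueError):
            v.cumulative_probs(simple_params, [np.nan])


class TestClassProbs:
    def test_oracle_differences(self, simple_params):
        # first differences of the logistic CDF at the cut-offs
        profile = v.class_probs(simple_params, [0.0])
        g = expit([-2.0, -1.0, 1.0, 2.0])
        expected = np.diff(np.concatenate([[0.0], g, [1.0]]))
        np.testing.assert_allclose(profile.probs, expected, atol=1e-12)
        np.testing.assert_allclose(profile.probs.sum(), 1.0, atol=1e-12)

    def test_covariate_drops_out_when_beta_zero(self, simple_params):
        p1 = v.class_probs(simple_params, [-100.0]).probs
        p2 = v.class_probs(simple_params, [100.0]).probs
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    @given(
        t1=st.floats(-5, 5),
        gaps=st.tuples(*[st.floats(0.01, 4)] * 3),
        beta=st.floats(-2, 2),
        x=st.floats(-50, 50),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_probs_sum_to_one_and_lie_in_unit_interval(self, t1, gaps, beta, x):
        params = v.CLMParameters(theta=t1 + np.concatenate([[0], np.cumsum(gaps)]), beta=[beta])
        profile = v.class_probs(params, [x])
        assert abs(profile.probs.sum() - 1.0) < 1e-12
        assert np.all(profile.probs >= 0) and np.all(profile.probs <= 1)
        assert np.all(np.diff(profile.cumulative) >= -1e-12)

    @given(x1=st.floats(-30, 30), x2=st.floats(-30, 30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_cumulative_mass_shifts_up_with_score_for_positive_beta(self, x1, x2):
        params = v.CLMParameters(theta=[-2.0, -1.0, 1.0, 2.0], beta=[0.5])
        lo, hi = min(x1, x2), max(x1, x2)
        g_lo = v.cumulative_probs(params, [lo])
        g_hi = v.cumulative_probs(params, [hi])
        assert np.all(g_hi <= g_lo + 1e-12)


class TestLikelihoodAndDeviance:
    def test_certain_observation_has_zero_loglik(self):
        params = v.CLMParameters(theta=[40.0], beta=[0.0])  # P(class 1) ~ 1
        ds = Dataset(records=[_record(0.0, 1)], n_classes=2)
        assert v.log_likelihood(params, ds) == pytest.approx(0.0, abs=1e-12)

    def test_single_record_matches_class_prob(self, simple_params):
        ds = Dataset(records=[_record(0.0, 3)], n_classes=5)
        expected = np.log(v.class_probs(simple_params, [0.0]).probs[2])
        assert v.log_likelihood(simple_params, ds) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(np.log(0.4621), abs=1e-4)

    def test_additivity_over_records(self, simple_params):
        one = Dataset(records=[_record(0.0, 2)], n_classes=5)
        two = Dataset(records=[_record(0.0, 2)] * 2, n_classes=5)
        assert v.log_likelihood(simple_params, two) == pytest.approx(
            2 * v.log_likelihood(simple_params, one), abs=1e-12
        )

    def test_empty_dataset_loglik_is_zero(self, simple_params):
        assert v.log_likelihood(simple_params, Dataset(n_classes=5)) == 0.0

    def test_deviance_formula(self, simple_params):
        # P = 0.5 => deviance = 2 ln 2
        params = v.CLMParameters(theta=[0.0], beta=[0.0])
        assert v.deviance(params, _record(0.0, 1)) == pytest.approx(2 * np.log(2), abs=1e-12)

    def test_deviance_decreasing_in_probability(self, simple_params):
        # class 3 is the most probable at x=0, class 1 less so
        d3 = v.deviance(simple_params, _record(0.0, 3))
        d1 = v.deviance(simple_params, _record(0.0, 1))
        assert d3 < d1

    def test_loglik_equals_minus_half_total_deviance(self, simple_params, rng):
        records = [
            _record(float(s), int(c))
            for s, c in zip(rng.normal(0, 5, 40), rng.integers(1, 6, 40))
        ]
        ds = Dataset(records=records, n_classes=5)
        total_dev = sum(v.deviance(simple_params, r) for r in records)
        assert v.log_likelihood(simple_params, ds) == pytest.approx(-total_dev / 2, rel=1e-12)


class TestAssignClass:
    def test_symmetric_model_prefers_middle(self, simple_params):
        assert v.assign_class(simple_params, [0.0]) == 3

    def test_extreme_score_hits_top_class(self):
        params = v.CLMParameters(theta=[-2.0, -1.0, 1.0, 2.0], beta=[1.0])
        assert v.assign_class(params, [1e3]) == 5

    def test_exact_tie_breaks_low(self):
        # J=2 with theta=0, beta=0: both classes at exactly 0.5
        params = v.CLMParameters(theta=[0.0], beta=[0.0])
        assert v.assign_class(params, [0.0]) == 1
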