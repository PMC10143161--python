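"""Discrete Bayesian estimation: likelihood, posterior, EM cycling."""

import numpy as np
import pytest

from lssrobust.bayes import (BayesianIndividualModel, EstimationFailureError,
                             ObservationSet, ResidualErrorModel,
                             estimate_individual, log_likelihood, npem_cycle,
                             population_parameter_error, posterior)
from lssrobust.pk import DoseEvent, PKParameters, concentration
from lssrobust.prior import SupportPointPrior
from lssrobust.robustness import sample_observations

DOSE = DoseEvent(3235.0)
TIMES = np.array([10 / 60, 30 / 60, 2.0, 5.0])


def _obs_from(theta, times=TIMES, dose=DOSE):
    p = PKParameters.from_array(theta)
    return ObservationSet(times, concentration(p, dose, times), dose)


class TestLogLikelihood:
    def test_perfect_fit_value(self):
        """At exact predictions every term is -log(sd * sqrt(2 pi))."""
        theta = np.array([2.0, 10.0, 8.0, 5.0])
        obs = _obs_from(theta)
        em = ResidualErrorModel(c0=0.5, c1=0.0)
        expected = -len(obs) * np.log(0.5 * np.sqrt(2 * np.pi))
        assert log_likelihood(obs, theta, em) == pytest.approx(expected)

    def test_doubling_sd_costs_n_log_two_at_perfect_fit(self):
        theta = np.array([2.0, 10.0, 8.0, 5.0])
        obs = _obs_from(theta)
        l1 = log_likelihood(obs, theta, ResidualErrorModel(0.3, 0.0))
        l2 = log_likelihood(obs, theta, ResidualErrorModel(0.6, 0.0))
        assert l1 - l2 == pytest.approx(len(obs) * np.log(2.0))

    def test_term_by_term_recomputation(self, rng):
        theta = np.array([1.5, 9.0, 7.0, 6.0])
        times = np.sort(rng.uniform(0.1, 8.0, 6))
        y = rng.uniform(1, 100, 6)
        obs = ObservationSet(times, y, DOSE)
        em = ResidualErrorModel(0.1, 0.05)
        p = PKParameters.from_array(theta)
        total = 0.0
        for t, yj in zip(times, y):
            mu = concentration(p, DOSE, t)
            sd = 0.1 + 0.05 * mu
            total += (-0.5 * ((yj - mu) / sd) ** 2
                      - np.log(sd) - 0.5 * np.log(2 * np.pi))
        assert log_likelihood(obs, theta, em) == pytest.approx(total)


class TestPosterior:
    def test_two_point_bayes(self):
        """With equal prior mass and likelihood ratio r the first weight is
        r / (1 + r)."""
        theta = np.array([[2.0, 10.0, 8.0, 5.0], [3.0, 10.0, 8.0, 5.0]])
        prior = SupportPointPrior(theta, np.array([0.5, 0.5]))
        obs = _obs_from(theta[0])
        em = ResidualErrorModel(0.5, 0.1)
        l1 = log_likelihood(obs, theta[0], em)
        l2 = log_likelihood(obs, theta[1], em)
        r = np.exp(l1 - l2)
        w = posterior(prior, obs, em)
        assert w[0] == pytest.approx(r / (1 + r), rel=1e-12)

    def test_no_observations_returns_prior(self, fixture_prior):
        obs = ObservationSet(np.array([]), np.array([]), DOSE)
        np.testing.assert_array_equal(posterior(fixture_prior, obs),
                                      fixture_prior.prob)

    def test_matches_high_precision_enumeration(self, rng):
        """Log-sum-exp path equals arbitrary-precision brute force for a
        10-point prior."""
        import sympy
        theta = np.column_stack([rng.uniform(1, 6, 10),
                                 rng.uniform(6, 15, 10),
                                 rng.uniform(4, 12, 10),
                                 rng.uniform(3, 12, 10)])
        prob = rng.dirichlet(np.ones(10))
        prior = SupportPointPrior(theta, prob / prob.sum())
        obs = _obs_from(theta[3] * 1.02)
        em = ResidualErrorModel(0.1, 0.05)
        w = posterior(prior, obs, em)
        ells = [log_likelihood(obs, theta[i], em) for i in range(10)]
        terms = [sympy.Float(prior.prob[i], 50) * sympy.exp(sympy.Float(e, 50))
                 for i, e in enumerate(ells)]
        total = sum(terms)
        brute = np.array([float(t / total) for t in terms])
        np.testing.assert_allclose(w, brute, atol=1e-12)

    def test_underflow_handled_for_distant_points(self):
        """Likelihoods far below the floating-point range still normalise."""
        theta = np.array([[2.0, 10.0, 8.0, 5.0], [11.0, 25.0, 30.0, 50.0]])
        prior = SupportPointPrior(theta, np.array([0.5, 0.5]))
        obs = _obs_from(theta[0])
        w = posterior(prior, obs, ResidualErrorModel(0.01, 0.001))
        assert w.sum() == pytest.approx(1.0)
        assert w[0] == pytest.approx(1.0)


class TestIndividualEstimation:
    def test_single_point_prior_returns_its_clearance(self):
        theta = np.array([[3.0, 10.0, 8.0, 5.0]])
        prior = SupportPointPrior(theta, np.array([1.0]))
        res = estimate_individual(prior, _obs_from(theta[0]))
        assert res.gfr == pytest.approx(3.0 * 1000 / 60)
        assert res.ess == pytest.approx(1.0)

    def test_error_vanishes_as_kernel_narrows(self, fixture_prior):
        """Observations generated from a support point in the prior are
        attributed to it as the residual SD shrinks."""
        theta = fixture_prior.theta[10]
        obs = _obs_from(theta)
        true_gfr = theta[0] * 1000 / 60
        errors = []
        for c0 in (1.0, 0.1, 0.001):
            res = estimate_individual(fixture_prior, obs,
                                      ResidualErrorModel(c0, c0 / 10))
            errors.append(abs(res.gfr - true_gfr))
        assert errors[-1] <= errors[0]
        assert errors[-1] < 1e-6 * true_gfr

    def test_rich_sampling_concentrates_posterior(self, fixture_prior):
        """Dense noiseless sampling pins the generating support point."""
        times = np.arange(1, 24 * 60 + 1) / 60.0
        theta = fixture_prior.theta[25]
        p = PKParameters.from_array(theta)
        obs = ObservationSet(times, concentration(p, DOSE, times), DOSE)
        res = BayesianIndividualModel(obs, fixture_prior,
                                      ResidualErrorModel(0.1, 0.05)).fit()
        assert res.weights[25] > 0.999

    def test_auc_bounded_by_support_range(self, fixture_prior, small_cohort):
        subject = small_cohort[0]
        obs = sample_observations(subject, TIMES)
        res = estimate_individual(fixture_prior, obs)
        auc_pts = DOSE.amount / fixture_prior.theta[:, 0]
        assert auc_pts.min() <= res.auc_inf <= auc_pts.max()

    def test_auc_matches_posterior_mean_curve_integral(self, fixture_prior,
                                                       small_cohort):
        """The reported AUC equals trapezoid + beta-tail integration of the
        posterior-mean predicted curve (integration is linear)."""
        from lssrobust.pk import hybrid_rate_constants, two_compartment_bolus
        subject = small_cohort[1]
        obs = sample_observations(subject, TIMES)
        res = estimate_individual(fixture_prior, obs)
        grid = np.arange(0, 24 * 60 + 1) / 60.0
        th = fixture_prior.theta
        curves = two_compartment_bolus(th[:, 0:1], th[:, 1:2], th[:, 2:3],
                                       th[:, 3:4], DOSE.amount, grid[None, :])
        mean_curve = res.weights @ curves
        tail = 0.0
        for i, w in enumerate(res.weights):
            _, beta = hybrid_rate_constants(PKParameters.from_array(th[i]))
            tail += w * curves[i, -1] / beta
        numeric = np.trapezoid(mean_curve, grid) + tail
        assert numeric == pytest.approx(res.auc_inf, rel=5e-3)

    def test_summary_lists_all_parameters(self, fixture_prior, small_cohort):
        obs = sample_observations(small_cohort[2], TIMES)
        table = BayesianIndividualModel(obs, fixture_prior).fit().summary()
        assert list(table.index[:4]) == ["CL", "V", "Vp", "Q"]
        assert "GFR (mL/min)" in table.index


class TestCycling:
    def _observations(self, cohort, n=20):
        return [sample_observations(cohort[i], TIMES)
                for i in range(min(n, len(cohort)))]

    def test_zero_cycles_is_identity(self, fixture_prior, small_cohort):
        obs = self._observations(small_cohort, 5)
        out = npem_cycle(fixture_prior, obs, 0)
        assert out is fixture_prior

    def test_single_subject_single_cycle_gives_posterior(self, fixture_prior,
                                                         small_cohort):
        obs = [sample_observations(small_cohort[0], TIMES)]
        out = npem_cycle(fixture_prior, obs, 1)
        # underflowed weights are floored at a representable minimum by the
        # EM update, so compare with a matching absolute tolerance
        np.testing.assert_allclose(out.prob,
                                   posterior(fixture_prior, obs[0]),
                                   rtol=1e-9, atol=1e-200)

    def test_marginal_likelihood_nondecreasing(self, fixture_prior,
                                               small_cohort):
        """EM property: the cohort marginal log-likelihood never decreases
        across reweighting cycles."""
        obs = self._observations(small_cohort, 20)
        _, trace = npem_cycle(fixture_prior, obs, 25, return_loglik=True)
        assert len(trace) == 25
        diffs = np.diff(trace)
        assert np.all(diffs >= -1e-8)

    def test_empty_cohort_rejected(self, fixture_prior):
        with pytest.raises(ValueError):
            npem_cycle(fixture_prior, [], 1)


class TestPopulationParameterError:
    def test_perfect_estimates(self, rng):
        truth = rng.uniform(1, 10, (30, 4))
        table = population_parameter_error(truth, truth)
        assert (table == 0).all().all()

    def test_uniform_ten_percent_bias(self, rng):
        truth = rng.uniform(1, 10, (30, 4))
        table = population_parameter_error(1.1 * truth, truth)
        np.testing.assert_allclose(table["population_pct"], 10.0, rtol=1e-9)
        np.testing.assert_allclose(table["individual_pct"], 10.0, rtol=1e-9)

    def test_matches_direct_arithmetic(self, rng):
        truth = rng.uniform(1, 10, (15, 4))
        est = truth * rng.uniform(0.7, 1.4, (15, 4))
        table = population_parameter_error(est, truth)
        for d in range(4):
            pop = 100 * abs(est[:, d].mean() - truth[:, d].mean()) \
                / truth[:, d].mean()
            ind = (100 * np.abs(est[:, d] - truth[:, d]) / truth[:, d]).mean()
            assert table["population_pct"].iloc[d] == pytest.approx(pop)
            assert table["individual_pct"].iloc[d] == pytest.approx(ind)
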