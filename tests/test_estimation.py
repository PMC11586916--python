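"""Likelihoods, unconstrained MLEs, and the constrained fit."""

import numpy as np
import pytest

from crsim import (
    CensoringModel,
    CompetingRisksModel,
    TransitionIntensity,
    fit_constrained,
    fit_mle,
    log_likelihood,
    log_likelihood_random_censoring,
    max_pairwise_distance,
    select_null_estimates,
    simulate_group,
)
from crsim.estimation import ConstrainedFitResult, censoring_log_likelihood


def _exp_model(rates, tau=90.0):
    return CompetingRisksModel(
        tuple(TransitionIntensity("exponential", (r,)) for r in rates), tau=tau
    )


class TestLogLikelihood:
    def test_two_subject_closed_form(self):
        # event of type 1 at t=10 plus a censoring at t=90 under rates
        # (0.01, 0.02, 0.03): survival term uses the all-cause rate 0.06
        m = _exp_model((0.01, 0.02, 0.03))
        ll = log_likelihood(m, (np.array([10.0, 90.0]), np.array([1, 0])))
        assert ll == pytest.approx((-0.06 * 10 + np.log(0.01)) + (-0.06 * 90))

    def test_empty_data(self):
        assert log_likelihood(_exp_model((0.01,)), (np.array([]), np.array([]))) == 0.0

    def test_additivity_doubling(self, rng):
        m = _exp_model((0.002, 0.001))
        times = rng.exponential(300, 40)
        status = rng.integers(0, 3, 40)
        one = log_likelihood(m, (times, status))
        two = log_likelihood(m, (np.tile(times, 2), np.tile(status, 2)))
        assert two == pytest.approx(2 * one)

    def test_event_at_zero_intensity_gives_minus_inf(self):
        m = CompetingRisksModel((TransitionIntensity("exponential", (0.0,)),), tau=90)
        ll = log_likelihood(m, (np.array([10.0]), np.array([1])))
        assert ll == -np.inf


class TestRandomCensoringLikelihood:
    def test_single_censored_subject_closed_form(self):
        m = _exp_model((0.002,))
        c = CensoringModel.exponential(0.01)
        ll = log_likelihood_random_censoring(m, c, (np.array([100.0]), np.array([0])))
        assert ll == pytest.approx(-0.002 * 100 + np.log(0.01) - 0.01 * 100)

    def test_no_censored_subjects_equals_plain_likelihood(self):
        m = _exp_model((0.002, 0.001))
        c = CensoringModel.exponential(0.01)
        data = (np.array([10.0, 20.0, 30.0]), np.array([1, 2, 1]))
        assert log_likelihood_random_censoring(m, c, data) == pytest.approx(
            log_likelihood(m, data)
        )

    def test_additivity_over_subjects(self):
        m = _exp_model((0.002,))
        c = CensoringModel.exponential(0.01)
        d1 = (np.array([10.0]), np.array([1]))
        d2 = (np.array([55.0]), np.array([0]))
        both = (np.array([10.0, 55.0]), np.array([1, 0]))
        assert log_likelihood_random_censoring(m, c, both) == pytest.approx(
            log_likelihood_random_censoring(m, c, d1)
            + log_likelihood_random_censoring(m, c, d2)
        )

    def test_theta_psi_separability(self, rng, scenario1_random):
        """The event-parameter MLE is unchanged by whether the censoring
        parameter is estimated jointly or not."""
        from crsim import generate_scenario_dataset

        ds = generate_scenario_dataset(scenario1_random, rng)
        g = ds.group(1)
        with_c = fit_mle(g, ["exponential"] * 3, CensoringModel.exponential(0.001))
        without_c = fit_mle(g, ["exponential"] * 3, None)
        assert with_c.model.theta == pytest.approx(without_c.model.theta)


class TestFitMLE:
    def test_exponential_occurrence_exposure(self):
        # 20 type-1 events in total observed time 10000 -> rate 0.002
        times = np.full(100, 100.0)
        status = np.array([1] * 20 + [0] * 80)
        fit = fit_mle((times, status), ["exponential"])
        assert fit.model.transitions[0].params[0] == pytest.approx(20 / 10000)
        assert fit.converged and fit.n_events_per_state[0] == 20

    def test_exponential_closed_form_on_simulated_data(self, rng, scenario1_random):
        from crsim import generate_scenario_dataset

        ds = generate_scenario_dataset(scenario1_random, rng)
        g = ds.group(2)
        fit = fit_mle(g, ["exponential"] * 3)
        total = g.times.sum()
        for j, ti in enumerate(fit.model.transitions, 1):
            assert ti.params[0] == pytest.approx(np.sum(g.status == j) / total, abs=1e-8)

    def test_exponential_censoring_occurrence_exposure(self, rng, scenario1_random):
        from crsim import generate_scenario_dataset

        ds = generate_scenario_dataset(scenario1_random, rng)
        g = ds.group(1)
        fit = fit_mle(g, ["exponential"] * 3, CensoringModel.exponential(0.001))
        assert fit.censoring.params[0] == pytest.approx(
            np.sum(g.status == 0) / g.times.sum()
        )

    def test_parameter_recovery_scenario1(self, rng):
        """Simulated data at n=1e5 recover the generating exponential rates
        within 3 standard errors (SE = rate/sqrt(events))."""
        truth = (0.001, 0.0011, 0.0004)
        g = simulate_group(_exp_model(truth), 100_000, CensoringModel.administrative(90), rng)
        fit = fit_mle(g, ["exponential"] * 3)
        for j, (ti, lam) in enumerate(zip(fit.model.transitions, truth), 1):
            d = np.sum(g.status == j)
            assert abs(ti.params[0] - lam) < 3 * lam / np.sqrt(d)

    def test_parameter_recovery_gompertz(self, rng):
        a, b = 0.002, -0.016
        m = CompetingRisksModel((TransitionIntensity("gompertz", (a, b)),), tau=90)
        g = simulate_group(m, 100_000, CensoringModel.administrative(90), rng)
        fit = fit_mle(g, ["gompertz"])
        ahat, bhat = fit.model.transitions[0].params
        se_a, se_b = _profile_ses(fit, g)
        assert abs(ahat - a) < 3 * se_a
        assert abs(bhat - b) < 3 * se_b

    def test_zero_event_state_flagged(self):
        times = np.full(50, 90.0)
        status = np.array([1] * 5 + [0] * 45)
        with pytest.warns(UserWarning, match="no events of type 2"):
            fit = fit_mle((times, status), ["exponential", "exponential"])
        assert fit.model.transitions[1].params[0] == 0.0
        assert not fit.converged

    def test_loglik_value_matches_direct_evaluation(self, rng):
        m = CompetingRisksModel(
            (
                TransitionIntensity("gompertz", (0.002, -0.016)),
                TransitionIntensity("weibull", (2894.8, 1.102)),
            ),
            tau=90,
        )
        g = simulate_group(m, 5000, CensoringModel.administrative(90), rng)
        fit = fit_mle(g, ["gompertz", "weibull"])
        assert fit.loglik == pytest.approx(log_likelihood(fit.model, g), rel=1e-10)


def _profile_ses(fit, g):
    """Standard errors from the numerically inverted observed information of
    the per-transition log-likelihood (central differences)."""
    from crsim.estimation import transition_loglik

    a, b = fit.model.transitions[0].params
    ev = g.times[g.status == 1]

    def ll(p):
        return transition_loglik(TransitionIntensity("gompertz", tuple(p)), g.times, ev)

    x = np.array([a, b])
    h = np.abs(x) * 1e-4
    hess = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            pp = x.copy(); pp[i] += h[i]; pp[j] += h[j]
            pm = x.copy(); pm[i] += h[i]; pm[j] -= h[j]
            mp = x.copy(); mp[i] -= h[i]; mp[j] += h[j]
            mm = x.copy(); mm[i] -= h[i]; mm[j] -= h[j]
            hess[i, j] = (ll(pp) - ll(pm) - ll(mp) + ll(mm)) / (4 * h[i] * h[j])
    cov = np.linalg.inv(-hess)
    return np.sqrt(np.diag(cov))


class TestConstrainedFit:
    def test_constraint_already_active_equals_unconstrained(self):
        """k=1 exponential groups whose MLE distance is exactly Delta."""
        t1 = np.full(100, 50.0)
        s1 = np.array([1] * 20 + [0] * 80)  # rate 0.004
        t2 = np.full(100, 50.0)
        s2 = np.array([1] * 10 + [0] * 90)  # rate 0.002
        con = fit_constrained((t1, s1), (t2, s2), ["exponential"], delta=0.002)
        assert con.model1.transitions[0].params[0] == pytest.approx(0.004)
        assert con.model2.transitions[0].params[0] == pytest.approx(0.002)
        assert con.constraint_residual <= 1e-6

    def test_matches_brute_force_profile_search(self, rng):
        """k=1 exponential equality fit agrees with a 1-D grid search over
        (lambda1, lambda1 +/- Delta) to log-likelihood tolerance 1e-6."""
        g1 = simulate_group(_exp_model((0.002,)), 300, CensoringModel.administrative(90), rng)
        g2 = simulate_group(_exp_model((0.0025,)), 300, CensoringModel.administrative(90), rng)
        delta = 0.003
        con = fit_constrained(g1, g2, ["exponential"], delta)

        def pair_ll(l1, l2):
            m1 = _exp_model((l1,))
            m2 = _exp_model((l2,))
            return log_likelihood(m1, g1) + log_likelihood(m2, g2)

        grid = np.linspace(1e-6, 0.02, 400_001)
        best = max(
            max(pair_ll(l, l + delta) for l in grid),
            max(pair_ll(l, l - delta) for l in grid if l - delta > 0),
        )
        assert con.joint_loglik == pytest.approx(best, abs=1e-6)
        assert con.constraint_residual <= 1e-6

    def test_joint_loglik_below_unconstrained_on_random_datasets(self, rng, scenario1):
        from crsim import generate_scenario_dataset

        for _ in range(50):
            ds = generate_scenario_dataset(scenario1, rng)
            g1, g2 = ds.group(1), ds.group(2)
            f1 = fit_mle(g1, ["exponential"] * 3)
            f2 = fit_mle(g2, ["exponential"] * 3)
            con = fit_constrained(g1, g2, ["exponential"] * 3, delta=0.0013)
            assert con.joint_loglik <= f1.loglik + f2.loglik + 1e-9
            assert con.constraint_residual <= 1e-6

    def test_gompertz_weibull_constraint_residual(self, rng):
        from crsim import generate_scenario_dataset, scenario_spec

        spec = scenario_spec(3, 300, 300)
        ds = generate_scenario_dataset(spec, rng)
        fams = ["gompertz", "gompertz", "weibull"]
        con = fit_constrained(ds.group(1), ds.group(2), fams, delta=0.01, rng=rng)
        assert con.constraint_residual <= 1e-6
        f1 = fit_mle(ds.group(1), fams)
        f2 = fit_mle(ds.group(2), fams)
        assert con.joint_loglik <= f1.loglik + f2.loglik + 1e-9

    def test_loglik_nonincreasing_as_delta_moves_from_dhat(self, rng, scenario1):
        from crsim import generate_scenario_dataset

        ds = generate_scenario_dataset(scenario1, rng)
        g1, g2 = ds.group(1), ds.group(2)
        f1 = fit_mle(g1, ["exponential"] * 3)
        f2 = fit_mle(g2, ["exponential"] * 3)
        d_hat = max_pairwise_distance(f1.model, f2.model).value
        deltas = d_hat + np.array([1e-4, 5e-4, 1e-3, 2e-3])
        lls = [
            fit_constrained(g1, g2, ["exponential"] * 3, d).joint_loglik for d in deltas
        ]
        assert np.all(np.diff(lls) <= 1e-9)

    def test_invalid_delta(self):
        with pytest.raises(ValueError):
            fit_constrained(
                (np.array([1.0]), np.array([1])),
                (np.array([1.0]), np.array([1])),
                ["exponential"],
                delta=0.0,
            )


class TestSelectNullEstimates:
    @pytest.fixture
    def pieces(self):
        unc1 = fit_mle((np.full(50, 50.0), np.array([1] * 10 + [0] * 40)), ["exponential"])
        unc2 = fit_mle((np.full(50, 50.0), np.array([1] * 5 + [0] * 45)), ["exponential"])
        con = ConstrainedFitResult(unc2.model, unc2.model, -1.0, 0.0)
        return unc1, unc2, con

    def test_unconstrained_branch(self, pieces):
        unc1, unc2, con = pieces
        m1, m2 = select_null_estimates((unc1, unc2), con, d_hat=0.5, delta=0.3)
        assert m1 is unc1.model and m2 is unc2.model

    def test_constrained_branch(self, pieces):
        unc1, unc2, con = pieces
        m1, m2 = select_null_estimates((unc1, unc2), con, d_hat=0.1, delta=0.3)
        assert m1 is con.model1 and m2 is con.model2

    def test_boundary_uses_unconstrained(self, pieces):
        unc1, unc2, con = pieces
        m1, _ = select_null_estimates((unc1, unc2), con, d_hat=0.3, delta=0.3)
        assert m1 is unc1.model


class TestCensoringModel:
    def test_parse(self):
        c = CensoringModel.parse("administrative:90")
        assert c.kind == "administrative" and c.tau == 90.0
        c = CensoringModel.parse("exponential:0.001")
        assert c.kind == "random" and c.params == (0.001,)
        with pytest.raises(ValueError):
            CensoringModel.parse("uniform:1,2")

    def test_full_censoring_likelihood_closed_form(self):
        c = CensoringModel.exponential(0.01)
        # censored at 100 (density term) + event at 50 (survival term)
        ll = censoring_log_likelihood(c, (np.array([100.0, 50.0]), np.array([0, 1])))
        assert ll == pytest.approx(np.log(0.01) - 0.01 * 100 - 0.01 * 50)
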