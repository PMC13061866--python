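import math
import warnings

import numpy as np
import pandas as pd
import pytest

import relcure as rc
from relcure.cure_models import PopulationTerms, design_matrix


class TestUncuredSurvival:
    def test_weibull_shape_one_reduces_to_exponential(self):
        assert rc.uncured_survival("weibull", (1.0, 2.0), 2.0) == \
            pytest.approx(math.exp(-1.0), rel=1e-12)

    @pytest.mark.parametrize("family,theta", [
        ("exponential", (1.5,)),
        ("weibull", (1.3, 1.2)),
        ("lognormal", (0.2, 0.8)),
        ("weibull_exponential", (0.6, 1.3, 1.2, 2.0)),
        ("weibull_weibull", (0.4, 1.3, 0.8, 0.9, 3.0)),
        ("generalized_modified_weibull", (1.4, 0.5, 1.2, 0.1)),
    ])
    def test_boundary_and_monotone(self, family, theta):
        t = np.linspace(0.0, 40.0, 200)
        s = rc.uncured_survival(family, theta, t)
        assert s[0] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(s) <= 1e-12)
        assert s[-1] < 1e-3  # vanishes at long follow-up

    def test_degenerate_mixture_weight(self):
        t = np.linspace(0.1, 10.0, 25)
        mix = rc.uncured_survival("weibull_weibull", (1.0, 1.3, 1.2, 2.0, 5.0), t)
        pure = rc.uncured_survival("weibull", (1.3, 1.2), t)
        assert np.allclose(mix, pure, atol=1e-14)

    def test_domain_violation_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            rc.uncured_survival("weibull", (1.3, -1.0), 1.0)


class TestMixtureRS:
    def test_limit_is_cure_fraction(self):
        assert rc.mixture_rs(0.104, "weibull", (1.3, 1.2), 1e6) == \
            pytest.approx(0.104, abs=1e-12)

    def test_fully_cured_is_one(self):
        t = np.linspace(0, 20, 10)
        assert np.allclose(rc.mixture_rs(1.0, "exponential", (1.0,), t), 1.0)

    def test_arithmetic(self):
        # S_u = 0.5 at t = ln 2 for a unit exponential
        assert rc.mixture_rs(0.5, "exponential", (1.0,), math.log(2)) == \
            pytest.approx(0.75, rel=1e-12)


class TestLogLikelihood:
    def test_censored_subject_closed_form(self, zero_lt):
        cohort = rc.make_cohort(age=67.0, sex="male", year=2015.0,
                                time=[1.0], event=[0])
        spec = rc.CureModelSpec("exponential")
        params = rc.pack_params(spec, pi=0.5, theta=[1.0])
        ll = rc.log_likelihood(cohort, zero_lt, spec, params)
        assert ll == pytest.approx(math.log(0.5 + 0.5 * math.exp(-1)),
                                   rel=1e-12)

    def test_death_collapses_to_uncured_density(self, zero_lt):
        # with no background hazard, a death contributes ln((1-pi) f_u)
        cohort = rc.make_cohort(age=67.0, sex="male", year=2015.0,
                                time=[0.8], event=[1])
        spec = rc.CureModelSpec("weibull")
        theta = np.array([1.3, 1.2])
        params = rc.pack_params(spec, pi=0.3, theta=theta)
        ll = rc.log_likelihood(cohort, zero_lt, spec, params)
        fam = rc.get_family("weibull")
        assert ll == pytest.approx(math.log(0.7 * fam.pdf(0.8, theta)),
                                   rel=1e-10)

    def test_fully_cured_censored_cohort_is_zero(self, zero_lt):
        cohort = rc.make_cohort(age=67.0, sex="male", year=2015.0,
                                time=[1.0, 3.0, 7.0], event=[0, 0, 0])
        spec = rc.CureModelSpec("exponential")
        params = rc.pack_params(spec, pi=1.0 - 1e-12, theta=[1.0])
        assert rc.log_likelihood(cohort, zero_lt, spec, params) == \
            pytest.approx(0.0, abs=1e-9)

    def test_matches_numerical_differentiation_oracle(self, fixture_lt,
                                                      small_cohort):
        # oracle: all-cause survival S_i(t) = S_pop,i(t) * RS(t); a death
        # contributes log(-dS_i/dt) by central difference, a censoring
        # log S_i(t)
        spec = rc.CureModelSpec("weibull")
        pi, theta = 0.25, np.array([1.3, 1.4])
        params = rc.pack_params(spec, pi=pi, theta=theta)
        fam = rc.get_family("weibull")

        def all_cause_surv(row, t):
            s_pop = rc.expected_survival_individual(
                fixture_lt, row["age"], row["sex"], row["year"], t)
            return s_pop * (pi + (1 - pi) * fam.sf(t, theta))

        h = 1e-6
        oracle = 0.0
        for _, row in small_cohort.df.iterrows():
            t = row["time"]
            if row["event"] == 1:
                dens = (all_cause_surv(row, t - h) -
                        all_cause_surv(row, t + h)) / (2 * h)
                oracle += math.log(dens)
            else:
                oracle += math.log(all_cause_surv(row, t))
        ll = rc.log_likelihood(small_cohort, fixture_lt, spec, params)
        assert ll == pytest.approx(oracle, abs=1e-5)

    def test_nonfinite_contribution_names_subject(self, zero_lt):
        # death beyond any uncured support with pi -> density 0 at finite t
        cohort = rc.make_cohort(age=67.0, sex="male", year=2015.0,
                                time=[1.0], event=[1], ids=["p7"])
        spec = rc.CureModelSpec("exponential")
        params = rc.pack_params(spec, pi=1.0 - 1e-16, theta=[1e-8])
        with pytest.raises(ValueError, match="p7"):
            rc.log_likelihood(cohort, zero_lt, spec, params)


@pytest.mark.parametrize("reduced,theta_r,full,theta_f", [
    ("weibull", (1.4, 1.1), "weibull_weibull", (1.0, 1.4, 1.1, 2.0, 3.0)),
    ("exponential", (2.0,), "weibull", (1.0, 2.0)),
    ("weibull", (1.4, 2.0 ** (1 / 1.4)), "generalized_modified_weibull",
     (1.0, 0.5, 1.4, 0.0)),
    ("weibull", (1.4, 1.1), "weibull_exponential", (1.0, 1.4, 1.1, 3.0)),
])
def test_nested_family_loglik_equivalence(fixture_lt, small_cohort,
                                          reduced, theta_r, full, theta_f):
    """Families at degenerate parameter values reproduce their nested
    special case exactly, as log-likelihoods on a shared cohort."""
    pi = 0.3
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # logit(1)/log(0) at the boundary
        spec_r = rc.CureModelSpec(reduced)
        spec_f = rc.CureModelSpec(full)
        ll_r = rc.log_likelihood(small_cohort, fixture_lt, spec_r,
                                 rc.pack_params(spec_r, pi=pi, theta=theta_r))
        ll_f = rc.log_likelihood(small_cohort, fixture_lt, spec_f,
                                 rc.pack_params(spec_f, pi=pi, theta=theta_f))
    assert ll_f == pytest.approx(ll_r, abs=1e-8)


class TestFitCureModel:
    def test_refit_same_seed_is_bit_identical(self, fixture_lt):
        config = rc.SimulationConfig(n=400, seed=21, pi=0.25,
                                     year_start=2005.0, year_end=2005.0,
                                     admin_censor_year=2020.0)
        cohort, _ = rc.simulate_cohort(config, fixture_lt)
        opts = rc.FitOptions(n_starts=3, seed=5)
        f1 = rc.fit_cure_model(cohort, fixture_lt, rc.CureModelSpec("weibull"),
                               opts)
        f2 = rc.fit_cure_model(cohort, fixture_lt, rc.CureModelSpec("weibull"),
                               opts)
        assert np.array_equal(f1.params, f2.params)
        assert f1.loglik == f2.loglik

    def test_no_cure_data_pushes_pi_to_zero(self, zero_lt):
        rng = np.random.default_rng(4)
        times = 1.2 * rng.weibull(1.3, size=2000)
        cohort = rc.make_cohort(age=67.0, sex="male", year=2015.0,
                                time=np.maximum(times, 1e-4),
                                event=np.ones(2000, int))
        fit = rc.fit_cure_model(cohort, zero_lt, rc.CureModelSpec("weibull"),
                                rc.FitOptions(n_starts=4, seed=2,
                                              raise_on_failure=False))
        assert fit.pi_hat < 0.01
        assert fit.theta[0] == pytest.approx(1.3, abs=0.1)
        assert fit.theta[1] == pytest.approx(1.2, abs=0.1)

    def test_aic_identity_and_convergence_reporting(self, weibull_fit):
        assert weibull_fit.aic == pytest.approx(
            2 * weibull_fit.n_free_params - 2 * weibull_fit.loglik, rel=1e-12)
        assert weibull_fit.converged
        assert 0 < weibull_fit.pi_hat < 1
        assert weibull_fit.vcov.shape == (3, 3)
        assert np.allclose(weibull_fit.vcov, weibull_fit.vcov.T)

    def test_needs_at_least_one_event(self, fixture_lt):
        cohort = rc.make_cohort(age=67.0, sex="male", year=2015.0,
                                time=[1.0, 2.0], event=[0, 0])
        with pytest.raises(ValueError, match="death"):
            rc.fit_cure_model(cohort, fixture_lt, rc.CureModelSpec("weibull"))


def _dummy_fit(family, loglik, k, converged=True):
    spec = rc.CureModelSpec(family)
    params = np.zeros(k)
    return rc.CureModelFit(
        spec=spec, params=params, beta=np.zeros(1), theta=np.ones(k - 1),
        pi_hat=0.5, pi_ci=(0.4, 0.6), loglik=loglik,
        aic=2 * k - 2 * loglik, vcov=np.eye(k), converged=converged,
        grad_norm=0.0, n=100, events=50)


class TestSelectByAIC:
    def test_lower_aic_wins(self):
        a = _dummy_fit("weibull", -100.0, 3)       # AIC 206
        b = _dummy_fit("weibull_weibull", -99.0, 5)  # AIC 208
        assert rc.select_by_aic([a, b]) is a

    def test_tie_prefers_fewer_parameters(self):
        a = _dummy_fit("lognormal", -100.0, 3)
        b = _dummy_fit("weibull_exponential", -99.0, 4)  # same AIC 206
        assert rc.select_by_aic([b, a]) is a

    def test_single_converged_candidate_warns(self):
        a = _dummy_fit("weibull", -100.0, 3)
        b = _dummy_fit("lognormal", -90.0, 3, converged=False)
        with pytest.warns(UserWarning, match="one candidate"):
            assert rc.select_by_aic([a, b]) is a

    def test_no_converged_fits_is_hard_error(self):
        with pytest.raises(ValueError, match="converged"):
            rc.select_by_aic([_dummy_fit("weibull", -1.0, 3, converged=False)])


class TestPredictCureProbability:
    def test_binary_covariate_logistic_arithmetic(self):
        fit = _dummy_fit("weibull", -100.0, 3)
        fit = rc.CureModelFit(
            spec=rc.CureModelSpec("weibull", ("ici",)),
            params=np.array([0.0, 2.18, 0.0, 0.0]),
            beta=np.array([0.0, 2.18]), theta=np.ones(2), pi_hat=0.5,
            pi_ci=(0.4, 0.6), loglik=-1.0, aic=10.0, vcov=np.eye(4),
            converged=True, grad_norm=0.0, n=10, events=5)
        p = rc.predict_cure_probability(fit, pd.DataFrame({"ici": [1.0, 0.0]}))
        assert p[0] == pytest.approx(1 / (1 + math.exp(-2.18)), rel=1e-12)
        assert p[0] == pytest.approx(0.898, abs=5e-4)
        assert p[1] == pytest.approx(0.5)

    def test_two_covariate_linear_predictor(self):
        fit = rc.CureModelFit(
            spec=rc.CureModelSpec("weibull", ("bmi", "age65")),
            params=np.zeros(5), beta=np.array([-2.0, 0.10, -1.10]),
            theta=np.ones(2), pi_hat=0.12, pi_ci=(0.1, 0.14), loglik=-1.0,
            aic=10.0, vcov=np.eye(5), converged=True, grad_norm=0.0,
            n=10, events=5)
        x = pd.DataFrame({"bmi": [22.0], "age65": [1.0]})
        eta = -2.0 + 0.10 * 22.0 - 1.10
        assert rc.predict_cure_probability(fit, x)[0] == \
            pytest.approx(1 / (1 + math.exp(-eta)), rel=1e-12)

    def test_missing_covariate_is_hard_error(self):
        fit = rc.CureModelFit(
            spec=rc.CureModelSpec("weibull", ("bmi",)), params=np.zeros(4),
            beta=np.array([0.0, 1.0]), theta=np.ones(2), pi_hat=0.5,
            pi_ci=(0.4, 0.6), loglik=-1.0, aic=10.0, vcov=np.eye(4),
            converged=True, grad_norm=0.0, n=10, events=5)
        with pytest.raises(KeyError, match="bmi"):
            rc.predict_cure_probability(fit, pd.DataFrame({"x": [1.0]}))

    def test_no_covariates_returns_pi_hat(self, weibull_fit):
        p = rc.predict_cure_probability(weibull_fit)
        assert p[0] == weibull_fit.pi_hat


def test_design_matrix_string_encoding_is_stable():
    c1 = rc.make_cohort(age=67.0, sex=["male", "female"], year=2015.0,
                        time=[1.0, 2.0], event=[1, 0])
    X, enc = design_matrix(c1, ("sex",))
    assert enc == {"sex": "male"}
    assert list(X[:, 1]) == [1.0, 0.0]
    # a table containing only one level must reuse the learned coding
    c2 = rc.make_cohort(age=67.0, sex=["female", "female"], year=2015.0,
                        time=[1.0, 2.0], event=[1, 0])
    X2, _ = design_matrix(c2, ("sex",), encoding=enc)
    assert list(X2[:, 1]) == [0.0, 0.0]
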