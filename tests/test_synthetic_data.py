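import io
import math

import numpy as np
import pytest
from scipy import stats

import relcure as rc


class TestMakeSyntheticLifeTable:
    def test_zero_gompertz_slope_gives_constant_hazard(self):
        lt = rc.make_synthetic_life_table(a=0.01, b=0.0, c=0.09)
        ages = np.arange(lt.age_min, lt.age_max + 1, dtype=float)
        assert np.allclose(lt.hazard_at(ages, "male", 2010.0), 0.01)

    def test_default_hazard_at_67_closed_form(self):
        lt = rc.make_synthetic_life_table()
        expected = 5e-4 + 3e-5 * math.exp(0.09 * 67)
        assert lt.hazard_at(67.0, "female", 2010.0) == \
            pytest.approx(expected, rel=1e-12)

    def test_monotone_increasing_in_age(self):
        lt = rc.make_synthetic_life_table()
        ages = np.arange(lt.age_min, lt.age_max + 1, dtype=float)
        assert np.all(np.diff(lt.hazard_at(ages, "male", 2010.0)) > 0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            rc.make_synthetic_life_table(a=-1.0)

    def test_packaged_fixture_matches_generator(self):
        packaged = rc.fixture_life_table()
        fresh = rc.make_synthetic_life_table()
        ages = np.arange(packaged.age_min, packaged.age_max + 1, dtype=float)
        assert np.allclose(packaged.hazard_at(ages, "male", 2010.0),
                           fresh.hazard_at(ages, "male", 2010.0), rtol=1e-12)


class TestSamplePopulationTime:
    def test_constant_hazard_draws_are_exponential(self, const_lt):
        rng = np.random.default_rng(12)
        draws = np.array([rc.sample_population_time(const_lt, 50.0, "male",
                                                    2005.0, rng)
                          for _ in range(100000)])
        stat = stats.kstest(draws, stats.expon(scale=1 / 0.02).cdf)
        assert stat.pvalue > 0.01

    def test_zero_table_returns_infinite_sentinel(self, zero_lt):
        rng = np.random.default_rng(1)
        assert rc.sample_population_time(zero_lt, 50.0, "male", 2005.0,
                                         rng) == math.inf

    def test_fixed_seed_reproducible(self, fixture_lt):
        a = [rc.sample_population_time(fixture_lt, 67.0, "male", 2015.0,
                                       np.random.default_rng(3))
             for _ in range(2)]
        assert a[0] == a[1]


class TestSampleExcessTime:
    @pytest.mark.parametrize("family,theta,cdf", [
        ("weibull", (1.3, 1.2),
         lambda t: 1 - np.exp(-(t / 1.2) ** 1.3)),
        ("lognormal", (0.2, 0.7),
         lambda t: stats.norm.cdf((np.log(t) - 0.2) / 0.7)),
        ("weibull_weibull", (0.5, 1.3, 0.8, 1.0, 3.0),
         lambda t: 1 - 0.5 * np.exp(-(t / 0.8) ** 1.3)
         - 0.5 * np.exp(-t / 3.0)),
    ])
    def test_draws_match_target_distribution(self, family, theta, cdf):
        rng = np.random.default_rng(13)
        draws = rc.sample_excess_time(family, theta, 20000, rng)
        assert stats.kstest(draws, cdf).pvalue > 0.01

    def test_numeric_inversion_path_gmw(self):
        rng = np.random.default_rng(14)
        theta = (1.5, 0.5, 1.2, 0.1)
        draws = rc.sample_excess_time("generalized_modified_weibull", theta,
                                      2000, rng)
        fam = rc.get_family("generalized_modified_weibull")
        cdf = lambda t: 1 - fam.sf(t, np.asarray(theta))
        assert stats.kstest(draws, cdf).pvalue > 0.01


class TestSimulateCohort:
    def test_no_cure_zero_table_times_follow_excess_family(self, zero_lt):
        config = rc.SimulationConfig(n=5000, seed=15, pi=0.0,
                                     family="weibull", theta=(1.3, 1.2),
                                     year_start=2005.0, year_end=2005.0,
                                     admin_censor_year=2100.0)
        cohort, _ = rc.simulate_cohort(config, zero_lt)
        assert cohort.n_events == len(cohort)  # nothing censored
        stat = stats.kstest(cohort.df["time"],
                            lambda t: 1 - np.exp(-(t / 1.2) ** 1.3))
        assert stat.pvalue > 0.01

    def test_same_seed_gives_identical_csv_bytes(self, fixture_lt):
        config = rc.SimulationConfig(n=200, seed=16)
        out = []
        for _ in range(2):
            cohort, _ = rc.simulate_cohort(config, fixture_lt)
            buf = io.StringIO()
            cohort.df.to_csv(buf, index=False)
            out.append(buf.getvalue())
        assert out[0] == out[1]

    def test_cohort_csv_roundtrip_lossless(self, fixture_lt, tmp_path):
        config = rc.SimulationConfig(
            n=150, seed=17, dropout_rate=0.02,
            covariates={"bmi": {"kind": "normal", "mean": 22.0, "sd": 3.0},
                        "treatment": {"kind": "binary", "p": 0.14,
                                      "labels": ["CRT", "CRT_ICI"]}})
        cohort, _ = rc.simulate_cohort(config, fixture_lt)
        path = tmp_path / "cohort.csv"
        cohort.to_csv(path)
        back = rc.read_cohort(path)
        for col in cohort.df.columns:
            a, b = cohort.df[col], back.df[col]
            if a.dtype == object:
                assert (a == b).all()
            else:
                assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_empirical_cure_fraction_matches_config(self, fixture_lt):
        for seed in (1, 2, 3):
            config = rc.SimulationConfig(n=4000, seed=seed, pi=0.3,
                                         year_start=2005.0, year_end=2005.0,
                                         admin_censor_year=2035.0)
            cohort, truth = rc.simulate_cohort(config, fixture_lt)
            # survivors past the excess support are (almost all) cured
            frac_alive = float(np.mean(cohort.df["time"] > 15.0))
            s_pop15 = rc.expected_survival_individual(
                fixture_lt, 67.0, "male", 2005.0, 15.0)
            tol = 3 * math.sqrt(0.3 * 0.7 / 4000)
            assert abs(frac_alive / s_pop15 - 0.3) < tol + 0.05

    def test_covariate_driven_cure_probability(self, fixture_lt):
        config = rc.SimulationConfig(
            n=20000, seed=18, pi=None,
            cure_beta={"intercept": -2.0, "treatment": 1.5},
            year_start=2005.0, year_end=2005.0, admin_censor_year=2035.0,
            covariates={"treatment": {"kind": "binary", "p": 0.5}})
        cohort, truth = rc.simulate_cohort(config, fixture_lt)
        from scipy.special import expit
        want = 0.5 * expit(-2.0) + 0.5 * expit(-0.5)
        assert truth.mean_pi == pytest.approx(want, abs=0.01)

    def test_empirical_rs_tracks_analytic_truth(self, fixture_lt):
        config = rc.SimulationConfig(n=100000, seed=19, pi=0.104,
                                     family="weibull", theta=(1.3, 1.2),
                                     year_start=2005.0, year_end=2005.0,
                                     admin_censor_year=2016.0)
        cohort, truth = rc.simulate_cohort(config, fixture_lt)
        grid = np.arange(1, 41) / 4.0  # quarterly over (0, 10]
        rs = rc.relative_survival_curve(cohort, fixture_lt, grid)
        assert np.max(np.abs(rs.values - truth.rs(grid))) < 0.01


class TestAnalyticCurePoint:
    def test_closed_form_exponential(self, fixture_lt):
        config = rc.SimulationConfig(n=1000, seed=1, pi=0.5,
                                     family="exponential", theta=(1.0,))
        cp = rc.analytic_cure_point(config, fixture_lt,
                                    "conditional_probability", 0.75)
        assert cp == pytest.approx(math.log(3), abs=1e-6)

    def test_bisection_agrees_with_grid_search(self, fixture_lt):
        config = rc.SimulationConfig(n=1000, seed=1, pi=0.104,
                                     family="weibull", theta=(1.3, 1.2))
        cp = rc.analytic_cure_point(config, fixture_lt,
                                    "conditional_probability", 0.8)
        # brute-force grid oracle at 1e-4 resolution
        fam = rc.get_family("weibull")
        grid = np.arange(0.0, 20.0, 1e-4)
        cond = 0.104 / (0.104 + 0.896 * fam.sf(grid, np.array([1.3, 1.2])))
        oracle = grid[np.argmax(cond >= 0.8)]
        assert cp == pytest.approx(oracle, abs=2e-4)

    def test_threshold_near_one_pushes_cure_point_out(self, fixture_lt):
        config = rc.SimulationConfig(n=1000, seed=1, pi=0.3,
                                     family="weibull", theta=(1.3, 1.2))
        cps = [rc.analytic_cure_point(config, fixture_lt,
                                      "conditional_probability", thr)
               for thr in (0.8, 0.95, 0.999)]
        assert cps[0] < cps[1] < cps[2]

    def test_smr_criterion_shrinks_with_smaller_cohort(self, fixture_lt):
        big = rc.SimulationConfig(n=100000, seed=1, pi=0.104,
                                  year_start=2005.0, year_end=2005.0,
                                  admin_censor_year=2020.0)
        small = rc.SimulationConfig(n=200, seed=1, pi=0.104,
                                    year_start=2005.0, year_end=2005.0,
                                    admin_censor_year=2020.0)
        cp_big = rc.analytic_cure_point(big, fixture_lt, "smr_normalization")
        cp_small = rc.analytic_cure_point(small, fixture_lt,
                                          "smr_normalization")
        # a larger cohort detects smaller excess, so cure comes later
        assert cp_big >= cp_small

    def test_covariate_config_rejected(self, fixture_lt):
        config = rc.SimulationConfig(
            n=100, seed=1, pi=None, cure_beta={"intercept": -2.0})
        with pytest.raises(ValueError, match="no-covariate"):
            rc.analytic_cure_point(config, fixture_lt)
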