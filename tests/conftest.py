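import numpy as np
import pytest

import relcure as rc


def constant_life_table(h: float, ages=(0, 110), years=(2000, 2000)):
    """A table with the same hazard in every cell (both sexes)."""
    n_ages = ages[1] - ages[0] + 1
    n_years = years[1] - years[0] + 1
    grid = np.full((n_ages, n_years), float(h))
    return rc.LifeTable(age_min=ages[0], age_max=ages[1],
                        year_min=years[0], year_max=years[1],
                        hazard={"male": grid.copy(), "female": grid.copy()})


@pytest.fixture(scope="session")
def zero_lt():
    return constant_life_table(0.0)


@pytest.fixture(scope="session")
def const_lt():
    return constant_life_table(0.02)


@pytest.fixture(scope="session")
def fixture_lt():
    return rc.fixture_life_table()


@pytest.fixture(scope="session")
def small_cohort():
    """Eight subjects with a mix of deaths and censorings."""
    return rc.make_cohort(
        age=[62.0, 70.5, 55.0, 67.0, 80.0, 48.0, 66.0, 71.0],
        sex=["male", "female", "male", "male", "female", "female",
             "male", "male"],
        year=[2015.0, 2016.5, 2014.0, 2018.0, 2015.0, 2017.0, 2016.0, 2019.0],
        time=[0.5, 1.2, 2.7, 3.4, 0.9, 5.5, 4.1, 1.8],
        event=[1, 1, 0, 1, 1, 0, 0, 1],
    )


@pytest.fixture(scope="session")
def weibull_fit(fixture_lt):
    """A converged no-covariate Weibull cure-model fit on synthetic data."""
    config = rc.SimulationConfig(n=2000, seed=11, pi=0.2, family="weibull",
                                 theta=(1.3, 1.2), year_start=2005.0,
                                 year_end=2005.0, admin_censor_year=2020.0)
    cohort, _ = rc.simulate_cohort(config, fixture_lt)
    return rc.fit_cure_model(cohort, fixture_lt, rc.CureModelSpec("weibull"),
                             rc.FitOptions(n_starts=4, seed=11))
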