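import pytest
from hypothesis import HealthCheck, settings

import prevapc as pv

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study_grid():
    """The 12 age x 6 period study lattice (71 one-year-shifted cohorts)."""
    return pv.make_survey_grid()


@pytest.fixture(scope="session")
def full_truth(study_grid):
    """Full-scenario ground truth: all effects active, mild heterogeneity."""
    return pv.generate_truth(study_grid, scenario="full", seed=3)


@pytest.fixture(scope="session")
def full_table(full_truth):
    return pv.generate_table(full_truth, stratum_label="synthetic/full")


@pytest.fixture(scope="session")
def apc_fit(full_table, study_grid):
    """One shared APC fit on full-scenario data (reused by several tests)."""
    return pv.sample_posterior(
        full_table, study_grid, pv.APCModelSpec(),
        chains=4, iterations=600, warmup=600, seed=1,
    )


@pytest.fixture(scope="session")
def small_grid():
    """6 age groups x 4 periods (K = 34), for fast fits."""
    return pv.build_grid(range(20, 50, 5), range(2004, 2016, 3))
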