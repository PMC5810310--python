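import datetime as dt

import pytest

from nccart import (
    SamplerConfig,
    SimulationConfig,
    build_study_pool,
    generate_cohort,
    generate_session_calendar,
)


@pytest.fixture(scope="session")
def calendar():
    return generate_session_calendar(dt.date(2010, 3, 1), dt.date(2015, 12, 31))


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared by read-only tests."""
    return generate_cohort(SimulationConfig(n_patients=800, seed=11))


@pytest.fixture(scope="session")
def small_pool(small_cohort):
    return build_study_pool(small_cohort.patients, small_cohort.visits)


@pytest.fixture()
def sampler_config():
    return SamplerConfig(seed=123)
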