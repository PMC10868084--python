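import dataclasses

import pytest
from hypothesis import settings

from frailsim import load_baseline_config, load_default_registry, load_scenario
from frailsim.population import cohort_to_frame, generate_cohort

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def registry():
    return load_default_registry()


@pytest.fixture(scope="session")
def pooled_config():
    return load_baseline_config("baseline_pooled")


@pytest.fixture(scope="session")
def pooled_cohort(pooled_config):
    """The full calibration cohort (n=100,000) from the shipped baseline config."""
    return generate_cohort(pooled_config)


@pytest.fixture(scope="session")
def pooled_frame(pooled_cohort):
    return cohort_to_frame(pooled_cohort)


@pytest.fixture(scope="session")
def sexspec_frame():
    config = load_baseline_config("baseline_sex_specific")
    return cohort_to_frame(generate_cohort(config))


@pytest.fixture(scope="session")
def small_cohort(pooled_cohort):
    return pooled_cohort[:300]


@pytest.fixture(scope="session")
def rc_scenario():
    return load_scenario("scenario_recommended_care")


@pytest.fixture(scope="session")
def uc_scenario():
    return load_scenario("scenario_usual_care")


@pytest.fixture
def scenario_factory(rc_scenario):
    """Variants of the recommended-care scenario with overridden fields."""

    def make(**overrides):
        return dataclasses.replace(rc_scenario, **overrides)

    return make
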