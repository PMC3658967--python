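import numpy as np
import pytest

from clusterrisk import ScenarioConfig, generate_source_population, two_stage_sample


@pytest.fixture(scope="session")
def icc5_population():
    """One base-scenario source population (ICC 5%, 100 centers)."""
    return generate_source_population(ScenarioConfig(icc=0.05, base_seed=123))


@pytest.fixture(scope="session")
def icc5_sample(icc5_population):
    """A 20-center / 1000-patient two-stage study sample from the base population."""
    rng = np.random.default_rng(99)
    return two_stage_sample(icc5_population, 20, 1000, rng)


@pytest.fixture(scope="session")
def unclustered_sample():
    """Data generated with zero random-intercept variance: i.i.d. logistic truth."""
    return generate_source_population(
        ScenarioConfig(
            icc=0.0,
            n_source_centers=25,
            center_size_log_mean=np.log(60.0),
            center_size_log_sd=0.0,
            base_seed=7,
        )
    )
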