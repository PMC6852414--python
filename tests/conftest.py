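import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pathmed as pm

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def worked_example():
    """Ten-patient worked-example dataset with frozen step models."""
    return pm.worked_example_fixture()


@pytest.fixture(scope="session")
def small_trial():
    """Two-visit synthetic trial, n=2000, light censoring."""
    return pm.simulate_trial(pm.two_visit_config(n=2000, censor_rate=0.005), seed=3)


@pytest.fixture()
def rng():
    # fresh, fixed-seed generator per test so results do not depend on test order
    return np.random.default_rng(12345)
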