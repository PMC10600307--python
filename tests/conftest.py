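import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", max_examples=25, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_study():
    """Small but complete synthetic study shared by read-only tests."""
    from phenosel import simdata

    return simdata.scenario_default(seed=11, n_geno=60, n_markers=120,
                                    grid_points=40)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
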