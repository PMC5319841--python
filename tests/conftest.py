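import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vectorsdm.synthetic import SyntheticWorldConfig, generate_world

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_world():
    """Compact synthetic world for unit tests (32x32, 250 surveys, 4 years)."""
    cfg = SyntheticWorldConfig(
        grid_width=32, grid_height=32, n_survey_locations=250,
        cluster_count=8, cluster_spread=20.0, years=(2001, 2004), seed=42,
    )
    return generate_world(cfg)


@pytest.fixture(scope="session")
def std_world():
    """The standard study-condition world (64x64, 8 bands, 2 active)."""
    return generate_world(SyntheticWorldConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
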