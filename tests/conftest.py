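import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scenario_kwargs():
    """Reduced problem sizes for fast end-to-end pipeline tests."""
    return dict(
        n_cells_per_condition=40,
        n_tracks_per_condition=60,
        frames_per_track=60,
    )
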