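import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_subject_kwargs():
    """Scaled-down subject dimensions for fast generator-based tests."""
    return dict(n_rois=8, n_epochs=2, epoch_len=2048)
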