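import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """A small, fast stimulus spec for unit tests."""
    from facepriors import StimulusSpec

    return StimulusSpec(image_size=96, n_circles=60, face_size=48,
                        n_targets=4, n_noise=6, n_distinct_faces=3, seed=7)
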