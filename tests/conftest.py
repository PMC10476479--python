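import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import entroseg as es

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_histogram(z: int, rng: np.random.Generator, min_levels: int = 4) -> es.GrayHistogram:
    """Random sparse histogram with at least ``min_levels`` occupied levels."""
    counts = rng.integers(0, 50, size=z).astype(float)
    counts[rng.random(z) < 0.3] = 0.0
    if (counts > 0).sum() < min_levels:
        counts[:min_levels] = 1.0
    return es.GrayHistogram(counts / counts.sum(), n_pixels=int(counts.sum()))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def liver3_small():
    """64x64 three-class phantom: fast substrate for pipeline tests."""
    spec = es.preset("liver3", shape=(64, 64), seed=7)
    image, truth = es.generate_phantom(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def liver3_default():
    """The default 256x256 scene used by the recovery checks."""
    spec = es.preset("liver3", seed=11)
    image, truth = es.generate_phantom(spec)
    return spec, image, truth
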