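import numpy as np
import pytest

from usblur.psf import MotionBlurParams
from usblur.synthetic import PhantomSpec, degrade, generate_phantom


@pytest.fixture(scope="session")
def phantom():
    """The 256x256 reference phantom used across the suite (seed 7)."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def blur_pair():
    """Factory: (clean, blurred) pair for given (L, theta), cached."""
    cache = {}

    def factory(length, angle, seed=7, noise=0.0):
        key = (length, angle, seed, noise)
        if key not in cache:
            clean = generate_phantom(PhantomSpec(seed=seed))
            cache[key] = (clean, degrade(clean, MotionBlurParams(length, angle),
                                         noise_sigma=noise, seed=seed))
        return cache[key]

    return factory


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
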