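import numpy as np
import pytest

from fbfdeblur import DegradationSpec, PhantomSpec, degrade, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def chest64():
    return generate_phantom(PhantomSpec(size=64, kind="chest", seed=1))


@pytest.fixture
def small_observation(rng):
    """A 16x16 random-image observation with a 3x3 motion PSF and mild noise."""
    clean = rng.random((16, 16))
    spec = DegradationSpec(
        psf_length=3, psf_angle=30, noise_family="gaussian", noise_level=0.001, seed=7
    )
    return degrade(clean, spec)
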