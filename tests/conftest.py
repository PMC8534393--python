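import numpy as np
import pytest

from clotseg import PhantomParams, generate_phantom


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default-geometry phantom with zero noise (piecewise-constant HU)."""
    return generate_phantom(PhantomParams(noise_sd=0.0, seed=0))


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default-geometry phantom with the default 3 HU Gaussian noise."""
    return generate_phantom(PhantomParams(noise_sd=3.0, seed=42))
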