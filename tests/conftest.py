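import numpy as np
import pytest

from leafspec import generate_spectra, make_wavelength_grid


@pytest.fixture(scope="session")
def grid():
    return make_wavelength_grid()


@pytest.fixture(scope="session")
def small_dataset():
    """120 adaxial spectra with linked nutrients, the study's sample size."""
    return generate_spectra(120, "adaxial", seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
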