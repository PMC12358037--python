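import numpy as np
import pytest

from floravision import bee_context, fly_context
from floravision.grid import DEFAULT_GRID
from floravision.spectra import Spectrum


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID


@pytest.fixture(scope="session")
def bee_ctx():
    return bee_context()


@pytest.fixture(scope="session")
def fly_ctx():
    return fly_context()


@pytest.fixture
def flat_spectrum():
    def make(level: float, label: str = "flat") -> Spectrum:
        return Spectrum(DEFAULT_GRID, np.full(len(DEFAULT_GRID), float(level)), label)

    return make


@pytest.fixture
def logistic_spectrum():
    """Sigmoidal reflectance step: lo -> lo + amplitude, inflection at centre."""

    def make(centre: float, amplitude: float, lo: float = 10.0, scale: float = 8.0,
             label: str = "step") -> Spectrum:
        wl = DEFAULT_GRID.wavelengths
        refl = lo + amplitude / (1.0 + np.exp(-(wl - centre) / scale))
        return Spectrum(DEFAULT_GRID, refl, label)

    return make
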