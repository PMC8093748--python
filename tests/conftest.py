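import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from cscolor.spectra import Spectrum
from cscolor import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def flat_spectrum():
    return Spectrum([300.0, 800.0], [1.0, 1.0])


@pytest.fixture(scope="session")
def small_species():
    """A small spectral species set shared across tests (seeded)."""
    return synthetic.generate_species(synthetic.GeneratorConfig(seed=11, n_species=40))


def random_spectrum(rng, n_knots=12, lo=300.0, hi=800.0):
    """Random piecewise-linear reflectance spectrum over [lo, hi]."""
    wl = np.sort(rng.uniform(lo, hi, n_knots - 2))
    wl = np.concatenate([[lo], wl, [hi]])
    return Spectrum(wl, rng.uniform(0.0, 1.0, n_knots))
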