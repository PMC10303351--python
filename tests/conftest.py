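import numpy as np
import pytest

from fundushsi import (
    DEFAULT_CAMERA,
    DEFAULT_GRID,
    NORMAL,
    fit_spectral_basis,
    fit_transformation,
    make_color_checker,
    make_phantom_fundus,
)


@pytest.fixture(scope="session")
def camera():
    return DEFAULT_CAMERA


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID


@pytest.fixture(scope="session")
def checker(camera):
    return make_color_checker(camera, seed=1)


@pytest.fixture(scope="session")
def basis(checker):
    return fit_spectral_basis(checker.spectra, k=6)


@pytest.fixture(scope="session")
def transform(checker, basis):
    return fit_transformation(checker, basis, ridge=1e-6)


@pytest.fixture(scope="session")
def phantom_noiseless():
    """Default-geometry normal-stage phantom without pixel noise."""
    return make_phantom_fundus(stage=NORMAL, noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def phantom_noisy():
    return make_phantom_fundus(stage=NORMAL, noise_sd=0.01, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
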