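import numpy as np
import pytest

from endospec import pipeline, simulate


@pytest.fixture(scope="session")
def patchset42():
    """Default 24-patch synthetic calibration fixture, seed 42."""
    return simulate.build_calibration_fixture(seed=42)


@pytest.fixture(scope="session")
def calibration42(patchset42):
    """(model, report) from calibrating on the seed-42 fixture with defaults."""
    return pipeline.calibrate(patchset42.srgb, patchset42.spectra)


@pytest.fixture(scope="session")
def model42(calibration42):
    return calibration42[0]


@pytest.fixture(scope="session")
def report42(calibration42):
    return calibration42[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
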