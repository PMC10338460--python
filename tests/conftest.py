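import numpy as np
import pytest

from chromarl.env import ChromatographyEnv, calibrate_observation_maxima
from chromarl.params import ColumnParameters


@pytest.fixture(scope="session")
def tiny_params() -> ColumnParameters:
    """Coarse column for fast full-episode tests."""
    return ColumnParameters(N_z=6, N_r=2, N_p=3)


@pytest.fixture(scope="session")
def small_params() -> ColumnParameters:
    """Reduced column used for solver accuracy checks."""
    return ColumnParameters(N_z=8, N_r=2, N_p=3)


@pytest.fixture(scope="session")
def nominal_params() -> ColumnParameters:
    return ColumnParameters()


@pytest.fixture(scope="session")
def tiny_calibration(tiny_params) -> np.ndarray:
    """Observation normalization maxima for the tiny column (one scripted
    calibration run shared by all tests)."""
    return calibrate_observation_maxima(tiny_params)


@pytest.fixture()
def tiny_env(tiny_params, tiny_calibration) -> ChromatographyEnv:
    return ChromatographyEnv(base_params=tiny_params, randomization=None,
                             calibration=tiny_calibration)
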