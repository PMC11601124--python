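import numpy as np
import pytest

from billflex import morphometry as mo
from billflex import rigidity as rg
from billflex import synthetic as sy


@pytest.fixture(scope="session")
def template() -> sy.BillTemplate:
    return sy.default_template()


@pytest.fixture(scope="session")
def base_frame(template) -> np.ndarray:
    """Resting 63-landmark configuration of the default bill."""
    return template.resampled_frame().landmarks


@pytest.fixture(scope="session")
def identity_cal() -> rg.DensityCalibration:
    """Calibration matching the default phantom gray map, E = rho."""
    return rg.DensityCalibration(gray_slope=0.05, gray_intercept=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234567)


def hinge_landmark_index(hinge_from_base: float) -> float:
    """True culmen landmark index of a hinge (index 1 = tip)."""
    return 1.0 + (mo.N_PER_LINE - 1) * (1.0 - hinge_from_base)
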