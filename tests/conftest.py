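import numpy as np
import pytest

from acidmri.config import AcquisitionConfig, CalibrationModel
from acidmri.synthetic import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def acq() -> AcquisitionConfig:
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def cal() -> CalibrationModel:
    return CalibrationModel()


@pytest.fixture(scope="session")
def symmetric_acq() -> AcquisitionConfig:
    """Uniform symmetric offset grid, for symmetry-based checks."""
    return AcquisitionConfig(sat_offsets=np.linspace(-10.0, 10.0, 46))


@pytest.fixture(scope="session")
def small_phantom():
    """Compact noiseless-friendly phantom reused across tests."""
    spec = PhantomSpec(grid_shape=(24, 24, 6), radii=(6.0, 6.0, 2.0),
                       ph_mean=6.72, ph_sd=0.10, b0_sd=0.0, seed=11)
    return make_phantom(spec)
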