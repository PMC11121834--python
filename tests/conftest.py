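import numpy as np
import pytest

from rvquant.geometry import (
    PhantomGeometry,
    calibrate_shape,
    default_shape,
)


@pytest.fixture(scope="session")
def calibrated_shape():
    """Reference family member: alpha=0.3, q0=0.9, p0 solved for k=1.21."""
    return default_shape()


@pytest.fixture(scope="session")
def mean_phantom(calibrated_shape):
    """Phantom at the cohort-mean diastolic dimensions (D=4.2, L=7.7 cm)."""
    return PhantomGeometry(shape=calibrated_shape, D=4.2, L=7.7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240512)
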