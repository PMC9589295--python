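import numpy as np
import pytest

from sctqa.core import Geometry, VolumeGrid
from sctqa.phantom import PhantomParams, generate_patient


@pytest.fixture(scope="session")
def small_params() -> PhantomParams:
    """Coarse phantom used by most unit tests (fast to generate)."""
    return PhantomParams(shape=(48, 48, 24), spacing=(4.0, 4.0, 4.0))


@pytest.fixture(scope="session")
def case(small_params):
    return generate_patient(small_params, 42)


@pytest.fixture(scope="session")
def geometry(small_params) -> Geometry:
    return small_params.geometry


def make_volume(values, spacing=(2.0, 2.0, 2.0), unit="unitless"):
    return VolumeGrid(np.asarray(values, dtype=float), spacing, unit=unit)
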