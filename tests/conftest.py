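import numpy as np
import pytest

from iefsim.dynamics import DynamicsParams
from iefsim.geometry import CellGeometry, NuclearField, PHField


@pytest.fixture
def geometry() -> CellGeometry:
    """Reference spherical cell: 3 um nucleus inside a 5 um membrane."""
    return CellGeometry()


@pytest.fixture
def ph_linear() -> PHField:
    """Linear radial pH 7.2 (NM) -> 7.4 (CM)."""
    return PHField.linear()


@pytest.fixture
def nucleus() -> NuclearField:
    return NuclearField()


@pytest.fixture
def params() -> DynamicsParams:
    return DynamicsParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
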