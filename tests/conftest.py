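import numpy as np
import pytest

from thermoring.interactions import GeometricCriteria
from thermoring.structure import select_pathway
from thermoring.synthetic import (default_geometry_blueprint,
                                  generate_structure_fixture)


@pytest.fixture(scope="session")
def geometry_model():
    """Single-chain model with one pose per interaction class + decoys."""
    return generate_structure_fixture(default_geometry_blueprint())


@pytest.fixture(scope="session")
def geometry_blueprint():
    return default_geometry_blueprint()


@pytest.fixture(scope="session")
def geometry_selection(geometry_model):
    return select_pathway(geometry_model, "A", 1, 100)


@pytest.fixture()
def criteria():
    return GeometricCriteria()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
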