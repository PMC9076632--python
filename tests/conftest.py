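"""Shared fixtures: chromophore basis and trained inverse models.

Session-scoped because grid construction and regressor training are the
expensive steps shared by many tests.
"""

import numpy as np
import pytest
from hypothesis import settings

from skindrs import build_property_grid, load_chromophore_basis, train_inverse

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def basis():
    return load_chromophore_basis()


@pytest.fixture(scope="session")
def property_grid():
    return build_property_grid()


@pytest.fixture(scope="session")
def lookup_model(property_grid):
    return train_inverse(property_grid, "lookup_interpolation", seed=0)


@pytest.fixture(scope="session")
def regressor_model(property_grid):
    return train_inverse(property_grid, "learned_regressor", seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
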