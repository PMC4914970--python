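import math

import numpy as np
import pytest

from eghr import MixingModel, Prior, SourceSpec, make_mixing


@pytest.fixture(scope="session")
def laplace_prior() -> Prior:
    return Prior(family="laplace", gamma=100.0)


@pytest.fixture(scope="session")
def sharp_laplace() -> Prior:
    """Laplace prior with the sharp smoothing used for the quadrature identities."""
    return Prior(family="laplace", gamma=1000.0)


@pytest.fixture(scope="session")
def uniform_prior() -> Prior:
    return Prior(family="uniform")


@pytest.fixture(scope="session")
def gaussian_prior() -> Prior:
    return Prior(family="gen_gaussian", alpha=2.0, beta=0.5)


@pytest.fixture(scope="session")
def rotation_mixing() -> MixingModel:
    return make_mixing("rotation", theta=math.pi / 6)


@pytest.fixture(scope="session")
def nonrotation_mixing() -> MixingModel:
    return make_mixing("explicit", A=np.array([[1.0, 0.5], [0.5, 1.0]]))


@pytest.fixture(scope="session")
def laplace_spec() -> SourceSpec:
    return SourceSpec(family="laplace", M=2, temporal="iid")
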