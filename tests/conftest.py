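import numpy as np
import pytest

from chromokin import (
    CompositionSpec,
    ExcitonParameters,
    GeometryConfig,
    build_reference_vesicle,
    build_vesicle,
)
from chromokin.qyield import build_transfer_network


@pytest.fixture(scope="session")
def reference_vesicle():
    return build_reference_vesicle(GeometryConfig(seed=0))


@pytest.fixture(scope="session")
def reference_network(reference_vesicle):
    network, rates = build_transfer_network(reference_vesicle, ExcitonParameters())
    return network, rates


@pytest.fixture(scope="session")
def mini_vesicle():
    """Small vesicle (6 LH2 + 2 RC-LH1 dimers) for geometry-heavy tests."""
    return build_vesicle(CompositionSpec(n_bc1_dimers=1, n_l_dimers=2, n_lh2=6), GeometryConfig(seed=7))


@pytest.fixture(scope="session")
def mini_network(mini_vesicle):
    return build_transfer_network(mini_vesicle, ExcitonParameters())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
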