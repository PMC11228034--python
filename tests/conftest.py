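import numpy as np
import pytest

from calyxwire import (
    ConnectivityMatrix,
    EyeMap,
    SynapseEdge,
    WiringSpec,
    build_matrix,
    generate_wiring,
    make_hex_eye,
)


@pytest.fixture(scope="session")
def small_edges():
    return [
        SynapseEdge("A", "K1", 6),
        SynapseEdge("A", "K2", 9),
        SynapseEdge("B", "K2", 5),
        SynapseEdge("B", "K1", 4),
        SynapseEdge("C", "K3", 12),
    ]


@pytest.fixture(scope="session")
def small_matrix(small_edges):
    return build_matrix(small_edges, {"A", "B", "C"}, {"K1", "K2", "K3"}, threshold=5)


@pytest.fixture(scope="session")
def default_wiring():
    """One draw under the default study conditions (74 inputs x 147 outputs)."""
    return generate_wiring(WiringSpec(seed=1234))


@pytest.fixture(scope="session")
def hex_eye():
    """A small hex-patch eyemap for geometry tests."""
    eye = make_hex_eye(199)
    return EyeMap.from_synthetic(eye)


@pytest.fixture(scope="session")
def full_eye():
    """The default 759-column eyemap."""
    eye = make_hex_eye(759)
    return EyeMap.from_synthetic(eye)


@pytest.fixture
def rng():
    return np.random.default_rng(99)
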