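import numpy as np
import pytest

from quadconn.grid import VolumeGrid
from quadconn.network import Edge, GroundTruthNetwork, Node
from quadconn.phantom import PhantomConfig, build_masks, build_phantom, low_noise


@pytest.fixture(scope="session")
def unit_grid4():
    return VolumeGrid((4, 4, 4), (1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def small_grid():
    return VolumeGrid((16, 16, 16))


@pytest.fixture(scope="session")
def default_phantom():
    """One full default-noise phantom, shared across read-only tests."""
    return build_phantom(PhantomConfig(rng_seed=42))


@pytest.fixture(scope="session")
def quiet_phantom():
    """Low-noise phantom for tests that probe signal structure."""
    return build_phantom(low_noise(PhantomConfig(rng_seed=7)))


@pytest.fixture()
def two_node_network(small_grid):
    """Straight two-node network with an adjustable-weight bundle."""

    def make(weight: float = 0.8) -> GroundTruthNetwork:
        nodes = [Node(0, (5, 8, 8), 1), Node(1, (11, 8, 8), 1)]
        edges = []
        if weight > 0:
            bundle = np.array([[x, 8, 8] for x in range(5, 12)])
            edges = [Edge(0, 1, weight, bundle)]
        return GroundTruthNetwork(nodes, edges)

    return make


@pytest.fixture()
def two_node_masks(small_grid, two_node_network):
    net = two_node_network(0.8)
    return build_masks(net, small_grid)


def random_fod_field(grid, rng):
    """Random antipodally-symmetric normalized FOD field on a grid."""
    from quadconn.structural import OPPOSITE, FODField

    amp = rng.random(grid.shape + (26,))
    amp = amp + amp[..., OPPOSITE]
    return FODField.normalized(grid, amp)
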