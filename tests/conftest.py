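import numpy as np
import pytest

from esabo import InteractionNetwork, demo_network


@pytest.fixture(scope="session")
def demo_net():
    return demo_network()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def two_node_positive():
    return InteractionNetwork.from_edges(("a", "b"), [("a", "b")], [])


@pytest.fixture()
def two_node_negative():
    return InteractionNetwork.from_edges(("a", "b"), [], [("a", "b")])


@pytest.fixture()
def empty_network():
    def make(n):
        return InteractionNetwork(np.zeros((n, n), dtype=np.int8))

    return make
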