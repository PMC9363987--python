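import numpy as np
import pytest

from netgames.networks import SocialNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def star_network(n_leaves: int) -> SocialNetwork:
    """Node 0 is the hub connected to nodes 1..n_leaves."""
    return SocialNetwork(
        n_individuals=n_leaves + 1,
        edges=frozenset((0, j) for j in range(1, n_leaves + 1)),
    )


def path_network(n: int) -> SocialNetwork:
    return SocialNetwork(
        n_individuals=n, edges=frozenset((i, i + 1) for i in range(n - 1))
    )
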