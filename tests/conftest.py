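import numpy as np
import pytest

from mulnet.folding import assign_codes
from mulnet.phylo import parse_newick
from mulnet.simulate import random_binary_multree, random_network


@pytest.fixture
def toy_tree():
    """Two-cherry MUL-tree with a repeated-label pair at both depths."""
    return parse_newick("((x,z)u,(x,y,z)v)w;")


def trees_isomorphic(t1, t2) -> bool:
    """Topology equality via canonical isomorphism codes."""
    return assign_codes(t1)[t1.root] == assign_codes(t2)[t2.root]


def make_random_network(rng: np.random.Generator, labels, n_reticulations,
                        max_tries: int = 50):
    """random_network with retries: small trees may lack attachment edges."""
    for _ in range(max_tries):
        try:
            net = random_network(rng, labels, n_reticulations)
        except ValueError:
            continue
        if len(net.reticulations()) == n_reticulations:
            return net
    raise RuntimeError("could not generate requested network")


@pytest.fixture
def rng():
    return np.random.default_rng(20240904)


__all__ = ["trees_isomorphic", "make_random_network", "random_binary_multree"]
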