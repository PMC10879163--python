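import numpy as np
import pytest

from axoclass.reconstruction_io import parse_swc
from axoclass.synthetic_fixtures import TreeSpec, generate_tree

CHAIN_SWC = """\
# soma plus two axon points
1 1 0 0 0 1 -1
2 2 0 0 1 1 1
3 2 0 0 2 1 2
"""

# two bifurcations, 7 points, 3 leaves
BRANCHED_SWC = """\
1 1 0 0 0 1 -1
2 2 0 0 1 1 1
3 2 1 0 2 1 2
4 2 -1 0 2 1 2
5 2 1 0 3 1 3
6 2 2 0 3 1 3
7 2 -1 0 3 1 4
"""


@pytest.fixture
def chain_neuron():
    return parse_swc(CHAIN_SWC, neuron_id="chain")


@pytest.fixture
def branched_neuron():
    return parse_swc(BRANCHED_SWC, neuron_id="branched")


@pytest.fixture
def random_tree():
    return generate_tree(TreeSpec(n_bifurcations=8, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
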