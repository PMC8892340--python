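import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from coevotrait.phylo import parse_newick
from coevotrait.traits import TraitStates


@pytest.fixture
def cherry():
    return parse_newick("(A:1,B:1);")


@pytest.fixture
def quartet():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def eight_tip_tree():
    from coevotrait.simulate import simulate_tree

    return simulate_tree(8, 1.0, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_states(tree, values):
    return TraitStates(dict(zip(tree.tip_labels, values)))
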