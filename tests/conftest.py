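import numpy as np
import pytest

from drivephy.phylo import parse_newick
from drivephy.simulate import yule_tree


@pytest.fixture
def three_tip():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def four_tip():
    return parse_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")


def random_tree(n_tips, seed, depth=1.0):
    return yule_tree(n_tips, np.random.default_rng(seed), depth=depth)


def random_painting(tree, seed, alphabet=("asymmetric", "symmetric")):
    """Random two-regime tip assignment guaranteed to use both labels."""
    rng = np.random.default_rng(seed)
    labels = tree.tip_labels
    states = [alphabet[int(b)] for b in rng.integers(0, 2, len(labels))]
    states[0], states[-1] = alphabet[0], alphabet[1]
    return dict(zip(labels, states))
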