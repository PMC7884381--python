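import numpy as np
import pytest

from waldspace.forest_core import parse_newick


@pytest.fixture
def caterpillar5():
    """5-leaf tree in the standard orthant, unequal edge lengths."""
    return parse_newick("((1:0.1,2:0.2):0.15,3:0.3,(4:0.25,5:0.1):0.2);")


@pytest.fixture
def f1_tree():
    """The F1 reference tree with internal lengths 0.3 and 0.2."""
    return parse_newick("((1:0.1,2:0.1):0.3,3:0.1,(4:0.1,5:0.1):0.2);")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
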