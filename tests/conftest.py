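import numpy as np
import pytest

import mastphylo as mp


@pytest.fixture
def tree3():
    """((A:1,B:1):1,C:2); — the 3-tip workhorse with known covariance."""
    return mp.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced4():
    return mp.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def tree5():
    """Fixed ultrametric 5-tip tree used for the lambda grid-search oracle."""
    return mp.parse_newick("(((A:0.3,B:0.3):0.4,(C:0.5,D:0.5):0.2):0.3,E:1.0);")


@pytest.fixture
def trait5():
    return {"A": 1.2, "B": 0.9, "C": -0.4, "D": -0.1, "E": 0.3}


@pytest.fixture
def rng():
    return np.random.default_rng(20240709)


@pytest.fixture
def yule20():
    return mp.simulate_tree(20, seed=11)
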