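import numpy as np
import pytest

from trianiche.phylo import brownian_covariance, parse_newick
from trianiche.simulate import simulate_yule_tree


@pytest.fixture
def three_tip_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree():
    return parse_newick("(A:1,B:1,C:1,D:1);")


@pytest.fixture
def yule20():
    return simulate_yule_tree(20, birth_rate=1.0, seed=42)


@pytest.fixture
def yule20_cov(yule20):
    return brownian_covariance(yule20)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
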