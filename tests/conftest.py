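import numpy as np
import pytest

from sexconstraint import synthetic
from sexconstraint.phylo import Phylogeny


@pytest.fixture(scope="session")
def yule23():
    """A 23-tip speciational tree, the study's clade size."""
    return synthetic.gen_yule_tree(23, seed=1)


@pytest.fixture
def small_tree():
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
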