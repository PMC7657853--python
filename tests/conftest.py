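import numpy as np
import pytest

from bacushape.trees import Phylogeny


@pytest.fixture(scope="session")
def balanced8() -> Phylogeny:
    """Balanced 8-tip ultrametric tree of unit height, cherries at 0.5."""
    newick = ("(((A:0.25,B:0.25):0.25,(C:0.25,D:0.25):0.25):0.5,"
              "((E:0.25,F:0.25):0.25,(G:0.25,H:0.25):0.25):0.5);")
    return Phylogeny.from_newick(newick)


@pytest.fixture(scope="session")
def two_tip() -> Phylogeny:
    return Phylogeny.from_newick("(A:0.4,B:0.9);")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
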