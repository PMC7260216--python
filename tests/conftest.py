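import numpy as np
import pytest

from troposse.states import SSEParams, TipStateMap
from troposse.trees import PhyloTree


@pytest.fixture
def cherry():
    """Two-tip tree, both pendant edges length 1."""
    return PhyloTree.from_newick("(A:1,B:1);")


@pytest.fixture
def quartet():
    """Balanced four-tip tree, every edge length 1."""
    return PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def caterpillar3():
    """Three-tip caterpillar: pendant edges (a,b,c)=(1,1,2), internal 1."""
    return PhyloTree.from_newick("((a:1,b:1):1,c:2);")


@pytest.fixture
def five_tip():
    """Non-trivial ultrametric 5-tip fixture for likelihood oracles."""
    return PhyloTree.from_newick(
        "(((A:0.6,B:0.6):0.5,C:1.1):0.4,(D:0.9,E:0.9):0.6);")


@pytest.fixture
def params2():
    """Asymmetric two-state SSE parameters."""
    return SSEParams.from_rates([0.15, 0.25], [0.05, 0.02],
                                np.array([[0.0, 0.08], [0.12, 0.0]]))


@pytest.fixture
def states5():
    return TipStateMap({"A": 1, "B": 2, "C": 1, "D": 2, "E": 2}, 2)
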