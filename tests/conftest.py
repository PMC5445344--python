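import pytest

from saxdiv.simulate import sim_bd_tree
from saxdiv.treeio import read_newick

NEWICK_2TIP = "(A:1.0,B:1.0);"
NEWICK_3TIP = "((A:1,B:1):1,C:2);"
NEWICK_3TIP_SHORT = "((A:0.5,B:0.5):0.5,C:1.0);"


@pytest.fixture
def tree2():
    return read_newick(NEWICK_2TIP)


@pytest.fixture
def tree3():
    return read_newick(NEWICK_3TIP)


@pytest.fixture
def tree3_short():
    return read_newick(NEWICK_3TIP_SHORT)


@pytest.fixture(scope="session")
def yule50():
    """A fixed mid-sized pure-birth tree reused across tests."""
    return sim_bd_tree(0.2, 0.0, {"taxa": 50}, rng=12345)


@pytest.fixture(scope="session")
def bd10():
    """A fixed 10-tip birth-death tree for likelihood oracles."""
    return sim_bd_tree(0.3, 0.1, {"taxa": 10}, rng=777)
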