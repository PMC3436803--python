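import sys
from pathlib import Path

import networkx as nx
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture(scope="session")
def atlas():
    from egdv.atlas import build_atlas

    return build_atlas()


@pytest.fixture
def triangle():
    return nx.Graph([("a", "b"), ("b", "c"), ("c", "a")])


@pytest.fixture
def path4():
    return nx.Graph([("a", "b"), ("b", "c"), ("c", "d")])
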