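import networkx as nx
import pytest

import medianet as mn


@pytest.fixture
def star3():
    """Star K1,3: centre 0, leaves 1-3."""
    return nx.star_graph(3)


@pytest.fixture
def triangle():
    return nx.complete_graph(3)


@pytest.fixture
def mediator_motif():
    """Minimal two-step motif: h - m - d, no h-d edge."""
    return nx.Graph([("m", "h"), ("m", "d")])


@pytest.fixture(scope="session")
def paper_scale_instance():
    """One full synthetic instance at the default (real-data-like) scale."""
    return mn.generate_instance(seed=101)


@pytest.fixture(scope="session")
def small_instance():
    """A cheaper instance for pipeline-level tests."""
    return mn.generate_instance(
        num_nodes=400,
        num_edges=700,
        sizes={"H": 4, "D": 10, "O": 6},
        mediators={"HD": 5, "HO": 2, "shared": 3},
        num_terms=20,
        seed=7,
    )
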