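import networkx as nx
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def path_graph_abc():
    return nx.path_graph(["a", "b", "c"])


@pytest.fixture
def bowtie():
    """Two triangles sharing one vertex."""
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                      ("c", "d"), ("c", "e"), ("d", "e")])
    return g
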