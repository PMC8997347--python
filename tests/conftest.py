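import numpy as np
import networkx as nx
import pytest

from shapenet import (
    CoexpressionParams,
    adjacency,
    detect_modules,
    filter_genes,
    topological_overlap,
)
from shapenet.synth import SynthConfig, gen_expression


@pytest.fixture(scope="session")
def default_config() -> SynthConfig:
    return SynthConfig()


@pytest.fixture(scope="session")
def default_data(default_config):
    """Expression, shape table and ground truth at the default study scale."""
    return gen_expression(default_config)


@pytest.fixture(scope="session")
def default_log2(default_data):
    expr, _, _ = default_data
    return np.log2(filter_genes(expr, None, 1.0))


@pytest.fixture(scope="session")
def default_modules(default_log2):
    adj = adjacency(default_log2, 9)
    tom = topological_overlap(adj)
    return detect_modules(1 - tom, default_log2, CoexpressionParams())


@pytest.fixture()
def toy_network() -> nx.DiGraph:
    """Five-protein signed toy network used by influence/flow tests."""
    net = nx.DiGraph()
    edges = [("a", "b", 1), ("b", "c", 1), ("c", "d", -1),
             ("d", "e", 1), ("a", "c", 1)]
    for s, t, sign in edges:
        net.add_edge(s, t, sign=sign, weight=1.0, similarity=1.0,
                     origin="pcsf")
    for v in net.nodes():
        net.nodes[v]["kind"] = "protein"
    return net
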