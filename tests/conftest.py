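import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from comboreg import (RegressionConfig, SyntheticScenario, generate_expression,
                      generate_scenario, infer_network)


@pytest.fixture(scope="session")
def default_scenario():
    return SyntheticScenario(seed=3)


@pytest.fixture(scope="session")
def default_data(default_scenario):
    return generate_scenario(default_scenario)


@pytest.fixture(scope="session")
def default_matrices(default_data):
    return generate_expression(default_data)


@pytest.fixture(scope="session")
def inferred_network(default_scenario, default_data, default_matrices):
    mirna, mrna = default_matrices
    return infer_network(mirna, mrna, default_data.candidates,
                         default_scenario.tf_ids, RegressionConfig())


def random_digraph(rng: np.random.Generator, n: int, p: float = 0.4) -> nx.DiGraph:
    """Erdős–Rényi-style digraph (no self-loops) for oracle comparisons."""
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for u in range(n):
        for v in range(n):
            if u != v and rng.random() < p:
                g.add_edge(u, v)
    return g
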