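import networkx as nx
import numpy as np
import pandas as pd
import pytest

import seasonet as sn


@pytest.fixture(scope="session")
def barbell_triangles() -> nx.Graph:
    """Two triangles joined by a single bridge edge (7 edges, 6 nodes)."""
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                      ("d", "e"), ("e", "f"), ("d", "f"),
                      ("c", "d")])
    return g


@pytest.fixture(scope="session")
def small_dataset():
    """One default simulated dataset (seed 0) shared across tests."""
    cfg = sn.SimulationConfig(rng_seed=0)
    return cfg, sn.simulate_dataset(cfg)


@pytest.fixture()
def random_graph_factory():
    def make(seed: int, n: int = 20, p: float = 0.2, weighted: bool = False) -> nx.Graph:
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if weighted:
            for u, v in g.edges():
                g.edges[u, v]["weight"] = float(rng.uniform(0.1, 1.0))
        return g
    return make


@pytest.fixture()
def monthly_matrix():
    """12-month matrix of a few well-behaved variables."""
    rng = np.random.default_rng(42)
    df = pd.DataFrame(rng.lognormal(mean=2.0, sigma=0.4, size=(12, 6)),
                      index=list(sn.MONTHS),
                      columns=[f"met_{i}" for i in range(6)])
    return df
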