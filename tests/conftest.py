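import numpy as np
import pandas as pd
import pytest

import pynetgsa as pg


def make_adjacency(p, edges, genes=None, directed=False):
    """0/1 adjacency from an explicit edge list of index pairs."""
    genes = pd.Index(genes if genes is not None else [f"g{i}" for i in range(p)])
    m = np.zeros((p, p), dtype=np.int8)
    for i, j in edges:
        m[i, j] = 1
        if not directed:
            m[j, i] = 1
    return pg.BinaryAdjacency(m, genes, directed=directed)


def barbell_edges(k=20):
    """Two k-cliques joined by a single bridge; returns (p, edge list)."""
    edges = []
    for block in (0, k):
        for i in range(k):
            for j in range(i + 1, k):
                edges.append((block + i, block + j))
    edges.append((k - 1, k))  # bridge
    return 2 * k, edges


@pytest.fixture
def barbell():
    p, edges = barbell_edges(20)
    return make_adjacency(p, edges)


@pytest.fixture(scope="session")
def fixture_50():
    """A seeded 50-gene two-condition dataset with its network and pathways."""
    design = pg.SimulationDesign(
        p=50, n_components=2, n_pathways=6, pathway_size_range=(4, 12),
        edge_density=0.12, seed=42,
    )
    adj, adjset = pg.generate_network(design)
    pathways = pg.generate_pathways(design)
    data = pg.generate_expression(
        adjset, None, design.sigma2_g, design.sigma2_e,
        {"cond1": 40, "cond2": 40}, seed=43,
    )
    return design, adj, adjset, pathways, data
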