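import numpy as np
import pytest

from csgdn.graph import GeneSimilarity, SignedBipartiteGraph


@pytest.fixture
def toy_graph():
    """2 genes, 1 phenotype: (g1,p1,+), (g2,p1,-)."""
    return SignedBipartiteGraph(["g1", "g2"], ["p1"], [(0, 0, 1), (1, 0, -1)])


@pytest.fixture
def toy_similarity():
    return GeneSimilarity(np.array([[1.0, 0.5], [0.5, 1.0]]), ["g1", "g2"])


def random_signed_graph(rng, n_genes=None, n_phenotypes=None, density=0.5):
    """A random signed bipartite graph for property tests."""
    n_genes = n_genes or int(rng.integers(2, 8))
    n_phenotypes = n_phenotypes or int(rng.integers(1, 5))
    edges = []
    for g in range(n_genes):
        for p in range(n_phenotypes):
            if rng.uniform() < density:
                edges.append((g, p, 1 if rng.uniform() < 0.5 else -1))
    return SignedBipartiteGraph(
        [f"g{i}" for i in range(n_genes)],
        [f"p{j}" for j in range(n_phenotypes)],
        edges,
    )
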