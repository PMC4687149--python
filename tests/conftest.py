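"""Shared fixtures: small genotype datasets and graph builders."""

import networkx as nx
import numpy as np
import pytest

from sennet.datatypes import EpistasisNetwork, GenotypeDataset


@pytest.fixture
def rng():
    return np.random.default_rng(2015062)


def make_dataset(genotypes, phenotype, snp_prefix="snp"):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    m, n = genotypes.shape
    return GenotypeDataset(
        snp_ids=[f"{snp_prefix}{i}" for i in range(m)],
        sample_ids=[f"s{j}" for j in range(n)],
        genotypes=genotypes,
        phenotype=np.asarray(phenotype, dtype=np.uint8),
    )


@pytest.fixture
def random_dataset_factory(rng):
    """Phenotype-independent genotype datasets of a given size."""

    def build(n_snps=10, n_samples=120, missing_rate=0.0, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        g = r.integers(0, 3, size=(n_snps, n_samples)).astype(np.int8)
        if missing_rate > 0:
            g[r.random(g.shape) < missing_rate] = -1
        pheno = r.integers(0, 2, size=n_samples).astype(np.uint8)
        return make_dataset(g, pheno)

    return build


def gene_level_network(edges, extra_nodes=()):
    g = nx.Graph()
    g.add_edges_from(edges)
    g.add_nodes_from(extra_nodes)
    return EpistasisNetwork(graph=g, level="gene")


def build_gene_edges_185() -> list[tuple[int, int]]:
    """173 distinct inter-gene edges over 185 genes with no isolated gene,
    25 connected components and a giant component of 134 (the published
    shape; the topology itself is synthetic).

    Giant: a random tree on genes 0..133 plus 13 extra edges (146 edges).
    Then 21 two-gene components and 3 three-gene paths (27 edges).
    """
    r = np.random.default_rng(185174)
    edges: set[tuple[int, int]] = set()
    for k in range(1, 134):
        edges.add((int(r.integers(0, k)), k))
    while len(edges) < 146:
        i, j = sorted(r.integers(0, 134, size=2).tolist())
        if i != j:
            edges.add((i, j))
    node = 134
    for _ in range(21):  # two-gene components
        edges.add((node, node + 1))
        node += 2
    for _ in range(3):  # three-gene paths
        edges.add((node, node + 1))
        edges.add((node + 1, node + 2))
        node += 3
    assert node == 185 and len(edges) == 173
    return sorted(edges)


@pytest.fixture
def published_shape_gene_network():
    """Gene network with the published shape: 185 vertices, 174 edges
    including 1 self-loop, 25 components, giant component of 134."""
    nodes = [f"gene{i:03d}" for i in range(185)]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from((nodes[i], nodes[j]) for i, j in build_gene_edges_185())
    g.add_edge(nodes[0], nodes[0])  # the self-loop
    return EpistasisNetwork(graph=g, level="gene")
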