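"""Core containers shared across the pipeline.

Genotypes are stored as an int8 SNP x sample matrix over {0, 1, 2} with -1
marking a missing call. The phenotype is a per-sample 0/1 class label
(1 = case). Networks are thin wrappers around :class:`networkx.Graph` that
carry the level of the vertices (``"snp"`` or ``"gene"``); self-loops are
only meaningful at the gene level, where a within-gene SNP interaction
collapses onto a single vertex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

MISSING: int = -1
GENOTYPE_LEVELS: tuple[int, ...] = (0, 1, 2)


@dataclass
class GenotypeDataset:
    """A case-control genotype matrix with SNP and sample identities."""

    snp_ids: list[str]
    sample_ids: list[str]
    genotypes: np.ndarray  # shape (n_snps, n_samples), int8, -1 = missing
    phenotype: np.ndarray  # shape (n_samples,), values in {0, 1}

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.uint8)
        n_snps, n_samples = self.genotypes.shape
        if len(self.snp_ids) != n_snps:
            raise ValueError("snp_ids length does not match genotype rows")
        if len(self.sample_ids) != n_samples:
            raise ValueError("sample_ids length does not match genotype columns")
        if self.phenotype.shape != (n_samples,):
            raise ValueError("phenotype length does not match sample count")
        allowed = set(GENOTYPE_LEVELS) | {MISSING}
        observed = set(np.unique(self.genotypes).tolist())
        if not observed <= allowed:
            raise ValueError(f"genotype values outside {sorted(allowed)}: {observed - allowed}")
        if not set(np.unique(self.phenotype).tolist()) <= {0, 1}:
            raise ValueError("phenotype must be binary 0/1")

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    def missing_fraction(self) -> np.ndarray:
        """Per-SNP fraction of missing calls."""
        return (self.genotypes == MISSING).mean(axis=1)

    def has_missing(self) -> bool:
        return bool((self.genotypes == MISSING).any())


@dataclass
class InteractionScores:
    """Pairwise information-gain scores and per-SNP main effects, in bits."""

    snp_ids: list[str]
    main_effect: np.ndarray  # shape (n_snps,), I(SNP; phenotype)
    ig: np.ndarray  # shape (n_snps, n_snps), symmetric, diagonal unused

    def __post_init__(self) -> None:
        self.main_effect = np.asarray(self.main_effect, dtype=float)
        self.ig = np.asarray(self.ig, dtype=float)
        m = len(self.snp_ids)
        if self.main_effect.shape != (m,):
            raise ValueError("main_effect shape mismatch")
        if self.ig.shape != (m, m):
            raise ValueError("ig matrix shape mismatch")
        if not np.allclose(self.ig, self.ig.T, atol=1e-12, equal_nan=True):
            raise ValueError("ig matrix must be symmetric")

    def pair_values(self) -> np.ndarray:
        """Upper-triangle IG values (each unordered pair once)."""
        iu = np.triu_indices(len(self.snp_ids), k=1)
        return self.ig[iu]


@dataclass
class EpistasisNetwork:
    """An undirected interaction network at SNP or gene level."""

    graph: nx.Graph
    level: str = "snp"

    def __post_init__(self) -> None:
        if self.level not in ("snp", "gene"):
            raise ValueError("level must be 'snp' or 'gene'")
        if self.level == "snp" and any(u == v for u, v in self.graph.edges):
            raise ValueError("self-loops are not allowed in a SNP-level network")

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_self_loops(self) -> int:
        return sum(1 for u, v in self.graph.edges if u == v)

    def vertices(self) -> list:
        return list(self.graph.nodes)


@dataclass
class NetworkSummary:
    """Global topology descriptors used for permutation comparison.

    ``degree_sequence`` counts distinct neighbors per vertex; a self-loop
    does not make a vertex its own neighbor.
    """

    n_vertices: int
    n_edges: int
    giant_component_size: int
    degree_sequence: tuple[int, ...]
    n_components: int

    @property
    def mean_neighbors(self) -> float:
        if self.n_vertices == 0:
            return 0.0
        return float(np.mean(self.degree_sequence))


@dataclass
class DyadCounts:
    """Observed dyad census of a binary vertex property.

    N is the vertex count, M the number of non-self-loop edges, n1 the
    number of vertices with property value 1. m11/m10/m00 classify each
    non-self edge by its endpoint values; self-loops never enter the census.
    """

    N: int
    M: int
    n1: int
    m11: int
    m10: int
    m00: int

    def __post_init__(self) -> None:
        if min(self.N, self.M, self.n1, self.m11, self.m10, self.m00) < 0:
            raise ValueError("dyad counts must be non-negative")
        if self.n1 > self.N:
            raise ValueError("n1 cannot exceed N")
        if self.m11 + self.m10 + self.m00 != self.M:
            raise ValueError("m11 + m10 + m00 must equal M")

    @property
    def n0(self) -> int:
        return self.N - self.n1


@dataclass
class DHResult:
    """Dyadicity/heterophilicity of one category: the result-table row."""

    category: str
    counts: DyadCounts
    m11_expected: float
    m10_expected: float
    D: float | None
    H: float | None
    p_D: float | None
    p_H: float | None
    n_perms: int


# A SNP -> gene map is a plain mapping; categories map name -> member gene set.
SnpGeneMap = Mapping[str, str]
CategoryAssignment = Mapping[str, set]


def make_snp_ids(n: int) -> list[str]:
    return [f"snp{i + 1:04d}" for i in range(n)]


def make_sample_ids(n: int) -> list[str]:
    return [f"s{i + 1:04d}" for i in range(n)]


def make_gene_ids(n: int) -> list[str]:
    return [f"gene{i + 1:03d}" for i in range(n)]
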