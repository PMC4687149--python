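"""Statistical epistasis network (SEN) construction and permutation-based
threshold selection.

A SEN is built by connecting SNP pairs whose information gain strictly
exceeds a threshold; SNPs incident to no retained edge are dropped, so the
network's vertex set is the edge-incident SNPs. The threshold is chosen by
comparing the real network's topology against networks built from
phenotype-permuted data at the same threshold: a grid of candidate
thresholds is scanned and the one maximizing the standardized excess
(z-score) of the real giant connected component over the permuted null is
selected. Degree-distribution comparisons are carried along as diagnostics.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import EpistasisNetwork, GenotypeDataset, InteractionScores, NetworkSummary
from .info_theory import _pair_ig_matrix

__all__ = [
    "build_network",
    "summarize",
    "null_network_summaries",
    "select_threshold",
]

logger = logging.getLogger(__name__)


def build_network(scores: InteractionScores, threshold: float, level: str = "snp") -> EpistasisNetwork:
    """Connect every SNP pair with IG strictly above the threshold.

    Vertices are the SNPs incident to at least one retained edge; isolated
    SNPs do not appear. Edges carry the IG value as a ``weight`` attribute.
    """
    if not np.isfinite(threshold) and threshold > 0:
        raise ValueError("threshold must be finite or -inf")
    graph = nx.Graph()
    m = len(scores.snp_ids)
    iu, ju = np.triu_indices(m, k=1)
    above = scores.ig[iu, ju] > threshold
    for i, j in zip(iu[above], ju[above]):
        graph.add_edge(scores.snp_ids[i], scores.snp_ids[j], weight=float(scores.ig[i, j]))
    return EpistasisNetwork(graph=graph, level=level)


def _as_graph(network) -> nx.Graph:
    return network.graph if isinstance(network, EpistasisNetwork) else network


def summarize(network) -> NetworkSummary:
    """Global topology: size, giant component, neighbor-degree sequence.

    Degree counts distinct neighbors, so a self-loop adds nothing to its
    vertex's degree; self-loops also never join components.
    """
    g = _as_graph(network)
    if g.number_of_nodes() == 0:
        return NetworkSummary(0, 0, 0, (), 0)
    components = list(nx.connected_components(g))
    degrees = tuple(sorted(len([u for u in g[v] if u != v]) for v in g.nodes))
    return NetworkSummary(
        n_vertices=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        giant_component_size=max(len(c) for c in components),
        degree_sequence=degrees,
        n_components=len(components),
    )


def null_network_summaries(
    dataset: GenotypeDataset, threshold: float, n_perms: int, seed: int = 0
) -> list[NetworkSummary]:
    """Topology of networks built from phenotype-permuted data.

    Each replicate shuffles the phenotype labels uniformly (preserving the
    case/control totals), rescores all pairs, thresholds, and summarizes.
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    if dataset.has_missing():
        raise ValueError("impute missing genotypes before permutation testing")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_perms):
        perm_pheno = rng.permutation(dataset.phenotype)
        _, ig = _pair_ig_matrix(dataset.genotypes, perm_pheno)
        scores = InteractionScores(snp_ids=list(dataset.snp_ids), main_effect=np.zeros(dataset.n_snps), ig=ig)
        out.append(summarize(build_network(scores, threshold)))
    return out


def default_threshold_grid(scores: InteractionScores, n_points: int = 50) -> np.ndarray:
    """Candidate thresholds: evenly spaced quantiles of the upper decile
    of the observed pairwise IG distribution."""
    vals = scores.pair_values()
    qs = 0.9 + 0.1 * np.arange(n_points) / n_points
    return np.unique(np.quantile(vals, qs))


def select_threshold(
    dataset: GenotypeDataset,
    threshold_grid=None,
    n_perms: int = 20,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Pick the IG threshold whose real network is most unlike its null.

    For each grid threshold the selection statistic is
    z = (giant_real - mean(giant_null)) / sd(giant_null). Null IG matrices
    are computed once (one all-pairs rescoring per phenotype permutation)
    and re-thresholded along the grid. Grid points with degenerate null
    variance are skipped with a warning. Returns the selected threshold and
    a per-threshold diagnostics table (real and null summaries).
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    if dataset.has_missing():
        raise ValueError("impute missing genotypes before threshold selection")
    real_main, real_ig = _pair_ig_matrix(dataset.genotypes, dataset.phenotype)
    scores = InteractionScores(snp_ids=list(dataset.snp_ids), main_effect=real_main, ig=real_ig)
    if threshold_grid is None:
        threshold_grid = default_threshold_grid(scores)
    grid = np.asarray(list(threshold_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid is empty")

    rng = np.random.default_rng(seed)
    null_igs = []
    for _ in range(n_perms):
        perm_pheno = rng.permutation(dataset.phenotype)
        _, ig = _pair_ig_matrix(dataset.genotypes, perm_pheno)
        null_igs.append(ig)

    rows = []
    for t in grid:
        real = summarize(build_network(scores, t))
        null_giants = []
        for ig in null_igs:
            ns = InteractionScores(
                snp_ids=list(dataset.snp_ids), main_effect=np.zeros(dataset.n_snps), ig=ig
            )
            null_giants.append(summarize(build_network(ns, t)).giant_component_size)
        null_giants = np.asarray(null_giants, dtype=float)
        std = float(null_giants.std(ddof=1)) if n_perms > 1 else 0.0
        if std == 0.0:
            logger.warning("degenerate null variance at threshold %.6g; grid point skipped", t)
            z = np.nan
        else:
            z = (real.giant_component_size - null_giants.mean()) / std
        rows.append(
            {
                "threshold": float(t),
                "n_vertices": real.n_vertices,
                "n_edges": real.n_edges,
                "giant_real": real.giant_component_size,
                "null_giant_mean": float(null_giants.mean()),
                "null_giant_std": std,
                "z": z,
            }
        )
    diag = pd.DataFrame(rows)
    if diag["z"].notna().any():
        best = diag.loc[diag["z"].idxmax(), "threshold"]
    else:
        # every grid point degenerate: fall back to the largest raw excess
        best = diag.loc[(diag["giant_real"] - diag["null_giant_mean"]).idxmax(), "threshold"]
        logger.warning("all grid points had degenerate null variance; using raw excess")
    return float(best), diag
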