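"""Collapse a SNP-level epistasis network to a gene-level network.

Two genes are connected if at least one SNP pair, one SNP from each gene,
is connected at the SNP level; a SNP edge within a single gene becomes a
self-loop on that gene. Gene edges are unweighted and deduplicated — the
number of underlying SNP edges is kept as an edge attribute
``multiplicity``.
"""

from __future__ import annotations

from typing import Mapping

import networkx as nx

from .datatypes import EpistasisNetwork, NetworkSummary
from .network import summarize

__all__ = ["collapse", "component_stats"]


def collapse(snp_network: EpistasisNetwork, snp_gene_map: Mapping[str, str]) -> EpistasisNetwork:
    """Map SNP vertices through the SNP->gene assignment and merge edges.

    Every SNP vertex must be covered by the map; an unmapped SNP raises
    with its identifier. Vertices of the result are the image of the SNP
    vertex set, so genes whose SNPs are all isolated do not appear (the
    SNP network itself excludes isolated SNPs).
    """
    g = snp_network.graph
    for snp in g.nodes:
        if snp not in snp_gene_map:
            raise KeyError(f"SNP {snp!r} has no gene assignment")
    gene_graph = nx.Graph()
    gene_graph.add_nodes_from({snp_gene_map[s] for s in g.nodes})
    for u, v in g.edges:
        a, b = snp_gene_map[u], snp_gene_map[v]
        if gene_graph.has_edge(a, b):
            gene_graph[a][b]["multiplicity"] += 1
        else:
            gene_graph.add_edge(a, b, multiplicity=1)
    for gene in gene_graph.nodes:
        gene_graph.nodes[gene]["gene_id"] = gene
    return EpistasisNetwork(graph=gene_graph, level="gene")


def component_stats(gene_network: EpistasisNetwork) -> NetworkSummary:
    """Connected-component and degree summary of a gene network.

    Self-loops are kept in the edge inventory but never connect
    components and never count toward a vertex's neighbor degree.
    """
    return summarize(gene_network)
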