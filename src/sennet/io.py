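"""Readers and writers for the pipeline's plain-text formats.

Genotypes: tab-separated, one row per SNP, header of sample IDs, first
column the SNP ID, missing calls written ``NA``. Phenotype: two-column TSV
(sample ID, 0/1) with header. SNP->gene map: two-column TSV. Categories:
GMT (name, description, tab-separated member genes). Networks: GraphML
(round-trippable), SIF and edge-list TSV (export only, Cytoscape-friendly).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    DHResult,
    EpistasisNetwork,
    GenotypeDataset,
    InteractionScores,
)

__all__ = [
    "write_genotypes",
    "read_genotypes",
    "write_snp_gene_map",
    "read_snp_gene_map",
    "write_gmt",
    "read_gmt",
    "write_network",
    "read_network",
    "write_sif",
    "write_edge_list",
    "write_scores",
    "results_to_frame",
    "write_dh_results",
]


def write_genotypes(dataset: GenotypeDataset, genotype_path, phenotype_path) -> None:
    G = dataset.genotypes.astype(object)
    G[G == MISSING] = "NA"
    frame = pd.DataFrame(G, index=dataset.snp_ids, columns=dataset.sample_ids)
    frame.index.name = "snp_id"
    frame.to_csv(genotype_path, sep="\t")
    pheno = pd.DataFrame({"sample_id": dataset.sample_ids, "phenotype": dataset.phenotype})
    pheno.to_csv(phenotype_path, sep="\t", index=False)


def read_genotypes(genotype_path, phenotype_path) -> GenotypeDataset:
    frame = pd.read_csv(genotype_path, sep="\t", index_col=0, dtype=str, na_filter=False)
    geno = frame.replace("NA", str(MISSING)).astype(np.int8).to_numpy()
    pheno = pd.read_csv(phenotype_path, sep="\t", dtype={"sample_id": str, "phenotype": np.uint8})
    order = {s: k for k, s in enumerate(pheno["sample_id"])}
    cols = list(frame.columns)
    if set(cols) != set(order):
        raise ValueError("genotype and phenotype files describe different samples")
    phenotype = pheno["phenotype"].to_numpy()[np.array([order[c] for c in cols])]
    return GenotypeDataset(
        snp_ids=list(frame.index),
        sample_ids=cols,
        genotypes=geno,
        phenotype=phenotype,
    )


def write_snp_gene_map(mapping: Mapping[str, str], path) -> None:
    pd.DataFrame(sorted(mapping.items()), columns=["snp_id", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_snp_gene_map(path) -> dict[str, str]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if list(frame.columns[:2]) != ["snp_id", "gene_id"]:
        raise ValueError(f"{path}: expected columns snp_id, gene_id")
    return dict(zip(frame["snp_id"], frame["gene_id"]))


def write_gmt(categories: Mapping[str, Iterable[str]], path, descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in categories.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_gmt(path) -> dict[str, set]:
    categories: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description and >=1 gene")
            categories[fields[0]] = set(fields[2:])
    return categories


def write_network(network: EpistasisNetwork, path) -> None:
    g = network.graph.copy()
    g.graph["level"] = network.level
    nx.write_graphml(g, path)


def read_network(path) -> EpistasisNetwork:
    g = nx.read_graphml(path)
    level = g.graph.get("level", "gene")
    return EpistasisNetwork(graph=nx.Graph(g), level=level)


def write_sif(network: EpistasisNetwork, path, interaction: str = "ig") -> None:
    with open(path, "w") as fh:
        isolated = [v for v in network.graph.nodes if network.graph.degree(v) == 0]
        for u, v in network.graph.edges:
            fh.write(f"{u}\t{interaction}\t{v}\n")
        for v in isolated:
            fh.write(f"{v}\n")


def write_edge_list(network: EpistasisNetwork, path, weight_attr: str = "weight") -> None:
    rows = []
    for u, v, data in network.graph.edges(data=True):
        row = {"source": u, "target": v}
        if weight_attr in data:
            row[weight_attr] = data[weight_attr]
        if "multiplicity" in data:
            row["multiplicity"] = data["multiplicity"]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_scores(scores: InteractionScores, pair_path, main_path) -> None:
    """Three-column pair TSV (snp_i, snp_j, ig_bits) and per-SNP main effects."""
    m = len(scores.snp_ids)
    iu, ju = np.triu_indices(m, k=1)
    pd.DataFrame(
        {
            "snp_i": [scores.snp_ids[i] for i in iu],
            "snp_j": [scores.snp_ids[j] for j in ju],
            "ig_bits": scores.ig[iu, ju],
        }
    ).to_csv(pair_path, sep="\t", index=False)
    pd.DataFrame({"snp_id": scores.snp_ids, "mi_bits": scores.main_effect}).to_csv(
        main_path, sep="\t", index=False
    )


_RESULT_COLUMNS = [
    "term",
    "n1",
    "m11",
    "m10",
    "m11_expected",
    "m10_expected",
    "D",
    "H",
    "p_D",
    "p_H",
    "n_perms",
]


def results_to_frame(results: list[DHResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "term": r.category,
                "n1": r.counts.n1,
                "m11": r.counts.m11,
                "m10": r.counts.m10,
                "m11_expected": r.m11_expected,
                "m10_expected": r.m10_expected,
                "D": r.D,
                "H": r.H,
                "p_D": r.p_D,
                "p_H": r.p_H,
                "n_perms": r.n_perms,
            }
        )
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS)


def write_dh_results(results: list[DHResult], path, full_path=None) -> None:
    """Rounded (3 d.p.) report TSV; optionally a full-precision companion."""
    frame = results_to_frame(results)
    if full_path is not None:
        frame.to_csv(full_path, sep="\t", index=False)
    rounded = frame.copy()
    for col in ["m11_expected", "m10_expected", "D", "H", "p_D", "p_H"]:
        rounded[col] = rounded[col].map(lambda v: "" if v is None or pd.isna(v) else f"{v:.3f}")
    rounded.to_csv(path, sep="\t", index=False)
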