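"""End-to-end orchestration: preprocessing, pair scoring, threshold
selection, network construction, gene collapse, and category analysis.

All randomness (phenotype permutations for threshold selection, label
permutations for D/H significance) flows from the single master seed in
the config. Every stage's artifacts are written under the output
directory and every parameter is logged.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import genes, io, network
from .dyadicity import analyze_categories
from .info_theory import all_pairs_ig, filter_missingness, impute_mode

__all__ = ["PipelineConfig", "run_all", "run_dh_only"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, parameters and seeds for a full run."""

    genotypes: str
    phenotype: str
    snp_gene_map: str
    categories: str
    outdir: str
    max_missing: float = 0.05
    threshold: float | None = None  # fixed IG threshold; None => grid selection
    threshold_grid: list[float] | None = None
    n_perms_threshold: int = 20
    n_perms_dh: int = 100_000
    min_category_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.max_missing < 1:
            raise ValueError("max_missing must be in [0, 1)")
        if self.n_perms_threshold < 1 or self.n_perms_dh < 1:
            raise ValueError("permutation counts must be positive")
        if self.min_category_size < 1:
            raise ValueError("min_category_size must be >= 1")

    def validate_paths(self) -> None:
        for name in ("genotypes", "phenotype", "snp_gene_map", "categories"):
            path = Path(getattr(self, name))
            if not path.exists():
                raise FileNotFoundError(f"config input {name!r}: {path} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def run_all(config: PipelineConfig) -> dict:
    """Execute filter -> impute -> score -> threshold -> network ->
    collapse -> category D/H, writing all intermediate artifacts.

    Inputs are validated before any output is created; any stage error
    aborts the run with the stage named in the exception.
    """
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline config: %s", dataclasses.asdict(config))

    stage = "load"
    try:
        dataset = io.read_genotypes(config.genotypes, config.phenotype)
        snp_gene_map = io.read_snp_gene_map(config.snp_gene_map)
        categories = io.read_gmt(config.categories)

        stage = "filter_missingness"
        dataset = filter_missingness(dataset, config.max_missing)
        logger.info("%d SNPs retained after missingness filter", dataset.n_snps)

        stage = "impute_mode"
        dataset = impute_mode(dataset)

        stage = "all_pairs_ig"
        scores = all_pairs_ig(dataset)
        io.write_scores(scores, outdir / "pair_ig.tsv", outdir / "main_effects.tsv")

        stage = "select_threshold"
        if config.threshold is not None:
            threshold = float(config.threshold)
            diagnostics = None
            logger.info("using fixed IG threshold %.6g", threshold)
        else:
            threshold, diagnostics = network.select_threshold(
                dataset,
                threshold_grid=config.threshold_grid,
                n_perms=config.n_perms_threshold,
                seed=config.seed,
            )
            diagnostics.to_csv(outdir / "threshold_diagnostics.tsv", sep="\t", index=False)
            logger.info("selected IG threshold %.6g", threshold)

        stage = "build_network"
        snp_net = network.build_network(scores, threshold)
        io.write_network(snp_net, outdir / "snp_network.graphml")
        io.write_sif(snp_net, outdir / "snp_network.sif")
        io.write_edge_list(snp_net, outdir / "snp_network_edges.tsv")

        stage = "collapse"
        gene_net = genes.collapse(snp_net, snp_gene_map)
        io.write_network(gene_net, outdir / "gene_network.graphml")
        io.write_sif(gene_net, outdir / "gene_network.sif")
        io.write_edge_list(gene_net, outdir / "gene_network_edges.tsv")
        summary = genes.component_stats(gene_net)
        logger.info(
            "gene network: %d vertices, %d edges, giant component %d",
            summary.n_vertices,
            summary.n_edges,
            summary.giant_component_size,
        )

        stage = "analyze_categories"
        results = analyze_categories(
            gene_net,
            categories,
            min_members=config.min_category_size,
            n_perms=config.n_perms_dh,
            seed=config.seed,
        )
        io.write_dh_results(results, outdir / "dh_results.tsv", outdir / "dh_results_full.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "dataset": dataset,
        "scores": scores,
        "threshold": threshold,
        "threshold_diagnostics": diagnostics,
        "snp_network": snp_net,
        "gene_network": gene_net,
        "gene_summary": summary,
        "dh_results": results,
    }


def run_dh_only(
    network_file,
    categories_file,
    n_perms: int = 100_000,
    min_category_size: int = 3,
    seed: int = 0,
    out=None,
) -> pd.DataFrame:
    """Dyadicity/heterophilicity of categories on a pre-built network.

    Loads a GraphML network and a GMT category file and runs the same
    analysis as the full pipeline's final stage. With ``out`` set, writes
    the rounded report and a full-precision companion next to it.
    """
    net = io.read_network(network_file)
    categories = io.read_gmt(categories_file)
    results = analyze_categories(
        net, categories, min_members=min_category_size, n_perms=n_perms, seed=seed
    )
    if out is not None:
        out = Path(out)
        io.write_dh_results(results, out, out.with_name(out.stem + "_full.tsv"))
    return io.results_to_frame(results)
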