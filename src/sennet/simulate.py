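"""Synthetic data generators: case-control genotypes with planted two-locus
epistasis, many-to-one SNP->gene maps, attributed networks with planted
dyadic/heterophilic label structure, and overlapping gene categories.

The genotype generator emulates the shape of a candidate-gene case-control
panel: ~1400 biallelic SNPs from ~400 genes typed on ~1300 subjects, with a
few percent missing calls. Genotypes are drawn under Hardy-Weinberg
equilibrium from a minor-allele frequency sampled per SNP; there is no
linkage disequilibrium or population structure. Epistatic signal is planted
through two-locus penetrance tables:

``xor``
    Penetrance depends on the parity of heterozygosity at the two loci.
    At MAF 0.5 the heterozygote indicator is a fair coin, so the model is
    purely epistatic: each locus alone carries (asymptotically) zero
    information about the phenotype while the pair is fully informative
    at effect 1.
``threshold``
    Case risk is raised when the combined risk-allele count g_i + g_j
    reaches 3; has both marginal and interaction effects.
``multiplicative``
    Penetrance deviation proportional to g_i * g_j / 4.

Each model maps a genotype pair to x in [0, 1]; the penetrance is
0.5 + effect * (x - 0.5). Multiple planted pairs combine their deviations
additively (clipped to [0, 1]), so K pairs sharing a hub SNP each keep an
O(effect) signal. Case/control totals are met exactly by quota sampling:
subjects are simulated until the requested numbers of cases and controls
have accrued, which holds the non-planted SNPs phenotype-independent by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .datatypes import (
    MISSING,
    EpistasisNetwork,
    GenotypeDataset,
    make_gene_ids,
    make_sample_ids,
    make_snp_ids,
)

__all__ = [
    "SyntheticGenotypeSpec",
    "SyntheticNetworkSpec",
    "PENETRANCE_MODELS",
    "penetrance_table",
    "generate_genotypes",
    "plant_epistatic_pair",
    "generate_snp_gene_map",
    "generate_attributed_network",
    "generate_categories",
]

_HET = np.array([0, 1, 0])  # heterozygote indicator per genotype code
_G = np.arange(3)


def _xor_pattern() -> np.ndarray:
    return (_HET[:, None] != _HET[None, :]).astype(float)


def _threshold_pattern() -> np.ndarray:
    return (np.add.outer(_G, _G) >= 3).astype(float)


def _multiplicative_pattern() -> np.ndarray:
    return np.outer(_G, _G) / 4.0


PENETRANCE_MODELS = {
    "xor": _xor_pattern,
    "threshold": _threshold_pattern,
    "multiplicative": _multiplicative_pattern,
}


def penetrance_table(model: str, effect: float) -> np.ndarray:
    """3x3 P(case | g_i, g_j) table: 0.5 + effect * (pattern - 0.5)."""
    if model not in PENETRANCE_MODELS:
        raise ValueError(f"unknown penetrance model {model!r}; choose from {sorted(PENETRANCE_MODELS)}")
    if not 0 <= effect <= 1:
        raise ValueError("effect must be in [0, 1]")
    return 0.5 + effect * (PENETRANCE_MODELS[model]() - 0.5)


@dataclass
class SyntheticGenotypeSpec:
    """Parameters of a synthetic case-control genotype panel."""

    n_snps: int
    n_cases: int
    n_controls: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.02
    planted_pairs: list[tuple[int, int, str, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1 or self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_snps, n_cases, n_controls must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must be in [0, 0.5)")
        seen = set()
        for i, j, model, effect in self.planted_pairs:
            if i == j:
                raise ValueError("planted pair indices must be distinct")
            if not (0 <= i < self.n_snps and 0 <= j < self.n_snps):
                raise ValueError(f"planted pair ({i}, {j}) out of range for {self.n_snps} SNPs")
            if model not in PENETRANCE_MODELS:
                raise ValueError(f"unknown penetrance model {model!r}")
            if not 0 <= effect <= 1:
                raise ValueError("planted effect must be in [0, 1]")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate planted pair {key}")
            seen.add(key)


@dataclass
class SyntheticNetworkSpec:
    """Parameters of an attributed network with planted label structure."""

    n_vertices: int
    n_edges: int
    n1: int
    regime: str = "random"
    strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vertices < 2:
            raise ValueError("need at least 2 vertices")
        if self.n1 > self.n_vertices or self.n1 < 0:
            raise ValueError("n1 must be in [0, n_vertices]")
        max_edges = self.n_vertices * (self.n_vertices - 1) // 2
        if not 0 <= self.n_edges <= max_edges:
            raise ValueError(f"n_edges must be in [0, {max_edges}]")
        if self.regime not in ("dyadic", "heterophilic", "random"):
            raise ValueError("regime must be 'dyadic', 'heterophilic' or 'random'")
        if self.strength < 1:
            raise ValueError("strength must be >= 1")


def _hw_column_batch(rng: np.random.Generator, mafs: np.ndarray, n: int) -> np.ndarray:
    """Draw n subjects' genotypes (n_snps x n) under Hardy-Weinberg."""
    q = mafs[:, None]
    u = rng.random((mafs.size, n))
    p0 = (1 - q) ** 2
    p01 = p0 + 2 * q * (1 - q)
    return (np.where(u < p0, 0, np.where(u < p01, 1, 2))).astype(np.int8)


def _case_probability(batch: np.ndarray, planted: list[tuple[int, int, str, float]]) -> np.ndarray:
    prob = np.full(batch.shape[1], 0.5)
    for i, j, model, effect in planted:
        table = penetrance_table(model, effect)
        prob += table[batch[i], batch[j]] - 0.5
    return np.clip(prob, 0.0, 1.0)


def generate_genotypes(spec: SyntheticGenotypeSpec) -> GenotypeDataset:
    """Simulate a complete case-control panel under the spec.

    The phenotype has exactly ``n_cases`` ones followed by ``n_controls``
    zeros (samples are ordered cases-first). Identical seeds give
    bit-identical datasets.
    """
    rng = np.random.default_rng(spec.seed)
    mafs = rng.uniform(spec.maf_range[0], spec.maf_range[1], spec.n_snps)

    case_cols: list[np.ndarray] = []
    ctrl_cols: list[np.ndarray] = []
    need_cases, need_ctrls = spec.n_cases, spec.n_controls
    for _ in range(1000):
        if need_cases <= 0 and need_ctrls <= 0:
            break
        batch = _hw_column_batch(rng, mafs, max(64, 2 * (need_cases + need_ctrls)))
        status = rng.random(batch.shape[1]) < _case_probability(batch, spec.planted_pairs)
        if need_cases > 0:
            take = batch[:, status][:, :need_cases]
            case_cols.append(take)
            need_cases -= take.shape[1]
        if need_ctrls > 0:
            take = batch[:, ~status][:, :need_ctrls]
            ctrl_cols.append(take)
            need_ctrls -= take.shape[1]
    else:
        raise RuntimeError("penetrance model produced too few cases or controls")

    G = np.concatenate(case_cols + ctrl_cols, axis=1)
    phenotype = np.concatenate(
        [np.ones(spec.n_cases, dtype=np.uint8), np.zeros(spec.n_controls, dtype=np.uint8)]
    )
    if spec.missing_rate > 0:
        mask = rng.random(G.shape) < spec.missing_rate
        G = np.where(mask, np.int8(MISSING), G)
    return GenotypeDataset(
        snp_ids=make_snp_ids(spec.n_snps),
        sample_ids=make_sample_ids(spec.n_cases + spec.n_controls),
        genotypes=G,
        phenotype=phenotype,
    )


def plant_epistatic_pair(
    dataset: GenotypeDataset, i: int, j: int, model: str, effect: float, seed: int = 0
) -> GenotypeDataset:
    """Regenerate the phenotype from a two-locus penetrance table on (i, j).

    Genotypes are untouched; the phenotype of every sample is redrawn as
    Bernoulli(P(case | g_i, g_j)). Missing calls at the two loci are
    mode-imputed for the table lookup only. The resulting case/control
    split is random, not quota-matched.
    """
    if i == j or not (0 <= i < dataset.n_snps and 0 <= j < dataset.n_snps):
        raise ValueError("i and j must be distinct valid SNP indices")
    table = penetrance_table(model, effect)
    rng = np.random.default_rng(seed)

    def complete(row: np.ndarray) -> np.ndarray:
        miss = row == MISSING
        if not miss.any():
            return row
        counts = np.bincount(row[~miss], minlength=3)
        out = row.copy()
        out[miss] = int(np.argmax(counts))
        return out

    gi = complete(dataset.genotypes[i])
    gj = complete(dataset.genotypes[j])
    prob = table[gi, gj]
    phenotype = (rng.random(dataset.n_samples) < prob).astype(np.uint8)
    return GenotypeDataset(
        snp_ids=list(dataset.snp_ids),
        sample_ids=list(dataset.sample_ids),
        genotypes=dataset.genotypes,
        phenotype=phenotype,
    )


def generate_snp_gene_map(n_snps: int, n_genes: int, seed: int = 0) -> dict[str, str]:
    """Random many-to-one SNP->gene assignment; every gene gets >= 1 SNP."""
    if n_genes > n_snps:
        raise ValueError("n_genes cannot exceed n_snps")
    if n_genes < 1:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(seed)
    # gene sizes: composition of n_snps into n_genes positive parts
    if n_genes == 1:
        sizes = np.array([n_snps])
    else:
        cuts = np.sort(rng.choice(np.arange(1, n_snps), size=n_genes - 1, replace=False))
        sizes = np.diff(np.concatenate([[0], cuts, [n_snps]]))
    snp_ids = make_snp_ids(n_snps)
    gene_ids = make_gene_ids(n_genes)
    order = rng.permutation(n_snps)
    mapping: dict[str, str] = {}
    pos = 0
    for g, size in zip(gene_ids, sizes):
        for k in order[pos : pos + size]:
            mapping[snp_ids[k]] = g
        pos += size
    return dict(sorted(mapping.items()))


def generate_attributed_network(spec: SyntheticNetworkSpec) -> tuple[EpistasisNetwork, dict[str, int]]:
    """A random graph with binary vertex labels and optional planted bias.

    Edges are sampled without replacement from all vertex pairs with
    weight ``strength`` on 1-1 pairs (dyadic regime) or 1-0 pairs
    (heterophilic regime) and weight 1 elsewhere; the random regime is
    uniform. Isolated vertices are kept — the dyad census needs the full
    vertex set. Labels assign exactly n1 ones to a uniform vertex subset.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_vertices
    names = [f"g{i:04d}" for i in range(n)]
    lab = np.zeros(n, dtype=bool)
    lab[rng.choice(n, size=spec.n1, replace=False)] = True

    iu, ju = np.triu_indices(n, k=1)
    w = np.ones(iu.size)
    if spec.regime == "dyadic":
        w[lab[iu] & lab[ju]] = spec.strength
    elif spec.regime == "heterophilic":
        w[lab[iu] ^ lab[ju]] = spec.strength
    # weighted sampling without replacement (Efraimidis-Spirakis keys)
    keys = rng.random(iu.size) ** (1.0 / w)
    sel = np.argpartition(-keys, spec.n_edges - 1)[: spec.n_edges] if spec.n_edges > 0 else np.array([], dtype=int)

    graph = nx.Graph()
    graph.add_nodes_from(names)
    graph.add_edges_from((names[iu[k]], names[ju[k]]) for k in sel)
    labels = {names[i]: int(lab[i]) for i in range(n)}
    return EpistasisNetwork(graph=graph, level="gene"), labels


def generate_categories(
    genes: list[str],
    n_categories: int,
    size_range: tuple[int, int] = (3, 50),
    overlap_allowed: bool = True,
    seed: int = 0,
) -> dict[str, set]:
    """Random gene categories (GO-term stand-ins), possibly overlapping."""
    if len(genes) == 0:
        raise ValueError("empty gene list")
    lo, hi = size_range
    if not (1 <= lo <= hi <= len(genes)):
        raise ValueError("size_range must lie within [1, number of genes]")
    rng = np.random.default_rng(seed)
    genes = list(genes)
    categories: dict[str, set] = {}
    pool = list(genes)
    for k in range(n_categories):
        size = int(rng.integers(lo, hi + 1))
        name = f"cat{k + 1:04d}"
        if overlap_allowed:
            members = rng.choice(len(genes), size=size, replace=False)
            categories[name] = {genes[m] for m in members}
        else:
            if size > len(pool):
                raise ValueError("disjoint categories exhausted the gene pool")
            idx = rng.choice(len(pool), size=size, replace=False)
            categories[name] = {pool[m] for m in idx}
            pool = [g for m, g in enumerate(pool) if m not in set(idx.tolist())]
    return categories
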