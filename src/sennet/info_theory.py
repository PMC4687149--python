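"""Plug-in entropy, mutual information, and the information-gain epistasis
score, plus the genotype preprocessing rules (missingness filter, mode
imputation).

All information quantities are in bits (log base 2). Estimators are plain
plug-in (maximum likelihood) frequencies with no bias correction; with a
binary phenotype and 3-level genotypes the joint tables are small (at most
9 x 2 cells), so the plug-in bias is modest at the sample sizes this kind
of case-control analysis uses, and it cancels to first order in the
permutation comparisons downstream.

The epistasis score for a SNP pair (A, B) against the phenotype C is

    IG(A;B;C) = I(A,B;C) - I(A;C) - I(B;C)

where (A, B) is the joint variable over the observed genotype combinations.
IG > 0 means the pair carries synergistic information about the phenotype
beyond the two marginal associations; IG < 0 indicates redundancy and is
retained as-is (thresholding happens at network construction).
"""

from __future__ import annotations

import numpy as np

from .datatypes import MISSING, GenotypeDataset, InteractionScores

__all__ = [
    "entropy",
    "mutual_information",
    "information_gain",
    "filter_missingness",
    "impute_mode",
    "all_pairs_ig",
]


def entropy(counts) -> float:
    """Shannon entropy in bits of a non-negative count table.

    Zero cells contribute nothing (0 log 0 := 0). Raises on an empty or
    all-zero table and on negative counts.
    """
    c = np.asarray(counts, dtype=float).ravel()
    if c.size == 0:
        raise ValueError("empty count table")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("count table sums to zero")
    p = c[c > 0] / total
    return float(-(p * np.log2(p)).sum())


def _encode(v: np.ndarray) -> tuple[np.ndarray, int]:
    """Map an arbitrary discrete vector to codes 0..k-1."""
    levels, codes = np.unique(np.asarray(v), return_inverse=True)
    return codes, len(levels)


def mutual_information(x, y) -> float:
    """I(X;Y) in bits between two equal-length discrete vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size == 0:
        raise ValueError("empty vectors")
    xc, kx = _encode(x)
    yc, ky = _encode(y)
    joint = np.bincount(xc * ky + yc, minlength=kx * ky).reshape(kx, ky)
    mi = entropy(joint.sum(axis=1)) + entropy(joint.sum(axis=0)) - entropy(joint)
    # plug-in MI is non-negative; trim float round-off only
    return max(mi, 0.0) if mi > -1e-12 else mi


def information_gain(a, b, c) -> float:
    """IG(A;B;C) = I((A,B);C) - I(A;C) - I(B;C), in bits.

    Symmetric in a and b; may be negative when A and B are redundant
    about C.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    c = np.asarray(c)
    if not (a.shape == b.shape == c.shape) or a.ndim != 1:
        raise ValueError("a, b, c must be 1-D vectors of equal length")
    ac, ka = _encode(a)
    bc, kb = _encode(b)
    joint_ab = ac * kb + bc
    return mutual_information(joint_ab, c) - mutual_information(a, c) - mutual_information(b, c)


def filter_missingness(dataset: GenotypeDataset, max_missing_fraction: float = 0.05) -> GenotypeDataset:
    """Drop SNPs whose missing-call fraction exceeds the threshold.

    The rule is strict ("more than"): a SNP at exactly the threshold is
    retained. SNP order is preserved. May return an empty dataset.
    """
    if not 0 <= max_missing_fraction < 1:
        raise ValueError("max_missing_fraction must be in [0, 1)")
    keep = dataset.missing_fraction() <= max_missing_fraction
    return GenotypeDataset(
        snp_ids=[s for s, k in zip(dataset.snp_ids, keep) if k],
        sample_ids=list(dataset.sample_ids),
        genotypes=dataset.genotypes[keep],
        phenotype=dataset.phenotype,
    )


def impute_mode(dataset: GenotypeDataset) -> GenotypeDataset:
    """Replace missing calls by the SNP's most frequent genotype.

    The mode is taken across all samples (cases and controls pooled). Ties
    break toward the lowest genotype code for determinism. A SNP with every
    call missing has no mode and raises.
    """
    G = dataset.genotypes.copy()
    for i in range(G.shape[0]):
        row = G[i]
        miss = row == MISSING
        if not miss.any():
            continue
        observed = row[~miss]
        if observed.size == 0:
            raise ValueError(f"SNP {dataset.snp_ids[i]} has all calls missing")
        counts = np.bincount(observed, minlength=3)
        row[miss] = int(np.argmax(counts))  # argmax picks the lowest code on ties
    return GenotypeDataset(
        snp_ids=list(dataset.snp_ids),
        sample_ids=list(dataset.sample_ids),
        genotypes=G,
        phenotype=dataset.phenotype,
    )


def _main_effects(G: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-SNP I(SNP; C) for a complete 3-level genotype matrix."""
    h_c = entropy(np.bincount(c, minlength=2))
    m = G.shape[0]
    main = np.empty(m)
    for i in range(m):
        cnt = np.bincount(G[i].astype(np.int64) * 2 + c, minlength=6)
        mi = entropy(cnt.reshape(3, 2).sum(axis=1)) + h_c - entropy(cnt)
        main[i] = max(mi, 0.0)
    return main, h_c


def _pair_ig_matrix(G: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs IG and per-SNP main effects for a complete genotype matrix.

    G: (n_snps, n_samples) over {0,1,2}; c: binary phenotype. The joint
    variable for a pair is the 9-cell cross-product of genotype levels.
    """
    c = c.astype(np.int64)
    main, h_c = _main_effects(G, c)
    m = G.shape[0]
    ig = np.zeros((m, m))
    G64 = G.astype(np.int64)
    for i in range(m):
        base = G64[i] * 6
        for j in range(i + 1, m):
            cnt = np.bincount(base + G64[j] * 2 + c, minlength=18)
            i_ab_c = entropy(cnt.reshape(9, 2).sum(axis=1)) + h_c - entropy(cnt)
            val = max(i_ab_c, 0.0) - main[i] - main[j]
            ig[i, j] = ig[j, i] = val
    return main, ig


def all_pairs_ig(dataset: GenotypeDataset) -> InteractionScores:
    """Score every unordered SNP pair by information gain.

    Requires a complete dataset (run :func:`impute_mode` first) with at
    least two SNPs. Returns the symmetric IG matrix plus per-SNP
    phenotype mutual information.
    """
    if dataset.n_snps < 2:
        raise ValueError("need at least 2 SNPs to score pairs")
    if dataset.has_missing():
        raise ValueError("dataset contains missing genotypes; impute first")
    main, ig = _pair_ig_matrix(dataset.genotypes, dataset.phenotype)
    return InteractionScores(snp_ids=list(dataset.snp_ids), main_effect=main, ig=ig)
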