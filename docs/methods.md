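# Methods

## Overview

`sennet` implements a pipeline for interpreting statistical epistasis in
case-control genetic association data through network structure:

1. **Pairwise interaction scoring.** For SNPs *A*, *B* and binary
   phenotype *C*, the epistasis score is the information gain
   *IG(A;B;C) = I(A,B;C) − I(A;C) − I(B;C)*, where *(A,B)* is the joint
   variable over the (up to) 9 observed genotype combinations. Positive
   IG is synergy — the pair says more about the phenotype than its parts;
   negative IG is redundancy and is retained unclipped.
2. **Network construction.** SNP pairs with IG strictly above a threshold
   become edges of the statistical epistasis network (SEN); SNPs with no
   retained edge are excluded. The threshold is selected by comparing the
   real network's topology to networks built at the same threshold from
   phenotype-permuted data.
3. **Gene collapse.** The SNP network is mapped through a many-to-one
   SNP→gene assignment: two genes are adjacent when any of their SNPs
   are; within-gene SNP edges become gene self-loops; parallel gene edges
   are merged (multiplicity kept as an edge attribute).
4. **Category dyadicity/heterophilicity.** For each binary gene category
   (e.g. a GO term) with *n1* member genes in a network of *N* vertices
   and *M* edges, each edge is a dyad classified by its endpoints'
   membership. With *p = 2M/(N(N−1))*, random label placement predicts
   *m̄11 = n1(n1−1)p/2* same-category dyads and *m̄10 = n1(N−n1)p*
   cross-boundary dyads. Dyadicity *D = m11/m̄11* and heterophilicity
   *H = m10/m̄10* measure enrichment of within-category and across-boundary
   interaction; significance comes from shuffling the labels over vertices
   with *n1* fixed.

## Estimators and conventions

- **Entropy base.** All information quantities are in bits. The base only
  rescales IG thresholds.
- **Plug-in estimation.** Entropies use maximum-likelihood cell
  frequencies with no small-sample bias correction. Joint tables are at
  most 9×2, so the first-order bias ≈ (cells−1)/(2n ln 2) is small at
  typical cohort sizes and common to real and permuted data, cancelling
  in the permutation comparison.
- **Missingness.** SNPs with *more than* the missingness threshold
  (default 5%) of calls missing are removed (a SNP at exactly the
  threshold stays); remaining missing calls are imputed with the SNP's
  most frequent genotype across all samples, ties breaking to the lowest
  genotype code for determinism. Imputation precedes pair scoring.
- **Edge rule.** Strict inequality (IG > t). Raising the threshold never
  adds edges.
- **Self-loops.** A gene self-loop counts in the edge inventory (the
  gene-network edge count reports it) but is excluded from (a) neighbor
  degrees, (b) connected components, and (c) the dyad census: *M* and all
  *m* counts cover non-self-loop edges only. This convention is forced by
  the published expectations: with 185 vertices and "174 edges including
  1 self-loop", every printed expected dyad count is reproduced with
  M = 173, and the mean neighbor count 1.87 equals 2·173/185.
- **p-values.** p = (#replicates with statistic ≥ observed)/n_perms; ties
  count toward the numerator. Reported p-values are floored at 1/n_perms
  (the Monte-Carlo resolution), so p ∈ (0, 1]. No plus-one correction and
  no multiple-testing adjustment across categories — categories overlap
  and are analyzed independently. Since permutation fixes (N, M, n1), the
  test compares m11 (m10) directly, which is equivalent to comparing
  D (H).
- **Undefined statistics.** D requires n1 ≥ 2 and H requires
  0 < n1 < N; outside these, the statistic and its p-value are reported
  missing rather than raising. m11 = 0 with positive expectation yields
  D = 0 (in-band, not missing).
- **Permutation streams.** Each category gets its own generator seeded by
  (master seed, category position), so per-category results do not depend
  on which other categories are analyzed. D and H share one replicate
  stream per category.

## Threshold selection

The published framework describes choosing the IG cutoff where the real
network is most topologically distinct from permuted-data networks,
without an explicit selection formula. We operationalize this as a grid
search: candidate thresholds default to 50 evenly spaced quantiles of the
upper decile of the observed IG distribution; for each candidate, the
phenotype is permuted (case/control totals fixed), all pairs rescored,
and the network rebuilt, and the statistic is the z-score of the real
giant-component size against the null replicates. Null IG matrices are
computed once per permutation and re-thresholded along the grid. Grid
points with zero null variance are skipped with a warning (with a raw
giant-excess fallback if every point is degenerate). Degree distributions
and network sizes are returned as diagnostics rather than folded into the
selection statistic, keeping the criterion a single scalar.

## Synthetic data

The generator emulates the shape of a candidate-gene case-control panel
(defaults mirror the motivating study: 1422 SNPs from 396 genes, 491
cases, 791 controls, ≤5% missingness):

- Genotypes drawn under Hardy–Weinberg equilibrium from a per-SNP MAF
  sampled uniformly in a configurable range; no linkage disequilibrium,
  no population structure, no genotyping-batch artifacts. Missing calls
  are injected uniformly at random.
- Epistasis is planted via 3×3 two-locus penetrance tables
  P(case|g_i,g_j) = 0.5 + effect·(x − 0.5), with pattern x given by the
  model: `xor` (parity of heterozygosity — at MAF 0.5 the heterozygote
  indicator is a fair coin, making the model purely epistatic with
  vanishing marginal effects), `threshold` (risk-allele count ≥ 3; has
  marginal effects), `multiplicative` (x = g_i·g_j/4). Multiple planted
  pairs combine their penetrance deviations additively (clipped to
  [0,1]), so pairs sharing a hub SNP each retain an O(effect) signal.
- Exact case/control totals are met by quota sampling: subjects are
  simulated in batches and assigned to the case or control pool by a
  Bernoulli draw from their penetrance until both quotas fill. Unplanted
  SNPs are phenotype-independent by construction.
- Attributed networks with planted label structure place edges by
  weighted sampling without replacement (Efraimidis–Spirakis keys) with
  weight `strength` on 1-1 pairs (dyadic regime) or 1-0 pairs
  (heterophilic regime); the random regime is uniform, under which the
  mean observed m11 matches m̄11 and D and H are calibrated at 1.
- Gene categories are random member subsets (sizes uniform in a range,
  overlapping allowed), standing in for GO-term membership.

Because the synthetic data lack LD and realistic allele-frequency spectra,
passing tests demonstrate the statistical machinery (calibration, power
against planted signal, exactness of the arithmetic), not robustness to
the confounders of real genotype panels.

## Problem sizes in the test suite

Simulation-backed tests use deliberately modest sizes chosen to exercise
each property with comfortable statistical margins: 20–50 SNP panels with
400–2000 subjects for IG ranking and threshold selection; 100-vertex /
200-edge networks with n1 = 10 for calibration (1000 replicates) and
power (100 replicates at planting strength 5, 1000 permutations each);
exhaustive p-value enumeration on 12-vertex graphs (≤ 495 labelings). The
published-arithmetic checks are exact desk computations at the study's
own scale (N = 185, M = 173).

## Known limitations

- The threshold-selection statistic (giant-component z-score) is one
  reasonable operationalization of "most distinguishing topology"; the
  original derivation is not recoverable from the published description.
- Plug-in IG is biased upward for sparse cells; at very small n the
  ranking of weak pairs is noisy. The permutation null shares this bias.
- The quota sampler assumes the penetrance model produces both classes at
  workable rates; pathological configurations (near-zero prevalence)
  abort after a bounded number of batches.
- Gene assignment is taken as given (one gene per SNP); no windowing or
  regulatory-region logic.
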