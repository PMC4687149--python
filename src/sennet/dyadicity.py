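"""Dyadicity and heterophilicity of binary vertex properties.

For a network with N vertices and M edges (self-loops excluded throughout)
and a binary vertex property held by n1 vertices, each edge is a dyad
classified by its endpoint values: (1-1), (1-0) or (0-0), with observed
counts m11, m10, m00. If the property were placed uniformly at random on
the vertices, the expected counts would be

    m11_expected = n1 (n1 - 1) / 2 * p,      m10_expected = n1 (N - n1) * p,

with p = 2M / (N (N - 1)) the average connection probability. Dyadicity
and heterophilicity are the observed/expected ratios

    D = m11 / m11_expected,                  H = m10 / m10_expected.

D > 1 means vertices sharing the property connect to each other more than
chance (dyadic); H > 1 means they connect across the property boundary
more than chance (heterophilic). A property can be both when its carriers
are well-connected hubs. Significance is assessed by shuffling the
property assignment over vertices with n1 fixed: the p-value is the
fraction of permutations whose D (H) is greater than or equal to the
observed value; ties count toward the numerator, and reported p-values
are floored at 1/n_perms.

D requires n1 >= 2 and H requires 0 < n1 < N; outside those ranges the
statistic (and its p-value) is reported as missing (None). D is 0, not
missing, when m11 = 0 with a positive expectation.
"""

from __future__ import annotations

import numpy as np

from .datatypes import CategoryAssignment, DHResult, DyadCounts, EpistasisNetwork

__all__ = [
    "count_dyads",
    "expected_dyads",
    "dyadicity",
    "heterophilicity",
    "permutation_test",
    "analyze_categories",
]

_PERM_CHUNK = 4096


def _graph_of(network):
    return network.graph if isinstance(network, EpistasisNetwork) else network


def _edge_index(graph, vertices: list) -> tuple[np.ndarray, np.ndarray]:
    """Endpoint index arrays of the non-self-loop edges."""
    pos = {v: k for k, v in enumerate(vertices)}
    pairs = [(pos[u], pos[v]) for u, v in graph.edges if u != v]
    if not pairs:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    e = np.asarray(pairs, dtype=np.intp)
    return e[:, 0], e[:, 1]


def count_dyads(network, labels) -> DyadCounts:
    """Census of (1-1), (1-0), (0-0) dyads for a binary labeling.

    ``labels`` maps every vertex to 0 or 1; a vertex without a label
    raises. Self-loops are excluded from M and from every m count.
    """
    graph = _graph_of(network)
    vertices = list(graph.nodes)
    missing = [v for v in vertices if v not in labels]
    if missing:
        raise KeyError(f"vertices without labels: {missing[:5]}")
    lab = np.array([bool(labels[v]) for v in vertices])
    e0, e1 = _edge_index(graph, vertices)
    a, b = lab[e0], lab[e1]
    m11 = int((a & b).sum())
    m10 = int((a ^ b).sum())
    M = int(e0.size)
    return DyadCounts(
        N=len(vertices), M=M, n1=int(lab.sum()), m11=m11, m10=m10, m00=M - m11 - m10
    )


def expected_dyads(N: int, M: int, n1: int) -> tuple[float, float]:
    """Expected (1-1) and (1-0) dyad counts under random label placement."""
    if N < 2:
        raise ValueError("need at least 2 vertices")
    if not 0 <= n1 <= N:
        raise ValueError("n1 must be in [0, N]")
    if M < 0:
        raise ValueError("M must be non-negative")
    p = 2.0 * M / (N * (N - 1))
    return n1 * (n1 - 1) / 2.0 * p, n1 * (N - n1) * p


def dyadicity(counts: DyadCounts) -> float | None:
    """D = m11 / m11_expected; None when undefined (n1 < 2 or M = 0)."""
    if counts.n1 < 2:
        return None
    m11_exp, _ = expected_dyads(counts.N, counts.M, counts.n1)
    if m11_exp == 0.0:
        return None
    return counts.m11 / m11_exp


def heterophilicity(counts: DyadCounts) -> float | None:
    """H = m10 / m10_expected; None when undefined (n1 in {0, N} or M = 0)."""
    if counts.n1 == 0 or counts.n1 == counts.N:
        return None
    _, m10_exp = expected_dyads(counts.N, counts.M, counts.n1)
    if m10_exp == 0.0:
        return None
    return counts.m10 / m10_exp


def _permuted_dyad_counts(
    rng: np.random.Generator, N: int, n1: int, e0: np.ndarray, e1: np.ndarray, n_perms: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized m11, m10 for n_perms uniform placements of n1 labels."""
    m11 = np.empty(n_perms, dtype=np.int64)
    m10 = np.empty(n_perms, dtype=np.int64)
    if n1 == 0:
        m11[:] = 0
        m10[:] = 0
        return m11, m10
    done = 0
    while done < n_perms:
        k = min(_PERM_CHUNK, n_perms - done)
        r = rng.random((k, N))
        idx = np.argpartition(r, n1 - 1, axis=1)[:, :n1]
        lab = np.zeros((k, N), dtype=bool)
        lab[np.arange(k)[:, None], idx] = True
        a = lab[:, e0]
        b = lab[:, e1]
        m11[done : done + k] = (a & b).sum(axis=1)
        m10[done : done + k] = (a ^ b).sum(axis=1)
        done += k
    return m11, m10


def permutation_test(network, labels, n_perms: int = 100_000, seed: int = 0) -> tuple[float | None, float | None]:
    """Permutation p-values for D and H of a labeling.

    Each replicate places the n1 ones on a uniformly random vertex subset;
    both statistics are evaluated on the same replicate stream. Because
    the expectations depend only on (N, M, n1), which permutation
    preserves, comparing D (H) across replicates is equivalent to
    comparing m11 (m10); the test does exactly that. p = #{replicate
    statistic >= observed} / n_perms, floored at 1/n_perms.
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    obs = count_dyads(network, labels)
    graph = _graph_of(network)
    vertices = list(graph.nodes)
    e0, e1 = _edge_index(graph, vertices)
    rng = np.random.default_rng(seed)
    m11, m10 = _permuted_dyad_counts(rng, obs.N, obs.n1, e0, e1, n_perms)

    p_d: float | None = None
    p_h: float | None = None
    if obs.n1 >= 2:
        p_d = max(int((m11 >= obs.m11).sum()), 1) / n_perms
    if 0 < obs.n1 < obs.N:
        p_h = max(int((m10 >= obs.m10).sum()), 1) / n_perms
    return p_d, p_h


def analyze_categories(
    network,
    categories: CategoryAssignment,
    min_members: int = 3,
    n_perms: int = 100_000,
    seed: int = 0,
) -> list[DHResult]:
    """Dyadicity/heterophilicity of every category against one network.

    Each category's member set is intersected with the network's vertices;
    categories with fewer than ``min_members`` in-network members are
    dropped. Categories are analyzed independently (they may overlap; no
    multiplicity adjustment). Each retained category gets its own
    permutation stream seeded by (seed, category position) so results are
    reproducible regardless of evaluation order.
    """
    if min_members < 1:
        raise ValueError("min_members must be >= 1")
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    graph = _graph_of(network)
    vertex_set = set(graph.nodes)
    results: list[DHResult] = []
    for index, (name, members) in enumerate(categories.items()):
        in_network = set(members) & vertex_set
        if len(in_network) < min_members:
            continue
        labels = {v: int(v in in_network) for v in vertex_set}
        counts = count_dyads(graph, labels)
        m11_exp, m10_exp = expected_dyads(counts.N, counts.M, counts.n1)
        p_d, p_h = permutation_test(graph, labels, n_perms=n_perms, seed=np.random.default_rng([seed, index]).integers(2**31))
        results.append(
            DHResult(
                category=name,
                counts=counts,
                m11_expected=m11_exp,
                m10_expected=m10_exp,
                D=dyadicity(counts),
                H=heterophilicity(counts),
                p_D=p_d,
                p_H=p_h,
                n_perms=n_perms,
            )
        )
    return results
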