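"""Selection index, truncation selection, diversity metrics, GA parent picker.

Multi-trait selection uses the standardized index
``I = sum_t w_t u_t / s_t`` with weights (0.3, 0.3, 0.4) for disease
resistance, grain weight and grain yield, where ``u`` is a GEBV or a
phenotype mean and ``s`` its SD in the candidate cohort.  Genetic diversity
is tracked as per-trait TBV variance, the number of marker alleles fixed
(NAF) and the mean off-diagonal of VanRaden's genomic relationship matrix
G = ZZ' / (2 sum p(1-p)).  The diversity-preserving parent selector
maximizes ``f = I - lambda1 * mean_relationship - lambda2 * NAF`` over
subsets of exact cardinality with a genetic algorithm (membership
bit-vector encoding, one-point crossover, cardinality repair, elitism).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .population import Population
from .traits import INDEX_WEIGHTS, TRAITS, TraitArchitecture, tbv_matrix

__all__ = [
    "DiversityReport",
    "ParentSet",
    "GAParams",
    "selection_index",
    "truncate_select",
    "grm",
    "diversity_report",
    "ga_select_parents",
]


def selection_index(
    values: np.ndarray,
    sds: np.ndarray | None = None,
    weights: np.ndarray = INDEX_WEIGHTS,
) -> np.ndarray:
    """Weighted sum of cohort-standardized trait values, one score per candidate."""
    values = np.asarray(values, dtype=np.float64)
    if sds is None:
        sds = values.std(axis=0)
    out = np.zeros(values.shape[0])
    for ti in range(values.shape[1]):
        if sds[ti] <= 0:
            warnings.warn(f"zero SD for {TRAITS[ti]}; trait term dropped from index")
            continue
        out += weights[ti] * values[:, ti] / sds[ti]
    return out


def truncate_select(
    index_values: np.ndarray, n: int, ids: np.ndarray | None = None
) -> np.ndarray:
    """Positions of the top-``n`` candidates; ties broken by ascending id."""
    if n > len(index_values):
        raise ValueError("cannot select more candidates than exist")
    if ids is None:
        ids = np.arange(len(index_values))
    order = np.lexsort((ids, -np.asarray(index_values, dtype=np.float64)))
    return order[:n]


def grm(
    genotypes: np.ndarray, freqs: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """VanRaden genomic relationship matrix and its mean off-diagonal.

    ``genotypes`` holds 0/1/2 allele counts (rows = individuals); centring
    frequencies default to the cohort's own.
    """
    M = np.asarray(genotypes, dtype=np.float64)
    if M.shape[0] < 2:
        raise ValueError("need at least 2 individuals")
    p = M.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, dtype=np.float64)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all loci fixed in the reference; GRM undefined")
    Z = M - 2.0 * p
    G = Z @ Z.T / denom
    n = G.shape[0]
    mean_off = float((G.sum() - np.trace(G)) / (n * (n - 1)))
    return G, mean_off


@dataclass
class DiversityReport:
    """Cohort diversity snapshot: relationship, fixation, trait variances."""

    mean_offdiag_grm: float
    n_alleles_fixed: int
    pct_alleles_fixed: float
    tbv_variance: dict[str, float]
    aggregate_tbv_variance: float


def n_fixed(counts: np.ndarray) -> int:
    """Loci with zero allelic variation (all-0 or all-2, no heterozygote)."""
    return int(np.sum((counts.min(axis=0) == counts.max(axis=0)) & (counts[0] != 1)))


def diversity_report(
    cohort: Population,
    arch: TraitArchitecture,
    marker_loci: np.ndarray,
    weights: np.ndarray = INDEX_WEIGHTS,
    freqs: np.ndarray | None = None,
) -> DiversityReport:
    """Snapshot a cohort's diversity.

    ``freqs`` are the GRM centring frequencies — pass the base population's
    so relationships accumulate on a fixed reference as inbreeding builds
    (cohort-centred relationships have a mean off-diagonal pinned near
    ``-(1+F)/(n-1)`` by construction and cannot trend).
    """
    counts = cohort.allele_counts(marker_loci)
    naf = n_fixed(counts)
    pct = 100.0 * naf / counts.shape[1]
    if len(cohort) >= 2 and (freqs is not None or naf < counts.shape[1]):
        _, mean_off = grm(counts, freqs)
    else:
        mean_off = float("nan")
    g = tbv_matrix(cohort, arch).mean(axis=2)  # env-averaged, (n, T)
    variances = {t: float(g[:, ti].var()) for ti, t in enumerate(TRAITS)}
    agg = float(sum(w * variances[t] for w, t in zip(weights, TRAITS)))
    return DiversityReport(
        mean_offdiag_grm=mean_off,
        n_alleles_fixed=naf,
        pct_alleles_fixed=pct,
        tbv_variance=variances,
        aggregate_tbv_variance=agg,
    )


# ---------------------------------------------------------------- GA selector


@dataclass
class GAParams:
    """Genetic-algorithm settings for the diversity-preserving selector."""

    pop_size: int = 2000
    iterations: int = 1000
    mutation: float = 0.001
    elite_fraction: float = 0.2


@dataclass
class ParentSet:
    """The selected parent subset and its fitness decomposition."""

    indices: np.ndarray
    ids: np.ndarray
    fitness: float
    mean_index: float
    mean_relationship: float
    n_alleles_fixed: int


@njit(cache=True)
def _popcount(x):
    c = 0
    while x:
        x &= x - np.uint64(1)
        c += 1
    return c


@njit(cache=True)
def _eval_subset(member, G, idx, mask0, mask1, k, lam1, lam2, members_buf):
    n = member.shape[0]
    W = mask0.shape[1]
    cnt = 0
    s_idx = 0.0
    for i in range(n):
        if member[i]:
            members_buf[cnt] = i
            s_idx += idx[i]
            cnt += 1
    rel = 0.0
    for a in range(cnt):
        ia = members_buf[a]
        for b in range(a + 1, cnt):
            rel += G[ia, members_buf[b]]
    rel = 2.0 * rel / (cnt * (cnt - 1)) if cnt > 1 else 0.0
    naf = 0
    for w in range(W):
        or0 = np.uint64(0)
        or1 = np.uint64(0)
        for a in range(cnt):
            or0 |= mask0[members_buf[a], w]
            or1 |= mask1[members_buf[a], w]
        # fixed loci lack one of the two alleles across the whole subset
        naf += _popcount(~(or0 & or1) & (or0 | or1))
    f = s_idx / cnt - lam1 * rel - lam2 * naf
    return f, s_idx / cnt, rel, naf


@njit(cache=True)
def _repair(member, idx, k):
    n = member.shape[0]
    cnt = 0
    for i in range(n):
        cnt += member[i]
    while cnt > k:  # drop the lowest-index member
        worst = -1
        wv = 1e300
        for i in range(n):
            if member[i] and idx[i] < wv:
                wv = idx[i]
                worst = i
        member[worst] = 0
        cnt -= 1
    while cnt < k:  # add the highest-index non-member
        best = -1
        bv = -1e300
        for i in range(n):
            if not member[i] and idx[i] > bv:
                bv = idx[i]
                best = i
        member[best] = 1
        cnt += 1


@njit(cache=True)
def _ga_kernel(G, idx, mask0, mask1, k, lam1, lam2,
               pop_size, iters, mut, elite_frac, seed, init, best_member, best_stats):
    np.random.seed(seed)
    n = G.shape[0]
    pop = init.copy()
    fit = np.empty(pop_size)
    buf = np.empty(k + n, dtype=np.int64)
    for i in range(pop_size):
        fit[i], _, _, _ = _eval_subset(pop[i], G, idx, mask0, mask1, k, lam1, lam2, buf)
    n_elite = max(2, int(elite_frac * pop_size))
    best_f = -1e300
    for _ in range(iters):
        order = np.argsort(-fit)
        if fit[order[0]] > best_f:
            best_f = fit[order[0]]
            best_member[:] = pop[order[0]]
        new_pop = np.empty_like(pop)
        new_fit = np.empty(pop_size)
        for e in range(n_elite):
            new_pop[e] = pop[order[e]]
            new_fit[e] = fit[order[e]]
        for o in range(n_elite, pop_size):
            pa = order[np.random.randint(0, n_elite)]
            pb = order[np.random.randint(0, n_elite)]
            cut = np.random.randint(1, n)
            child = new_pop[o]
            child[:cut] = pop[pa][:cut]
            child[cut:] = pop[pb][cut:]
            n_mut = np.random.binomial(n, mut)
            for _ in range(n_mut):
                j = np.random.randint(0, n)
                child[j] = 1 - child[j]
            _repair(child, idx, k)
            new_fit[o], _, _, _ = _eval_subset(
                child, G, idx, mask0, mask1, k, lam1, lam2, buf)
        pop = new_pop
        fit = new_fit
    order = np.argsort(-fit)
    if fit[order[0]] > best_f:
        best_f = fit[order[0]]
        best_member[:] = pop[order[0]]
    f, mi, rel, naf = _eval_subset(best_member, G, idx, mask0, mask1, k, lam1, lam2, buf)
    best_stats[0] = f
    best_stats[1] = mi
    best_stats[2] = rel
    best_stats[3] = naf


def _allele_masks(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Packed has-allele-0 / has-allele-1 bitmasks per individual."""
    has0 = counts <= 1
    has1 = counts >= 1
    W = (counts.shape[1] + 63) // 64
    pad = W * 64 - counts.shape[1]
    if pad:
        z = np.zeros((counts.shape[0], pad), dtype=bool)
        has0 = np.concatenate([has0, z], axis=1)
        has1 = np.concatenate([has1, z], axis=1)
    m0 = np.ascontiguousarray(np.packbits(has0, axis=1, bitorder="little"))
    m1 = np.ascontiguousarray(np.packbits(has1, axis=1, bitorder="little"))
    return (m0.view(np.uint64).reshape(counts.shape[0], W),
            m1.view(np.uint64).reshape(counts.shape[0], W))


def ga_select_parents(
    candidates: Population,
    index_values: np.ndarray,
    marker_loci: np.ndarray,
    n_parents: int = 150,
    lambda1: float = 1.0,
    lambda2: float = 1e-6,
    ga: GAParams | None = None,
    rng: np.random.Generator | None = None,
    freqs: np.ndarray | None = None,
) -> ParentSet:
    """Diversity-preserving parent selection via a genetic algorithm.

    Maximizes ``f = mean index - lambda1 * mean off-diagonal relationship -
    lambda2 * NAF`` over subsets of exactly ``n_parents`` candidates.  The
    initial GA population is seeded with the truncation-selection subset
    (so the penalty-free limit recovers plain top-n selection) plus random
    subsets; elitism keeps the best-ever subset.
    """
    ga = ga or GAParams()
    rng = rng or np.random.default_rng(0)
    n = len(candidates)
    if n < n_parents:
        raise ValueError("candidate pool smaller than the requested parent count")
    idx = np.asarray(index_values, dtype=np.float64)
    counts = candidates.allele_counts(marker_loci)
    G32, _ = grm(counts, freqs)
    G = np.ascontiguousarray(G32, dtype=np.float32)
    mask0, mask1 = _allele_masks(counts)

    init = np.zeros((ga.pop_size, n), dtype=np.uint8)
    trunc = truncate_select(idx, n_parents, candidates.ids)
    init[0, trunc] = 1
    for i in range(1, ga.pop_size):
        init[i, rng.choice(n, size=n_parents, replace=False)] = 1

    best_member = np.zeros(n, dtype=np.uint8)
    best_stats = np.zeros(4)
    seed = int(rng.integers(0, 2**31 - 1))
    _ga_kernel(
        G, idx, mask0, mask1, n_parents, float(lambda1), float(lambda2),
        int(ga.pop_size), int(ga.iterations), float(ga.mutation),
        float(ga.elite_fraction), seed, init, best_member, best_stats,
    )
    sel = np.flatnonzero(best_member)
    return ParentSet(
        indices=sel,
        ids=candidates.ids[sel],
        fitness=float(best_stats[0]),
        mean_index=float(best_stats[1]),
        mean_relationship=float(best_stats[2]),
        n_alleles_fixed=int(best_stats[3]),
    )
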