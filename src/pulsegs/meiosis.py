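"""Meiosis: gametes, crosses, selfing and single-seed descent.

Per chromosome the crossover count is Poisson(lambda = 1) with crossover
positions uniform on ``(0, chrom_length)`` — no interference, no obligate
crossover.  The gamete copies alternating parental haplotype segments
starting from a fair-coin choice of haplotype.  Mutation then flips each
locus allele independently with probability ``mutation_rate`` (default
0.001 per locus per gamete; both marker and QTL loci mutate).

The inner loop is a numba kernel; all randomness is driven by integer
seeds drawn from the caller's :class:`numpy.random.Generator`, so a run is
reproducible from its top-level seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .genmap import GeneticMap
from .population import Individual, Population

__all__ = [
    "DEFAULT_MUTATION_RATE",
    "make_gamete",
    "gametes",
    "cross",
    "cross_pairs",
    "self_line",
    "ssd_advance",
]

DEFAULT_MUTATION_RATE = 0.001


@njit(cache=True)
def _copy_gamete(hap0, hap1, out, positions, offsets, lengths):
    """Write one recombinant gamete of (hap0, hap1) into ``out``."""
    n_chrom = lengths.shape[0]
    for c in range(n_chrom):
        lo = offsets[c]
        hi = offsets[c + 1]
        k = np.random.poisson(1.0)
        cur = np.random.randint(0, 2)
        if k == 0:
            if cur == 0:
                out[lo:hi] = hap0[lo:hi]
            else:
                out[lo:hi] = hap1[lo:hi]
            continue
        xs = np.sort(np.random.uniform(0.0, lengths[c], k))
        start = lo
        for xi in range(k):
            cut = lo + np.searchsorted(positions[lo:hi], xs[xi])
            if cut > start:
                if cur == 0:
                    out[start:cut] = hap0[start:cut]
                else:
                    out[start:cut] = hap1[start:cut]
                start = cut
            cur = 1 - cur
        if start < hi:
            if cur == 0:
                out[start:hi] = hap0[start:hi]
            else:
                out[start:hi] = hap1[start:hi]


@njit(cache=True)
def _mutate(out, mutation_rate):
    n = out.shape[0]
    n_mut = np.random.binomial(n, mutation_rate)
    for _ in range(n_mut):
        j = np.random.randint(0, n)
        out[j] = 1 - out[j]


@njit(cache=True)
def _gametes_kernel(haps, parent_idx, positions, offsets, lengths, mutation_rate, seed, out):
    np.random.seed(seed)
    for g in range(parent_idx.shape[0]):
        p = parent_idx[g]
        _copy_gamete(haps[p, 0], haps[p, 1], out[g], positions, offsets, lengths)
        if mutation_rate > 0.0:
            _mutate(out[g], mutation_rate)


def gametes(
    pop: Population,
    parent_idx: np.ndarray,
    rng: np.random.Generator,
    mutation_rate: float = DEFAULT_MUTATION_RATE,
) -> np.ndarray:
    """One gamete per entry of ``parent_idx`` (indices into ``pop``)."""
    parent_idx = np.ascontiguousarray(parent_idx, dtype=np.int64)
    m = pop.map
    out = np.empty((len(parent_idx), m.n_loci), dtype=np.int8)
    seed = int(rng.integers(0, 2**31 - 1))
    _gametes_kernel(
        pop.haps, parent_idx, m.flat_positions, m.offsets, m.lengths,
        float(mutation_rate), seed, out,
    )
    return out


def make_gamete(
    parent: Individual,
    gmap: GeneticMap,
    rng: np.random.Generator,
    mutation_rate: float = DEFAULT_MUTATION_RATE,
) -> np.ndarray:
    """A single gamete from one individual (flat allele vector)."""
    if parent.haplotypes.shape[1] != gmap.n_loci:
        raise ValueError("parent does not conform to the map")
    haps = parent.haplotypes[np.newaxis]
    pop = Population(map=gmap, haps=haps, ids=np.array([parent.id]))
    return gametes(pop, np.zeros(1, dtype=np.int64), rng, mutation_rate)[0]


def cross_pairs(
    pop: Population,
    mother_idx: np.ndarray,
    father_idx: np.ndarray,
    rng: np.random.Generator,
    mutation_rate: float = DEFAULT_MUTATION_RATE,
    label: str = "F1",
    cycle: int = 0,
    family: np.ndarray | None = None,
) -> Population:
    """One progeny per (mother, father) pair; one gamete from each parent."""
    mother_idx = np.asarray(mother_idx, dtype=np.int64)
    father_idx = np.asarray(father_idx, dtype=np.int64)
    if mother_idx.shape != father_idx.shape:
        raise ValueError("pair index arrays must match")
    g_m = gametes(pop, mother_idx, rng, mutation_rate)
    g_f = gametes(pop, father_idx, rng, mutation_rate)
    haps = np.stack([g_m, g_f], axis=1)
    fam = family if family is not None else np.arange(len(mother_idx), dtype=np.int64)
    return Population(map=pop.map, haps=haps, generation_label=label, cycle=cycle, family=fam)


def cross(
    mother: Individual,
    father: Individual,
    n_progeny: int,
    gmap: GeneticMap,
    rng: np.random.Generator,
    mutation_rate: float = DEFAULT_MUTATION_RATE,
    label: str = "F1",
) -> Population:
    """``n_progeny`` offspring of a single mother x father cross."""
    haps = np.stack([mother.haplotypes, father.haplotypes], axis=0)
    pair_pop = Population(map=gmap, haps=haps, ids=np.array([mother.id, father.id]))
    zeros = np.zeros(n_progeny, dtype=np.int64)
    ones = np.ones(n_progeny, dtype=np.int64)
    fam = np.zeros(n_progeny, dtype=np.int64)
    return cross_pairs(pair_pop, zeros, ones, rng, mutation_rate, label=label, family=fam)


def self_line(
    ind: Individual,
    n_seeds: int,
    gmap: GeneticMap,
    rng: np.random.Generator,
    mutation_rate: float = DEFAULT_MUTATION_RATE,
    label: str = "self",
) -> Population:
    """Self-pollination: ``cross`` with mother = father."""
    return cross(ind, ind, n_seeds, gmap, rng, mutation_rate, label=label)


def self_population(
    pop: Population,
    rng: np.random.Generator,
    mutation_rate: float = DEFAULT_MUTATION_RATE,
    label: str | None = None,
) -> Population:
    """Self every individual once, carrying one seed forward per line."""
    idx = np.arange(len(pop), dtype=np.int64)
    out = cross_pairs(
        pop, idx, idx, rng, mutation_rate,
        label=label or pop.generation_label, cycle=pop.cycle, family=pop.family,
    )
    return out


def ssd_advance(
    pop: Population,
    n_generations: int,
    rng: np.random.Generator,
    mutation_rate: float = DEFAULT_MUTATION_RATE,
    label: str | None = None,
) -> Population:
    """Single-seed descent: chain ``n_generations`` single-seed selfings.

    Output line ``i`` descends from input line ``i``; family ids are kept.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    cur = pop
    for _ in range(n_generations):
        cur = self_population(cur, rng, mutation_rate, label=label)
    return cur
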