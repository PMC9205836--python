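"""Founder populations of fully inbred lines.

The reference breeding pool is a large set of fully homozygous inbred lines.
Real marker data can be loaded from VCF or a delimited genotype matrix (with
the standard call-rate >= 0.5 and MAF >= 0.01 filters and random subsampling
to a marker budget), or an emulated base population can be simulated:
ancestral allele frequencies are drawn from a symmetric Beta distribution, a
random-mating population is gene-dropped for a number of burn-in generations
to build within-chromosome linkage disequilibrium, and each line is finished
by doubling a single sampled gamete (instant full inbreeding).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genmap import GeneticMap, build_map
from .meiosis import cross_pairs, gametes
from .population import Population

__all__ = [
    "FounderPopulation",
    "DegeneratePopulationError",
    "simulate_founders",
    "load_genotypes",
    "write_matrix",
    "save_founders",
    "load_founders",
]

_CONTAINER_VERSION = 1


class DegeneratePopulationError(RuntimeError):
    """All loci lost their variation during founder construction."""


@dataclass
class FounderPopulation:
    """Fully inbred base lines plus the map they live on."""

    population: Population
    retained_loci: np.ndarray  # flat indices into the pre-filter map

    @property
    def map(self) -> GeneticMap:
        return self.population.map

    def __len__(self) -> int:
        return len(self.population)


def _prune_map(gmap: GeneticMap, keep: np.ndarray) -> GeneticMap:
    keep = np.sort(np.asarray(keep))
    chroms = gmap.chrom_of(keep)
    positions = tuple(
        gmap.flat_positions[keep[chroms == c]] for c in range(gmap.n_chromosomes)
    )
    if any(len(p) == 0 for p in positions):
        raise DegeneratePopulationError("a chromosome lost all of its loci")
    return GeneticMap(positions=positions, lengths=gmap.lengths)


def simulate_founders(
    gmap: GeneticMap | None = None,
    n_lines: int = 1568,
    burn_in_generations: int = 50,
    ancestral_maf_shape: float = 0.2,
    min_maf: float = 0.01,
    seed: int = 0,
) -> FounderPopulation:
    """Simulate a fully inbred base population on ``gmap``.

    Procedure: ancestral frequencies ~ Beta(shape, shape); gene-drop a
    random-mating population of ``2 * n_lines`` diploids for
    ``burn_in_generations`` meioses (mutation off); double one gamete per
    line; drop loci whose realized MAF is below ``min_maf``.
    """
    if n_lines < 2:
        raise ValueError("n_lines must be >= 2")
    if gmap is None:
        gmap = build_map(seed=seed)
    rng = np.random.default_rng(seed)
    n_loci = gmap.n_loci
    freqs = rng.beta(ancestral_maf_shape, ancestral_maf_shape, size=n_loci)

    n_pop = 2 * n_lines
    haps = (rng.random((n_pop, 2, n_loci)) < freqs).astype(np.int8)
    pop = Population(map=gmap, haps=haps, generation_label="ancestral")
    for _ in range(burn_in_generations):
        mothers = rng.permutation(n_pop).astype(np.int64)
        fathers = rng.permutation(n_pop).astype(np.int64)
        pop = cross_pairs(pop, mothers, fathers, rng, mutation_rate=0.0,
                          label="ancestral")

    line_parents = rng.integers(0, n_pop, size=n_lines)
    g = gametes(pop, line_parents, rng, mutation_rate=0.0)
    founder_haps = np.stack([g, g], axis=1)

    freq = g.mean(axis=0)
    maf = np.minimum(freq, 1.0 - freq)
    keep = np.flatnonzero(maf >= min_maf)
    if keep.size == 0:
        raise DegeneratePopulationError("all loci monomorphic after burn-in")
    pruned = _prune_map(gmap, keep)
    founders = Population(
        map=pruned, haps=founder_haps[:, :, keep], generation_label="founder"
    )
    return FounderPopulation(population=founders, retained_loci=keep)


def _apply_filters(
    counts: np.ndarray,
    missing: np.ndarray,
    min_call_rate: float,
    min_maf: float,
) -> np.ndarray:
    call_rate = 1.0 - missing.mean(axis=0)
    n_called = np.maximum((~missing).sum(axis=0), 1)
    with np.errstate(invalid="ignore"):
        freq = np.where(missing, 0, counts).sum(axis=0) / (2.0 * n_called)
    maf = np.minimum(freq, 1.0 - freq)
    return np.flatnonzero((call_rate >= min_call_rate) & (maf >= min_maf))


def _read_matrix(path: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    counts = df.to_numpy(dtype=float)
    missing = ~np.isfinite(counts)
    counts = np.where(missing, 0, counts).astype(np.int8)
    return counts, missing, list(df.columns)


def _read_vcf(path: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    from cyvcf2 import VCF

    vcf = VCF(path)
    rows, names = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        gt = np.asarray(var.gt_types)  # 0 hom-ref, 1 het, 2 missing, 3 hom-alt
        counts = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=-1)
        rows.append(counts)
        names.append(f"{var.CHROM}:{var.POS}")
    if not rows:
        raise ValueError("no biallelic SNPs found in VCF")
    mat = np.asarray(rows).T  # lines x loci
    missing = mat < 0
    return np.where(missing, 0, mat).astype(np.int8), missing, names


def load_genotypes(
    path: str,
    format: str = "matrix",
    min_call_rate: float = 0.5,
    min_maf: float = 0.01,
    max_markers: int | None = 30000,
    heterozygous: str = "missing",
    gmap: GeneticMap | None = None,
    seed: int = 0,
) -> FounderPopulation:
    """Load inbred-line genotypes, filter, and subsample the marker panel.

    Loci failing the call-rate (< ``min_call_rate``) or MAF (< ``min_maf``)
    filters are dropped; if more loci remain than ``max_markers``, a seeded
    uniform subsample is taken.  Heterozygous founder calls are rejected
    (``heterozygous="error"``) or set missing and re-drawn as homozygotes
    from the locus allele frequency (``"missing"``, the default).  Without a
    supplied ``gmap`` a uniform 1 cM-spaced map is synthesised per
    chromosome (genotype files carry no genetic-map positions).
    """
    if format == "matrix":
        counts, missing, names = _read_matrix(path)
    elif format == "vcf":
        counts, missing, names = _read_vcf(path)
    else:
        raise ValueError(f"unknown format: {format!r}")
    if counts.shape[0] < 2:
        raise ValueError("fewer than 2 lines in the input")

    het = counts == 1
    if het.any():
        if heterozygous == "error":
            raise ValueError("heterozygous founder calls present")
        missing = missing | het

    keep = _apply_filters(counts, missing, min_call_rate, min_maf)
    rng = np.random.default_rng(seed)
    if max_markers is not None and keep.size > max_markers:
        keep = np.sort(rng.choice(keep, size=max_markers, replace=False))
    if keep.size == 0:
        raise ValueError("no loci pass the filters")
    counts, missing = counts[:, keep], missing[:, keep]

    # fill remaining missing calls as homozygotes drawn at the locus frequency
    n_called = np.maximum((~missing).sum(axis=0), 1)
    freq = np.where(missing, 0, counts).sum(axis=0) / (2.0 * n_called)
    draws = (rng.random(counts.shape) < freq).astype(np.int8) * 2
    counts = np.where(missing, draws, counts)

    if gmap is None:
        chrom_names = [n.split(":")[0] for n in (names[i] for i in keep)]
        uniq = list(dict.fromkeys(chrom_names))
        sizes = [chrom_names.count(u) for u in uniq]
        positions = tuple(np.arange(1, s + 1, dtype=float) for s in sizes)
        gmap = GeneticMap(positions=positions, lengths=np.array([s + 1.0 for s in sizes]))
    else:
        gmap = _prune_map(gmap, keep)

    hap = (counts // 2).astype(np.int8)
    pop = Population(map=gmap, haps=np.stack([hap, hap], axis=1),
                     generation_label="founder")
    return FounderPopulation(population=pop, retained_loci=keep)


def write_matrix(path: str, pop: Population) -> None:
    """Write 0/1/2 allele counts as the delimited matrix dialect."""
    chroms = pop.map.chrom_of(np.arange(pop.map.n_loci))
    idx_in_chrom = np.arange(pop.map.n_loci) - pop.map.offsets[chroms]
    cols = [f"{c}:{i}" for c, i in zip(chroms, idx_in_chrom)]
    df = pd.DataFrame(pop.allele_counts(), index=pop.ids, columns=cols)
    df.to_csv(path)


def save_founders(path: str, fp: FounderPopulation) -> None:
    """Serialize founders + map to a single versioned binary container."""
    m = fp.map
    np.savez_compressed(
        path,
        version=np.array([_CONTAINER_VERSION]),
        haps=fp.population.haps,
        ids=fp.population.ids,
        retained=fp.retained_loci,
        lengths=m.lengths,
        offsets=m.offsets,
        flat_positions=m.flat_positions,
    )


def load_founders(path: str) -> FounderPopulation:
    with np.load(path) as z:
        if int(z["version"][0]) != _CONTAINER_VERSION:
            raise ValueError("unsupported founder container version")
        offs = z["offsets"]
        positions = tuple(
            z["flat_positions"][offs[c]:offs[c + 1]] for c in range(len(offs) - 1)
        )
        gmap = GeneticMap(positions=positions, lengths=z["lengths"])
        pop = Population(map=gmap, haps=z["haps"], ids=z["ids"],
                         generation_label="founder")
        return FounderPopulation(population=pop, retained_loci=z["retained"])
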