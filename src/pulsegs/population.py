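"""Array-backed populations of diploid individuals.

Genotypes are stored as a single ``int8`` array of shape ``(n, 2, L)`` — two
haplotypes per individual over the flat locus index of a
:class:`~pulsegs.genmap.GeneticMap`.  Breeding-program bookkeeping (ids,
stage labels, cycle, family of origin) rides along as parallel arrays.
Fully inbred lines simply carry two identical haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genmap import GeneticMap

__all__ = ["Population", "Individual", "concat"]

_ID_COUNTER = np.array([0], dtype=np.int64)


def _fresh_ids(n: int) -> np.ndarray:
    start = int(_ID_COUNTER[0])
    _ID_COUNTER[0] = start + n
    return np.arange(start, start + n, dtype=np.int64)


@dataclass
class Individual:
    """Read-only view of one member of a :class:`Population`."""

    id: int
    haplotypes: np.ndarray  # (2, L) int8
    generation_label: str
    cycle: int
    family_id: int

    @property
    def allele_counts(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0)

    def is_homozygous(self) -> bool:
        return bool(np.all(self.haplotypes[0] == self.haplotypes[1]))


@dataclass
class Population:
    """A cohort of diploid individuals sharing one genetic map."""

    map: GeneticMap
    haps: np.ndarray  # (n, 2, L) int8
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    generation_label: str = ""
    cycle: int = 0
    family: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.haps = np.ascontiguousarray(self.haps, dtype=np.int8)
        if self.haps.ndim != 3 or self.haps.shape[1] != 2:
            raise ValueError("haps must have shape (n, 2, L)")
        if self.haps.shape[2] != self.map.n_loci:
            raise ValueError("haplotype length must equal the map's locus count")
        n = self.haps.shape[0]
        if self.ids is None:
            self.ids = _fresh_ids(n)
        if self.family is None:
            self.family = np.full(n, -1, dtype=np.int64)
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.family = np.asarray(self.family, dtype=np.int64)
        if len(self.ids) != n or len(self.family) != n:
            raise ValueError("metadata arrays must match population size")

    def __len__(self) -> int:
        return self.haps.shape[0]

    def __getitem__(self, i: int) -> Individual:
        return Individual(
            id=int(self.ids[i]),
            haplotypes=self.haps[i],
            generation_label=self.generation_label,
            cycle=self.cycle,
            family_id=int(self.family[i]),
        )

    def allele_counts(self, loci: np.ndarray | None = None) -> np.ndarray:
        """Genotype matrix of 0/1/2 allele counts, ``(n, L)`` or ``(n, len(loci))``."""
        counts = self.haps.sum(axis=1, dtype=np.int8)
        return counts if loci is None else counts[:, loci]

    def subset(self, idx: np.ndarray, label: str | None = None) -> "Population":
        return Population(
            map=self.map,
            haps=self.haps[idx],
            ids=self.ids[idx],
            generation_label=self.generation_label if label is None else label,
            cycle=self.cycle,
            family=self.family[idx],
        )

    def is_fully_homozygous(self) -> bool:
        return bool(np.all(self.haps[:, 0, :] == self.haps[:, 1, :]))

    def allele_frequencies(self, loci: np.ndarray | None = None) -> np.ndarray:
        haps = self.haps if loci is None else self.haps[:, :, loci]
        return haps.mean(axis=(0, 1))


def concat(pops: list[Population], label: str | None = None) -> Population:
    """Stack populations (same map) into one cohort, preserving ids."""
    if not pops:
        raise ValueError("nothing to concatenate")
    m = pops[0].map
    for p in pops[1:]:
        if p.map is not m and p.map.n_loci != m.n_loci:
            raise ValueError("populations must share a map")
    return Population(
        map=m,
        haps=np.concatenate([p.haps for p in pops], axis=0),
        ids=np.concatenate([p.ids for p in pops]),
        generation_label=label or pops[0].generation_label,
        cycle=pops[0].cycle,
        family=np.concatenate([p.family for p in pops]),
    )
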