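"""Genetic map: the shared genome coordinate system.

All loci live on a purely genetic (centimorgan) map of ``n_chromosomes``
chromosomes.  Modules address a locus either as ``(chromosome, index)`` or as
a flat 0-based index into the concatenation of the per-chromosome position
arrays; :class:`GeneticMap` provides both views.  Physical (bp) coordinates
are never used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GeneticMap", "build_map"]


@dataclass(frozen=True)
class GeneticMap:
    """Positions (cM) of every locus on every chromosome.

    Parameters
    ----------
    positions
        One strictly increasing float array per chromosome, each value in
        ``[0, chrom_length]``.
    lengths
        Map length of each chromosome in centimorgans.
    """

    positions: tuple[np.ndarray, ...]
    lengths: np.ndarray

    # flat-view helpers, derived once
    offsets: np.ndarray = field(init=False, repr=False)
    flat_positions: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.lengths):
            raise ValueError("one length per chromosome required")
        for pos, ln in zip(self.positions, self.lengths):
            if ln <= 0:
                raise ValueError("chromosome length must be positive")
            if len(pos) == 0:
                raise ValueError("empty chromosome")
            if np.any(np.diff(pos) <= 0):
                raise ValueError("locus positions must be strictly increasing")
            if pos[0] < 0 or pos[-1] > ln:
                raise ValueError("locus positions must lie in [0, length]")
        counts = np.array([len(p) for p in self.positions], dtype=np.int64)
        object.__setattr__(self, "offsets", np.concatenate([[0], np.cumsum(counts)]))
        object.__setattr__(self, "flat_positions", np.concatenate(self.positions))

    @property
    def n_chromosomes(self) -> int:
        return len(self.positions)

    @property
    def n_loci(self) -> int:
        return int(self.offsets[-1])

    def locus_counts(self) -> np.ndarray:
        return np.diff(self.offsets)

    def chrom_of(self, flat_index: np.ndarray | int) -> np.ndarray | int:
        """Chromosome containing each flat locus index."""
        return np.searchsorted(self.offsets, flat_index, side="right") - 1

    def flat_index(self, chrom: int, index: int) -> int:
        return int(self.offsets[chrom]) + index


def build_map(
    n_chromosomes: int = 7,
    snp_range: tuple[int, int] = (3200, 5200),
    length_range: tuple[float, float] = (192.7, 429.7),
    seed: int = 0,
) -> GeneticMap:
    """Draw a genetic map with per-chromosome locus counts and lengths.

    Locus counts are drawn uniformly in ``snp_range`` (inclusive) and map
    lengths uniformly in ``length_range``; locus positions are uniform on
    ``(0, length)`` and sorted.  Deterministic given ``seed``.
    """
    if n_chromosomes <= 0:
        raise ValueError("n_chromosomes must be positive")
    lo, hi = int(snp_range[0]), int(snp_range[1])
    llo, lhi = float(length_range[0]), float(length_range[1])
    if lo <= 0 or hi < lo:
        raise ValueError("snp_range must be a positive ordered pair")
    if llo <= 0 or lhi < llo:
        raise ValueError("length_range must be a positive ordered pair")
    rng = np.random.default_rng(seed)
    counts = rng.integers(lo, hi + 1, size=n_chromosomes)
    lengths = rng.uniform(llo, lhi, size=n_chromosomes)
    positions = tuple(
        np.sort(rng.uniform(0.0, ln, size=int(c))) for c, ln in zip(counts, lengths)
    )
    return GeneticMap(positions=positions, lengths=lengths)
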