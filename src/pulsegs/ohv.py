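"""Optimal haploid value (OHV) scoring and OHV-driven cross selection.

The OHV scores a genotype by its best extractable fully inbred descendant:
each chromosome's marker panel is split into five contiguous segments, a
haplotype value HV = sum_k h_k beta_k is computed for both haplotypes of
every segment, and the OHV is the sum of the better HV per segment across
the genome.  Primary crosses are chosen by ranking all possible parent
pairs on the OHV index of the virtual F1 (for a pair, the per-segment best
over the four parental haplotypes) under a per-parent usage cap.  F1
intercross pairs are ranked by in-silico projection: virtual progeny are
selfed to F8 by single-seed descent (mutation off) and the pair is scored
by the mean (optionally mean + SD) of the progeny GEBV index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .genmap import GeneticMap
from .meiosis import _copy_gamete
from .population import Individual, Population
from .prediction import MarkerEffects, gebv
from .traits import INDEX_WEIGHTS, TRAITS

__all__ = [
    "SegmentScheme",
    "CrossCandidate",
    "build_segments",
    "haplotype_value",
    "ohv",
    "ohv_matrix",
    "ohv_index",
    "select_primary_crosses",
    "project_inbred_progeny",
    "select_intercrosses",
]


@dataclass(frozen=True)
class SegmentScheme:
    """Contiguous marker-index segments partitioning each chromosome's panel.

    ``bounds`` are offsets into the (sorted) marker panel; segment ``s``
    covers panel columns ``bounds[s]:bounds[s+1]``.  Within a chromosome
    segment sizes differ by at most one marker.
    """

    bounds: np.ndarray  # (n_segments + 1,)
    chrom_of_segment: np.ndarray

    @property
    def n_segments(self) -> int:
        return len(self.bounds) - 1


def build_segments(
    gmap: GeneticMap, marker_loci: np.ndarray, segments_per_chrom: int = 5
) -> SegmentScheme:
    marker_loci = np.sort(np.asarray(marker_loci))
    chroms = gmap.chrom_of(marker_loci)
    bounds = [0]
    chrom_of_segment = []
    for c in range(gmap.n_chromosomes):
        n_c = int(np.sum(chroms == c))
        if n_c < segments_per_chrom:
            raise ValueError("fewer markers than segments on a chromosome")
        sizes = np.full(segments_per_chrom, n_c // segments_per_chrom)
        sizes[: n_c % segments_per_chrom] += 1
        for s in sizes:
            bounds.append(bounds[-1] + int(s))
            chrom_of_segment.append(c)
    return SegmentScheme(
        bounds=np.asarray(bounds), chrom_of_segment=np.asarray(chrom_of_segment)
    )


def haplotype_value(
    hap: np.ndarray, beta: np.ndarray, segment: tuple[int, int]
) -> float:
    """HV = sum over segment loci of allele dose x marker effect."""
    a, b = segment
    return float(hap[a:b].astype(np.float64) @ beta[a:b])


def _segment_hv(haps_panel: np.ndarray, beta: np.ndarray, scheme: SegmentScheme) -> np.ndarray:
    """Per-haplotype segment HVs: (n, 2, S) from (n, 2, m) panel haplotypes."""
    weighted = haps_panel * beta.astype(np.float32)[None, None, :]
    return np.add.reduceat(weighted, scheme.bounds[:-1], axis=2)


def best_segment_values(
    pop: Population, effects: MarkerEffects, scheme: SegmentScheme
) -> np.ndarray:
    """Per-individual best-haplotype HV per segment and trait, (n, S, T)."""
    haps_panel = pop.haps[:, :, effects.marker_loci].astype(np.float32)
    out = np.empty((len(pop), scheme.n_segments, len(TRAITS)), dtype=np.float32)
    for ti in range(len(TRAITS)):
        hv = _segment_hv(haps_panel, effects.beta[:, ti], scheme)
        out[:, :, ti] = hv.max(axis=1)
    return out


def ohv_matrix(
    pop: Population, effects: MarkerEffects, scheme: SegmentScheme, doubling: bool = False
) -> np.ndarray:
    """OHV per individual and trait, ``(n, T)``."""
    best = best_segment_values(pop, effects, scheme)
    out = best.sum(axis=1).astype(np.float64)
    return 2.0 * out if doubling else out


def ohv(
    ind: Individual,
    effects: MarkerEffects,
    scheme: SegmentScheme,
    trait: str,
    gmap: GeneticMap,
    doubling: bool = False,
) -> float:
    """Sum over segments of the better haplotype value (one trait)."""
    pop = Population(map=gmap, haps=ind.haplotypes[np.newaxis], ids=np.array([ind.id]))
    return float(ohv_matrix(pop, effects, scheme, doubling)[0, TRAITS.index(trait)])


def ohv_index(
    per_trait: np.ndarray,
    weights: np.ndarray = INDEX_WEIGHTS,
    sds: np.ndarray | None = None,
) -> np.ndarray:
    """Cohort-standardized, weighted OHV index; zero-SD traits drop out."""
    per_trait = np.asarray(per_trait, dtype=np.float64)
    if sds is None:
        sds = per_trait.std(axis=0)
    sds = np.asarray(sds, dtype=np.float64)
    out = np.zeros(per_trait.shape[0])
    for ti in range(per_trait.shape[1]):
        if sds[ti] <= 0:
            warnings.warn(f"zero OHV variance for {TRAITS[ti]}; trait term dropped")
            continue
        out += weights[ti] * per_trait[:, ti] / sds[ti]
    return out


@dataclass
class CrossCandidate:
    """A scored parent pair (primary cross or F1 intercross)."""

    parents: tuple[int, int]  # indices into the candidate cohort
    parent_ids: tuple[int, int]
    score: float
    components: np.ndarray | None = None  # per-trait score parts
    score_sd: float = 0.0


def _pair_scores(best: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """OHV-index score for every ordered pair from per-individual segment bests.

    The virtual F1 of two parents holds the union of their haplotypes, so
    its best per-segment HV is the elementwise max of the parents' bests.
    Standardization uses the SD of single-parent OHVs per trait (a fixed,
    cohort-level scale).
    """
    n = best.shape[0]
    single = best.sum(axis=1)  # (n, T)
    sds = single.std(axis=0)
    score = np.zeros((n, n), dtype=np.float64)
    for ti in range(best.shape[2]):
        if sds[ti] <= 0:
            continue
        b = best[:, :, ti]
        pair = np.maximum(b[:, None, :], b[None, :, :]).sum(axis=2)
        score += weights[ti] / sds[ti] * pair
    return score


def select_primary_crosses(
    parents: Population,
    effects: MarkerEffects,
    scheme: SegmentScheme,
    n_crosses: int = 300,
    usage_cap: int = 4,
    weights: np.ndarray = INDEX_WEIGHTS,
) -> list[CrossCandidate]:
    """Greedy top crosses over all parent pairs under a usage cap.

    All C(n, 2) pairs are enumerated and scored by the virtual-F1 OHV
    index; pairs are accepted in descending score, skipping any that would
    push either parent past ``usage_cap`` uses, until ``n_crosses``.
    """
    n = len(parents)
    if usage_cap < np.inf and n_crosses > n * usage_cap // 2:
        raise ValueError("usage cap makes the requested cross count infeasible")
    best = best_segment_values(parents, effects, scheme)
    score = _pair_scores(best, weights)
    iu, ju = np.triu_indices(n, k=1)
    order = np.argsort(-score[iu, ju], kind="stable")
    usage = np.zeros(n, dtype=np.int64)
    out: list[CrossCandidate] = []
    used = set()

    def accept(i: int, j: int) -> None:
        usage[i] += 1
        usage[j] += 1
        used.add((i, j))
        out.append(CrossCandidate(
            parents=(i, j),
            parent_ids=(int(parents.ids[i]), int(parents.ids[j])),
            score=float(score[i, j]),
        ))

    # strict pass: distinct pairs under the cap; then allow repeating a pair
    # (two F1 plants of the same cross); finally relax the cap one use at a
    # time — the greedy can strand capacity when 2 n_crosses = n x cap.
    cap = usage_cap
    allow_dup = False
    while len(out) < n_crosses:
        before = len(out)
        for o in order:
            if len(out) == n_crosses:
                break
            i, j = int(iu[o]), int(ju[o])
            if usage[i] >= cap or usage[j] >= cap:
                continue
            if not allow_dup and (i, j) in used:
                continue
            accept(i, j)
        if len(out) == before:
            if not allow_dup:
                allow_dup = True
            else:
                cap += 1
    return out


@njit(cache=True)
def _project_kernel(
    hapA, hapB, beta, positions, offsets, lengths,
    n_virtual, n_self, seed, out_mean, out_sd,
):
    """Mean/SD of inbred-progeny scores for each candidate pair.

    For pair p: draw one gamete from each parent (the virtual intercross
    progeny), self it ``n_self`` times carrying a single seed forward, and
    score the final genotype with ``beta``.  Marker loci only; mutation off.
    """
    np.random.seed(seed)
    P = hapA.shape[0]
    m = hapA.shape[2]
    h0 = np.empty(m, dtype=np.int8)
    h1 = np.empty(m, dtype=np.int8)
    g0 = np.empty(m, dtype=np.int8)
    g1 = np.empty(m, dtype=np.int8)
    for p in range(P):
        s1 = 0.0
        s2 = 0.0
        shift = 0.0
        for v in range(n_virtual):
            _copy_gamete(hapA[p, 0], hapA[p, 1], h0, positions, offsets, lengths)
            _copy_gamete(hapB[p, 0], hapB[p, 1], h1, positions, offsets, lengths)
            for _ in range(n_self):
                _copy_gamete(h0, h1, g0, positions, offsets, lengths)
                _copy_gamete(h0, h1, g1, positions, offsets, lengths)
                h0[:] = g0
                h1[:] = g1
            sc = 0.0
            for j in range(m):
                sc += beta[j] * (h0[j] + h1[j])
            if v == 0:
                shift = sc  # shift-invariant variance accumulation
            d = sc - shift
            s1 += d
            s2 += d * d
        mean = s1 / n_virtual
        var = s2 / n_virtual - mean * mean
        out_mean[p] = shift + mean
        out_sd[p] = np.sqrt(var) if var > 0.0 else 0.0


@njit(cache=True)
def _mosaic_gamete(e0, s0, n0, e1, s1, n1, Lc, out_e, out_s, xs, k, cur, u_pos, xi):
    """Recombine two breakpoint-mosaic haplotypes into a gamete mosaic.

    A mosaic is (segment end positions in cM, source haplotype ids); the
    last end equals the chromosome length.  The crossover count ``k``
    (Poisson(1)), starting haplotype ``cur`` (fair coin) and raw uniform
    positions (``u_pos`` from cursor ``xi``) are pre-drawn by the caller.
    Runs in O(segments + crossovers) — no locus-level work.  Returns the
    output segment count and the advanced uniform cursor.
    """
    cap = out_e.shape[0]
    if k > xs.shape[0] - 1:
        k = xs.shape[0] - 1
    for i in range(k):  # insertion sort of the crossover positions
        x = u_pos[xi] * Lc
        xi += 1
        j = i
        while j > 0 and xs[j - 1] > x:
            xs[j] = xs[j - 1]
            j -= 1
        xs[j] = x
    xs[k] = Lc
    t = 0.0
    i0 = 0
    i1 = 0
    m = 0
    for bi in range(k + 1):
        b = xs[bi]
        if cur == 0:
            while i0 < n0 and e0[i0] <= t:
                i0 += 1
            while i0 < n0 and e0[i0] < b and m < cap - 1:
                if m > 0 and out_s[m - 1] == s0[i0]:
                    out_e[m - 1] = e0[i0]  # extend same-source segment
                else:
                    out_e[m] = e0[i0]
                    out_s[m] = s0[i0]
                    m += 1
                i0 += 1
            src = s0[min(i0, n0 - 1)]
        else:
            while i1 < n1 and e1[i1] <= t:
                i1 += 1
            while i1 < n1 and e1[i1] < b and m < cap - 1:
                if m > 0 and out_s[m - 1] == s1[i1]:
                    out_e[m - 1] = e1[i1]
                else:
                    out_e[m] = e1[i1]
                    out_s[m] = s1[i1]
                    m += 1
                i1 += 1
            src = s1[min(i1, n1 - 1)]
        if m > 0 and out_s[m - 1] == src:
            out_e[m - 1] = b
        else:
            out_e[m] = b
            out_s[m] = src
            m += 1
        t = b
        cur = 1 - cur
    return m, xi


@njit(cache=True)
def _mosaic_score(e, s, n, pref, positions, lo, hi):
    """Score a mosaic haplotype from per-source beta prefix sums."""
    sc = 0.0
    prev = lo
    for i in range(n):
        idx = lo + np.searchsorted(positions[lo:hi], e[i])
        sc += pref[s[i], idx] - pref[s[i], prev]
        prev = idx
    return sc


@njit(cache=True)
def _project_mosaic_kernel(
    hapA, hapB, beta, positions, offsets, lengths,
    n_virtual, n_self, counts, coins, u_pos, out_mean, out_sd,
):
    """Mosaic-representation projection: same stochastic model as
    :func:`_project_kernel`, tracking haplotypes as breakpoint mosaics of
    the four parental haplotypes instead of explicit locus arrays.  All
    randomness (crossover counts, start coins, raw uniform positions) is
    pre-drawn and consumed sequentially."""
    P = hapA.shape[0]
    m = hapA.shape[2]
    C = lengths.shape[0]
    cap = 512
    pref = np.empty((4, m + 1))
    one_e = np.empty(1)
    srcs = np.empty((4, 1), dtype=np.int64)
    for h in range(4):
        srcs[h, 0] = h
    h0_e = np.empty(cap); h0_s = np.empty(cap, dtype=np.int64)
    h1_e = np.empty(cap); h1_s = np.empty(cap, dtype=np.int64)
    g0_e = np.empty(cap); g0_s = np.empty(cap, dtype=np.int64)
    g1_e = np.empty(cap); g1_s = np.empty(cap, dtype=np.int64)
    xs = np.empty(64)
    ci = 0
    xi = 0
    for p in range(P):
        for h in range(2):
            accA = 0.0
            accB = 0.0
            pref[h, 0] = 0.0
            pref[2 + h, 0] = 0.0
            for j in range(m):
                accA += hapA[p, h, j] * beta[j]
                accB += hapB[p, h, j] * beta[j]
                pref[h, j + 1] = accA
                pref[2 + h, j + 1] = accB
        s1 = 0.0
        s2 = 0.0
        shift = 0.0
        for v in range(n_virtual):
            total = 0.0
            for c in range(C):
                lo = offsets[c]
                hi = offsets[c + 1]
                Lc = lengths[c]
                one_e[0] = Lc
                n_h0, xi = _mosaic_gamete(one_e, srcs[0], 1, one_e, srcs[1], 1,
                                          Lc, h0_e, h0_s, xs,
                                          counts[ci], coins[ci], u_pos, xi)
                ci += 1
                n_h1, xi = _mosaic_gamete(one_e, srcs[2], 1, one_e, srcs[3], 1,
                                          Lc, h1_e, h1_s, xs,
                                          counts[ci], coins[ci], u_pos, xi)
                ci += 1
                for _ in range(n_self):
                    n_g0, xi = _mosaic_gamete(h0_e, h0_s, n_h0, h1_e, h1_s, n_h1,
                                              Lc, g0_e, g0_s, xs,
                                              counts[ci], coins[ci], u_pos, xi)
                    ci += 1
                    n_g1, xi = _mosaic_gamete(h0_e, h0_s, n_h0, h1_e, h1_s, n_h1,
                                              Lc, g1_e, g1_s, xs,
                                              counts[ci], coins[ci], u_pos, xi)
                    ci += 1
                    for i in range(n_g0):
                        h0_e[i] = g0_e[i]
                        h0_s[i] = g0_s[i]
                    for i in range(n_g1):
                        h1_e[i] = g1_e[i]
                        h1_s[i] = g1_s[i]
                    n_h0 = n_g0
                    n_h1 = n_g1
                    # once both haplotypes are the same mosaic, every later
                    # gamete equals it — the chromosome is fixed; stop early
                    if n_h0 == n_h1:
                        same = True
                        for i in range(n_h0):
                            if h0_e[i] != h1_e[i] or h0_s[i] != h1_s[i]:
                                same = False
                                break
                        if same:
                            break
                total += _mosaic_score(h0_e, h0_s, n_h0, pref, positions, lo, hi)
                total += _mosaic_score(h1_e, h1_s, n_h1, pref, positions, lo, hi)
            if v == 0:
                shift = total  # shift-invariant variance accumulation
            d = total - shift
            s1 += d
            s2 += d * d
        mean = s1 / n_virtual
        var = s2 / n_virtual - mean * mean
        out_mean[p] = shift + mean
        out_sd[p] = np.sqrt(var) if var > 0.0 else 0.0


def _run_mosaic_projection(
    hapsA, hapsB, beta, positions, offsets, lengths,
    n_virtual, n_self, rng, chunk=2048,
):
    """Drive the mosaic kernel in pair chunks with bulk pre-drawn randomness."""
    P = hapsA.shape[0]
    out_mean = np.empty(P)
    out_sd = np.empty(P)
    C = len(lengths)
    per_pair = n_virtual * C * (2 + 2 * n_self)
    for start in range(0, P, chunk):
        end = min(P, start + chunk)
        units = (end - start) * per_pair
        counts = np.minimum(rng.poisson(1.0, size=units), 62).astype(np.int64)
        coins = rng.integers(0, 2, size=units, dtype=np.int64)
        u_pos = rng.random(int(counts.sum()))
        _project_mosaic_kernel(
            hapsA[start:end], hapsB[start:end], beta, positions, offsets,
            lengths, n_virtual, n_self, counts, coins, u_pos,
            out_mean[start:end], out_sd[start:end],
        )
    return out_mean, out_sd


_GEN_NUMBER = {"F2": 1, "F3": 2, "F4": 3, "F5": 4, "F6": 5, "F7": 6, "F8": 7}


def _panel_geometry(gmap: GeneticMap, marker_loci: np.ndarray):
    marker_loci = np.sort(np.asarray(marker_loci))
    positions = gmap.flat_positions[marker_loci]
    chroms = gmap.chrom_of(marker_loci)
    offsets = np.concatenate([[0], np.cumsum(np.bincount(chroms, minlength=gmap.n_chromosomes))])
    return positions, offsets.astype(np.int64)


def _index_beta(effects: MarkerEffects, sds: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Collapse per-trait effects into one index-scoring vector."""
    beta = np.zeros(effects.beta.shape[0])
    for ti in range(effects.beta.shape[1]):
        if sds[ti] > 0:
            beta += weights[ti] * effects.beta[:, ti] / sds[ti]
    return beta


def project_inbred_progeny(
    mother: Individual,
    father: Individual,
    effects: MarkerEffects,
    gmap: GeneticMap,
    rng: np.random.Generator,
    n_virtual: int = 20,
    target_gen: str = "F8",
    index_sds: np.ndarray | None = None,
    weights: np.ndarray = INDEX_WEIGHTS,
    backend: str = "mosaic",
) -> tuple[float, float]:
    """(mean, SD) of GEBV-index scores of virtual inbred descendants.

    The cross is advanced to ``target_gen`` by single-seed descent with an
    isolated random stream; mutation is off for projection.  The default
    backend tracks haplotypes as breakpoint mosaics; ``"explicit"`` runs
    the same model on explicit locus arrays (slower, used as a
    cross-check).
    """
    panel = effects.marker_loci
    hapA = mother.haplotypes[np.newaxis, :, :][:, :, panel]
    hapB = father.haplotypes[np.newaxis, :, :][:, :, panel]
    positions, offsets = _panel_geometry(gmap, panel)
    if index_sds is None:
        index_sds = np.ones(effects.beta.shape[1])
    beta = _index_beta(effects, index_sds, weights)
    n_self = _GEN_NUMBER[target_gen]
    if backend == "mosaic":
        out_mean, out_sd = _run_mosaic_projection(
            np.ascontiguousarray(hapA), np.ascontiguousarray(hapB), beta,
            positions, offsets, gmap.lengths, int(n_virtual), n_self, rng,
        )
    else:
        out_mean = np.empty(1)
        out_sd = np.empty(1)
        seed = int(rng.integers(0, 2**31 - 1))
        _project_kernel(
            np.ascontiguousarray(hapA), np.ascontiguousarray(hapB), beta,
            positions, offsets, gmap.lengths,
            int(n_virtual), n_self, seed, out_mean, out_sd,
        )
    return float(out_mean[0]), float(out_sd[0])


def select_intercrosses(
    f1s: Population,
    effects: MarkerEffects,
    rng: np.random.Generator,
    n_select: int = 200,
    criterion: str = "mean_plus_sd",
    n_virtual: int = 20,
    target_gen: str = "F8",
    prefilter_fraction: float = 1.0,
    weights: np.ndarray = INDEX_WEIGHTS,
    backend: str = "mosaic",
) -> list[CrossCandidate]:
    """Rank all F1 x F1 intercross pairs by projected inbred-progeny score.

    Enumerates all C(n, 2) pairs (optionally pre-filtered to the top
    fraction by mid-parent GEBV index), projects ``n_virtual`` virtual F8
    descendants per pair, and returns the top ``n_select`` by the chosen
    criterion (``mean_ohv`` = progeny mean; ``mean_plus_sd`` = mean + SD).
    """
    n = len(f1s)
    iu, ju = np.triu_indices(n, k=1)
    if len(iu) < n_select:
        raise ValueError("not enough F1 pairs for the requested intercross count")
    u = gebv(effects, f1s)  # (n, T)
    sds = u.std(axis=0)
    sds = np.where(sds > 0, sds, 1.0)
    idx = np.zeros(n)
    for ti in range(u.shape[1]):
        idx += weights[ti] * u[:, ti] / sds[ti]
    if prefilter_fraction < 1.0:
        mid = idx[iu] + idx[ju]
        keep_n = max(n_select, int(np.ceil(prefilter_fraction * len(iu))))
        keep = np.argsort(-mid, kind="stable")[:keep_n]
        iu, ju = iu[keep], ju[keep]

    panel = effects.marker_loci
    haps_panel = np.ascontiguousarray(f1s.haps[:, :, panel])
    positions, offsets = _panel_geometry(f1s.map, panel)
    beta = _index_beta(effects, sds, weights)
    if backend == "mosaic":
        out_mean, out_sd = _run_mosaic_projection(
            haps_panel[iu], haps_panel[ju], beta, positions, offsets,
            f1s.map.lengths, int(n_virtual), _GEN_NUMBER[target_gen], rng,
        )
    else:
        out_mean = np.empty(len(iu))
        out_sd = np.empty(len(iu))
        seed = int(rng.integers(0, 2**31 - 1))
        _project_kernel(
            haps_panel[iu], haps_panel[ju], beta, positions, offsets,
            f1s.map.lengths, int(n_virtual), _GEN_NUMBER[target_gen], seed,
            out_mean, out_sd,
        )
    if criterion == "mean_ohv":
        rank_score = out_mean
    elif criterion == "mean_plus_sd":
        rank_score = out_mean + out_sd
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    order = np.argsort(-rank_score, kind="stable")[:n_select]
    return [
        CrossCandidate(
            parents=(int(iu[o]), int(ju[o])),
            parent_ids=(int(f1s.ids[iu[o]]), int(f1s.ids[ju[o]])),
            score=float(rank_score[o]),
            score_sd=float(out_sd[o]),
        )
        for o in order
    ]
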