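"""Segmented optimal haploid values and OHV-driven cross selection."""

import itertools

import numpy as np
import pytest

from pulsegs.ohv import (
    CrossCandidate,
    SegmentScheme,
    build_segments,
    haplotype_value,
    ohv,
    ohv_index,
    ohv_matrix,
    project_inbred_progeny,
    select_intercrosses,
    select_primary_crosses,
)
from pulsegs.population import Population
from pulsegs.prediction import MarkerEffects, gebv


@pytest.fixture(scope="module")
def panel_effects(small_founders, small_panel):
    markers, _ = small_panel
    rng = np.random.default_rng(17)
    beta = rng.normal(size=(len(markers), 3)) * 0.2
    return MarkerEffects(beta=beta, intercept=np.zeros(3),
                         marker_loci=markers)


@pytest.fixture(scope="module")
def scheme(small_founders, small_panel):
    markers, _ = small_panel
    return build_segments(small_founders.map, markers, 5)


class TestHaplotypeValue:
    def test_hand_sum(self):
        hap = np.array([1, 0, 1], np.int8)
        beta = np.array([0.5, -1.0, 2.0])
        assert haplotype_value(hap, beta, (0, 3)) == 2.5

    def test_zero_haplotype(self):
        assert haplotype_value(np.zeros(5, np.int8), np.ones(5), (0, 5)) == 0.0

    def test_matches_loop_oracle(self, rng):
        hap = rng.integers(0, 2, 40).astype(np.int8)
        beta = rng.normal(size=40)
        a, b = 7, 23
        expected = sum(float(hap[k]) * beta[k] for k in range(a, b))
        assert np.isclose(haplotype_value(hap, beta, (a, b)), expected)


class TestOHV:
    def test_segments_partition_evenly(self, scheme, small_panel):
        markers, _ = small_panel
        sizes = np.diff(scheme.bounds)
        assert sizes.sum() == len(markers)
        for c in np.unique(scheme.chrom_of_segment):
            cs = sizes[scheme.chrom_of_segment == c]
            assert cs.max() - cs.min() <= 1
            assert len(cs) == 5

    def test_homozygote_ohv_equals_gebv(self, small_founders, panel_effects,
                                        scheme):
        pop = small_founders.population  # fully inbred
        o2 = ohv_matrix(pop, panel_effects, scheme, doubling=True)
        u = gebv(panel_effects, pop)
        np.testing.assert_allclose(o2, u, rtol=1e-4, atol=1e-4)

    def test_ohv_dominates_best_whole_haplotype(self, small_founders,
                                                panel_effects, scheme, rng):
        markers = panel_effects.marker_loci
        L = small_founders.map.n_loci
        haps = rng.integers(0, 2, size=(1000, 2, L)).astype(np.int8)
        pop = Population(map=small_founders.map, haps=haps)
        o = ohv_matrix(pop, panel_effects, scheme)
        hp = haps[:, :, markers].astype(np.float64)
        for ti in range(3):
            whole = (hp @ panel_effects.beta[:, ti]).max(axis=1)
            assert np.all(o[:, ti] >= whole - 1e-6)

    def test_single_segment_equals_best_haplotype(self, small_founders,
                                                  panel_effects, small_panel):
        markers, _ = small_panel
        one = build_segments(small_founders.map, markers,
                             segments_per_chrom=1)
        pop = small_founders.population.subset(np.arange(10))
        o = ohv_matrix(pop, panel_effects, one)
        hp = pop.haps[:, :, markers].astype(np.float64)
        # per-chromosome best haplotype, summed
        for ti in range(3):
            per_chrom = []
            for s in range(one.n_segments):
                a, b = one.bounds[s], one.bounds[s + 1]
                per_chrom.append(
                    (hp[:, :, a:b] @ panel_effects.beta[a:b, ti]).max(axis=1))
            np.testing.assert_allclose(o[:, ti], np.sum(per_chrom, axis=0),
                                       rtol=1e-4, atol=1e-4)

    def test_finer_nested_segmentation_never_lowers_ohv(self, small_founders,
                                                        panel_effects,
                                                        small_panel):
        markers, _ = small_panel
        coarse = build_segments(small_founders.map, markers, 2)
        # split every coarse segment in two -> nested refinement
        bounds = [0]
        chrom = []
        for s in range(coarse.n_segments):
            a, b = int(coarse.bounds[s]), int(coarse.bounds[s + 1])
            mid = (a + b) // 2
            bounds.extend([mid, b])
            chrom.extend([coarse.chrom_of_segment[s]] * 2)
        fine = SegmentScheme(bounds=np.array(bounds),
                             chrom_of_segment=np.array(chrom))
        rng = np.random.default_rng(3)
        haps = rng.integers(0, 2, size=(200, 2, small_founders.map.n_loci))
        pop = Population(map=small_founders.map, haps=haps.astype(np.int8))
        o_c = ohv_matrix(pop, panel_effects, coarse)
        o_f = ohv_matrix(pop, panel_effects, fine)
        assert np.all(o_f >= o_c - 1e-6)


class TestOHVIndex:
    def test_equal_standardized_values(self):
        v = np.array([[2.0, 4.0, 6.0], [4.0, 8.0, 12.0], [0.0, 0.0, 0.0]])
        idx = ohv_index(v)
        sds = v.std(axis=0)
        expected = (0.3 * v[:, 0] / sds[0] + 0.3 * v[:, 1] / sds[1]
                    + 0.4 * v[:, 2] / sds[2])
        np.testing.assert_allclose(idx, expected)

    def test_single_trait_weights(self):
        v = np.array([[1.0, 9.0, 9.0], [3.0, 1.0, 5.0]])
        idx = ohv_index(v, weights=np.array([1.0, 0.0, 0.0]))
        np.testing.assert_allclose(idx, v[:, 0] / v[:, 0].std())

    def test_zero_sd_trait_dropped_with_warning(self):
        v = np.array([[1.0, 5.0, 2.0], [2.0, 5.0, 4.0]])
        with pytest.warns(UserWarning):
            idx = ohv_index(v)
        assert np.isfinite(idx).all()


class TestPrimaryCrosses:
    def test_unconstrained_greedy_equals_sort(self, small_founders,
                                              panel_effects, scheme):
        pop = small_founders.population.subset(np.arange(12))
        out = select_primary_crosses(pop, panel_effects, scheme, n_crosses=5,
                                     usage_cap=np.inf)
        scores = [c.score for c in out]
        assert scores == sorted(scores, reverse=True)
        assert len({c.parents for c in out}) == 5

    def test_cap_one_uses_each_parent_once(self, small_founders,
                                           panel_effects, scheme):
        pop = small_founders.population.subset(np.arange(12))
        out = select_primary_crosses(pop, panel_effects, scheme, n_crosses=6,
                                     usage_cap=1)
        used = [p for c in out for p in c.parents]
        assert len(used) == len(set(used)) == 12

    def test_greedy_matches_exhaustive_on_toy(self, small_founders,
                                              panel_effects, scheme):
        """6 parents, cap 2, top 3 crosses: greedy equals brute force over
        all feasible 3-cross sets (frozen instance)."""
        pop = small_founders.population.subset(np.arange(6))
        out = select_primary_crosses(pop, panel_effects, scheme, n_crosses=3,
                                     usage_cap=2)
        greedy_total = sum(c.score for c in out)

        from pulsegs.ohv import _pair_scores, best_segment_values

        best = best_segment_values(pop, panel_effects, scheme)
        score = _pair_scores(best, np.array([0.3, 0.3, 0.4]))
        pairs = list(itertools.combinations(range(6), 2))
        best_total = -np.inf
        for combo in itertools.combinations(pairs, 3):
            usage = np.zeros(6)
            for i, j in combo:
                usage[i] += 1
                usage[j] += 1
            if usage.max() <= 2:
                best_total = max(best_total,
                                 sum(score[i, j] for i, j in combo))
        assert np.isclose(greedy_total, best_total)

    def test_infeasible_cap_rejected(self, small_founders, panel_effects,
                                     scheme):
        pop = small_founders.population.subset(np.arange(6))
        with pytest.raises(ValueError):
            select_primary_crosses(pop, panel_effects, scheme, n_crosses=10,
                                   usage_cap=1)


class TestProjection:
    def test_identical_homozygous_parents(self, small_founders,
                                          panel_effects, rng):
        pop = small_founders.population
        mean, sd = project_inbred_progeny(pop[0], pop[0], panel_effects,
                                          pop.map, rng, n_virtual=10)
        u = gebv(panel_effects, pop.subset(np.array([0])))
        sds = np.ones(3)
        expected = float((np.array([0.3, 0.3, 0.4]) / sds) @ u[0])
        assert sd == 0.0
        assert np.isclose(mean, expected, rtol=1e-5)

    @pytest.mark.parametrize("backend", ["mosaic", "explicit"])
    def test_mean_approaches_mid_parent(self, small_founders, panel_effects,
                                        backend, rng):
        """Additivity oracle: with mutation off the expected projected score
        is the mid-parent GEBV index."""
        pop = small_founders.population
        mean, sd = project_inbred_progeny(
            pop[0], pop[1], panel_effects, pop.map, rng, n_virtual=2000,
            backend=backend)
        u = gebv(panel_effects, pop.subset(np.array([0, 1])))
        w = np.array([0.3, 0.3, 0.4])
        mid = float((u @ w).mean())
        assert abs(mean - mid) < 3 * sd / np.sqrt(2000)

    def test_backends_agree_statistically(self, small_founders,
                                          panel_effects):
        pop = small_founders.population
        r1 = np.random.default_rng(5)
        r2 = np.random.default_rng(6)
        m1, s1 = project_inbred_progeny(pop[2], pop[3], panel_effects,
                                        pop.map, r1, n_virtual=3000,
                                        backend="mosaic")
        m2, s2 = project_inbred_progeny(pop[2], pop[3], panel_effects,
                                        pop.map, r2, n_virtual=3000,
                                        backend="explicit")
        se = np.sqrt(s1**2 / 3000 + s2**2 / 3000)
        assert abs(m1 - m2) < 4 * se
        assert abs(s1 - s2) < 0.1 * max(s1, s2) + 1e-9


class TestIntercrosses:
    def _f1_pool(self, small_founders, rng, n=10):
        from pulsegs.meiosis import cross_pairs

        pop = small_founders.population
        mi = rng.choice(len(pop), size=n, replace=False).astype(np.int64)
        fi = rng.choice(len(pop), size=n, replace=False).astype(np.int64)
        fi[fi == mi] = (fi[fi == mi] + 1) % len(pop)
        return cross_pairs(pop, mi, fi, rng, mutation_rate=0.0)

    def test_enumeration_is_exhaustive_and_deterministic(self, small_founders,
                                                         panel_effects):
        rng = np.random.default_rng(8)
        f1 = self._f1_pool(small_founders, rng)
        a = select_intercrosses(f1, panel_effects,
                                np.random.default_rng(42), n_select=5,
                                n_virtual=10)
        b = select_intercrosses(f1, panel_effects,
                                np.random.default_rng(42), n_select=5,
                                n_virtual=10)
        assert [c.parents for c in a] == [c.parents for c in b]
        assert len({c.parents for c in a}) == 5

    def test_criterion_mean_plus_sd(self, small_founders, panel_effects):
        rng = np.random.default_rng(9)
        f1 = self._f1_pool(small_founders, rng)
        sel = select_intercrosses(f1, panel_effects,
                                  np.random.default_rng(1), n_select=45,
                                  n_virtual=40, criterion="mean_plus_sd")
        # scores are mean + 1.0 * SD and sorted descending
        scores = [c.score for c in sel]
        assert scores == sorted(scores, reverse=True)

    def test_prefilter_keeps_requested_fraction(self, small_founders,
                                                panel_effects):
        rng = np.random.default_rng(10)
        f1 = self._f1_pool(small_founders, rng, n=12)
        sel = select_intercrosses(f1, panel_effects,
                                  np.random.default_rng(2), n_select=4,
                                  n_virtual=5, prefilter_fraction=0.2)
        assert len(sel) == 4

    def test_too_small_pool_rejected(self, small_founders, panel_effects):
        rng = np.random.default_rng(11)
        f1 = self._f1_pool(small_founders, rng, n=3)
        with pytest.raises(ValueError):
            select_intercrosses(f1, panel_effects, rng, n_select=10)


def test_ohv_scalar_wrapper(small_founders, panel_effects, scheme):
    pop = small_founders.population
    o = ohv(pop[0], panel_effects, scheme, "grain_yield", pop.map)
    om = ohv_matrix(pop.subset(np.array([0])), panel_effects, scheme)
    assert np.isclose(o, om[0, 2])
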