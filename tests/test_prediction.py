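"""Ridge marker effects, GEBVs, training assembly and prediction accuracy."""

import numpy as np
import pytest

from pulsegs.population import Population
from pulsegs.prediction import (
    MarkerEffects,
    TrainingArchive,
    TrainingSet,
    accuracy,
    add_f2_family_records,
    assemble_training,
    entry_mean_h2,
    estimate_marker_effects,
    gebv,
)
from pulsegs.traits import TRAITS, sample_architecture, tbv_matrix


def _training(X, y, cycle=0):
    n = X.shape[0]
    Y = np.tile(np.asarray(y, float)[:, None], (1, len(TRAITS)))
    return TrainingSet(X=X, Y=Y, cycles=np.full(n, cycle),
                       source=np.array(["stage_trial"] * n),
                       ids=np.arange(n, dtype=np.int64))


class TestRidge:
    def test_single_marker_shrinkage_formula(self):
        """y = 2 x at one varying marker: beta_k = 2 Sxx / (Sxx + lambda)."""
        rng = np.random.default_rng(0)
        n, m = 40, 10
        X = np.zeros((n, m), dtype=np.float32)
        X[:, 4] = rng.choice([0, 2], size=n)
        y = 2.0 * X[:, 4]
        h = 0.5
        tr = _training(X, y)
        eff = estimate_marker_effects(tr, np.arange(m),
                                      h2_eff={t: h for t in TRAITS})
        lam = m * (1 - h) / h
        xc = X[:, 4] - X[:, 4].mean()
        expected = 2.0 * (xc @ xc) / (xc @ xc + lam)
        assert np.isclose(eff.beta[4, 0], expected, rtol=1e-6)
        assert np.allclose(np.delete(eff.beta[:, 0], 4), 0.0)

    def test_record_order_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.choice([0, 2], size=(30, 25)).astype(np.float32)
        y = rng.normal(size=30)
        tr = _training(X, y)
        perm = rng.permutation(30)
        tr2 = _training(X[perm], y[perm])
        a = estimate_marker_effects(tr, np.arange(25))
        b = estimate_marker_effects(tr2, np.arange(25))
        np.testing.assert_allclose(a.beta, b.beta, atol=1e-8)

    def test_matches_dense_solver_oracle(self):
        """Closed-form backend equals an independent dense normal-equation
        solve on a 50 x 200 toy problem to 1e-8."""
        rng = np.random.default_rng(2)
        n, m = 50, 200
        X = rng.choice([0, 1, 2], size=(n, m)).astype(np.float32)
        y = rng.normal(size=n)
        h = 0.4
        eff = estimate_marker_effects(_training(X, y), np.arange(m),
                                      h2_eff={t: h for t in TRAITS})
        lam = m * (1 - h) / h
        Xc = (X - X.mean(axis=0)).astype(np.float64)
        yc = y - y.mean()
        oracle = np.linalg.solve(Xc.T @ Xc + lam * np.eye(m), Xc.T @ yc)
        np.testing.assert_allclose(eff.beta[:, 0], oracle, atol=1e-8)

    def test_gibbs_backend_agrees_with_closed_form(self):
        rng = np.random.default_rng(3)
        n, m = 100, 60
        X = rng.choice([0, 2], size=(n, m)).astype(np.float32)
        beta_true = rng.normal(size=m) * 0.3
        y = X @ beta_true + rng.normal(size=n)
        tr = _training(X, y)
        a = estimate_marker_effects(tr, np.arange(m))
        b = estimate_marker_effects(tr, np.arange(m), backend="gibbs",
                                    n_samples=4000,
                                    rng=np.random.default_rng(7))
        # posterior mean estimated by sampling: Monte-Carlo error only
        err = np.abs(a.beta[:, 0] - b.beta[:, 0])
        assert err.mean() < 0.05 * max(np.abs(a.beta[:, 0]).mean(), 0.01) + 0.02

    def test_constant_phenotypes_warn_and_zero(self):
        X = np.array([[0, 2], [2, 0], [0, 0]], dtype=np.float32)
        tr = _training(X, np.ones(3))
        with pytest.warns(UserWarning):
            eff = estimate_marker_effects(tr, np.arange(2))
        assert np.allclose(eff.beta, 0.0)

    def test_too_few_records_rejected(self):
        tr = _training(np.zeros((1, 3), np.float32), np.zeros(1))
        with pytest.raises(ValueError):
            estimate_marker_effects(tr, np.arange(3))


class TestGEBV:
    def test_zero_effects_zero_gebv(self, small_founders):
        eff = MarkerEffects(beta=np.zeros((5, 3)), intercept=np.zeros(3),
                            marker_loci=np.arange(5))
        u = gebv(eff, small_founders.population.allele_counts(np.arange(5)))
        assert np.all(u == 0)

    def test_matches_loop_oracle_and_linearity(self, small_founders,
                                               small_panel):
        markers, _ = small_panel
        rng = np.random.default_rng(4)
        beta = rng.normal(size=(len(markers), 3))
        eff = MarkerEffects(beta=beta, intercept=np.zeros(3),
                            marker_loci=markers)
        pop = small_founders.population
        u = gebv(eff, pop)
        counts = pop.allele_counts(markers)
        expected = sum(float(counts[7, k]) * beta[k, 1]
                       for k in range(len(markers)))
        assert np.isclose(u[7, 1], expected, rtol=1e-4)
        eff2 = MarkerEffects(beta=2 * beta, intercept=np.zeros(3),
                             marker_loci=markers)
        np.testing.assert_allclose(gebv(eff2, pop), 2 * u, rtol=1e-5)


class TestAssembleTraining:
    def _block(self, cycle, n=5):
        return _training(np.full((n, 4), cycle, np.float32),
                         np.full(n, cycle), cycle)

    def test_window_keeps_three_most_recent_available(self):
        arc = TrainingArchive()
        for c in range(1, 6):
            arc.add_stage(c, available_year=8.0 * c, records=self._block(c))
        tr = assemble_training(arc, now_year=40.0, window=3)
        assert sorted(set(tr.cycles)) == [3, 4, 5]
        tr1 = assemble_training(arc, now_year=40.0, window=1)
        assert sorted(set(tr1.cycles)) == [5]

    def test_calendar_gates_availability(self):
        arc = TrainingArchive()
        arc.add_stage(1, available_year=8.0, records=self._block(1))
        arc.add_stage(2, available_year=16.0, records=self._block(2))
        tr = assemble_training(arc, now_year=10.0)
        assert set(tr.cycles) == {1}

    def test_frozen_training_for_early_recycling(self):
        # phenotypes maturing after the horizon never enter the training set
        arc = TrainingArchive()
        for c in (1, 2, 3):
            arc.add_stage(c, available_year=8.0 * c, records=self._block(c))
        for c in (4, 5, 6):
            arc.add_stage(c, available_year=24.0 + (c - 4) + 8.5,
                          records=self._block(c))
        t4 = assemble_training(arc, now_year=24.0)
        t6 = assemble_training(arc, now_year=26.0)
        assert sorted(set(t4.cycles)) == sorted(set(t6.cycles)) == [1, 2, 3]

    def test_error_without_phenotyped_cycles(self):
        with pytest.raises(RuntimeError, match="warm-start"):
            assemble_training(TrainingArchive(), now_year=0.0)

    def test_f2_records_accumulate(self):
        arc = TrainingArchive()
        for c in (1, 2, 3):
            arc.add_stage(c, 8.0 * c, self._block(c))
        f2 = _training(np.full((2, 4), 9, np.float32), np.ones(2), 4)
        f2.source[:] = "f2_family"
        arc.add_f2(4, available_year=25.0, records=f2)
        tr = assemble_training(arc, now_year=26.0)
        assert (tr.source == "f2_family").sum() == 2


class TestF2FamilyRecords:
    def test_family_mean_genotype_and_identity(self, small_founders,
                                               small_panel, small_arch, rng):
        markers, _ = small_panel
        pop = small_founders.population
        fam_same = pop.subset(np.array([0, 0, 0]))
        two = pop.subset(np.array([1, 2]))
        empty = _training(np.empty((0, len(markers)), np.float32),
                          np.empty(0))
        out = add_f2_family_records(empty, [fam_same, two], small_arch,
                                    markers, rng, n_families=2)
        assert len(out) == 2
        counts = pop.allele_counts(markers)
        # a family of identical members records that member's genotype
        i_same = 0 if out.ids[0] == pop.ids[0] else 1
        np.testing.assert_allclose(out.X[i_same], counts[0])
        np.testing.assert_allclose(out.X[1 - i_same],
                                   counts[1:3].mean(axis=0))
        assert np.all((out.X >= 0) & (out.X <= 2))

    def test_requesting_too_many_families_warns(self, small_founders,
                                                small_panel, small_arch, rng):
        markers, _ = small_panel
        fam = small_founders.population.subset(np.array([0, 1]))
        empty = _training(np.empty((0, len(markers)), np.float32),
                          np.empty(0))
        with pytest.warns(UserWarning):
            out = add_f2_family_records(empty, [fam], small_arch, markers,
                                        rng, n_families=50)
        assert len(out) == 1


class TestAccuracy:
    def test_oracle_effects_give_unit_accuracy(self, small_founders,
                                               small_panel):
        """With the true QTL effects exposed as the marker panel, GEBV
        equals TBV and the correlation is exactly 1."""
        _, qtl_pool = small_panel
        arch = sample_architecture(
            small_founders.map, qtl_pool, n_qtl=40, overlap=1.0,
            env_cor={t: 1.0 for t in TRAITS}, seed=9,
            founders=small_founders.population)
        t = TRAITS[0]
        loci = arch.qtl_loci[(t, "env1")]
        beta = np.zeros((len(loci), 3))
        beta[:, 0] = arch.effects[(t, "env1")]
        eff = MarkerEffects(beta=beta, intercept=np.zeros(3),
                            marker_loci=loci)
        acc = accuracy(eff, small_founders.population, arch, t)
        assert acc > 0.999

    def test_random_effects_accuracy_near_zero(self, small_founders,
                                               small_panel, small_arch):
        markers, _ = small_panel
        accs = []
        for s in range(20):
            rng = np.random.default_rng(1000 + s)
            beta = rng.normal(size=(len(markers), 3))
            eff = MarkerEffects(beta=beta, intercept=np.zeros(3),
                                marker_loci=markers)
            accs.append(accuracy(eff, small_founders.population, small_arch,
                                 TRAITS[0]))
        mean = np.mean(accs)
        se = np.std(accs) / np.sqrt(len(accs))
        assert abs(mean) < 3 * se + 0.02

    def test_leave_cycle_out_enforced(self, small_founders, small_panel,
                                      small_arch):
        markers, _ = small_panel
        pop = small_founders.population
        eff = MarkerEffects(beta=np.zeros((len(markers), 3)),
                            intercept=np.zeros(3), marker_loci=markers,
                            training_ids=pop.ids[:10])
        with pytest.raises(ValueError, match="leak"):
            accuracy(eff, pop, small_arch, TRAITS[0])

    def test_accuracy_improves_with_training_size(self, small_founders,
                                                  small_panel, small_arch,
                                                  rng):
        """More training records give higher GEBV accuracy in expectation."""
        from pulsegs.traits import trial_entry_means

        markers, _ = small_panel
        pop = small_founders.population
        X = pop.allele_counts(markers).astype(np.float32)
        means = {20: [], 80: [], 160: []}
        for s in range(8):
            r = np.random.default_rng(50 + s)
            Y = trial_entry_means(pop, "stage_trial_2rep_2env", small_arch, r)
            for n in means:
                idx = r.choice(len(pop), size=n, replace=False)
                tr = TrainingSet(X=X[idx], Y=Y[idx], cycles=np.zeros(n),
                                 source=np.array(["stage_trial"] * n),
                                 ids=pop.ids[idx])
                eff = estimate_marker_effects(tr, markers)
                cohort = pop.subset(np.setdiff1d(np.arange(len(pop)), idx))
                means[n].append(accuracy(eff, cohort, small_arch, TRAITS[1]))
        m20, m80, m160 = (np.mean(means[k]) for k in (20, 80, 160))
        assert m20 < m80 < m160


def test_entry_mean_h2_formula():
    assert np.isclose(entry_mean_h2(0.5, 4), 4 * 0.5 / (1 + 3 * 0.5))
    assert entry_mean_h2(1.0, 4) == 1.0
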