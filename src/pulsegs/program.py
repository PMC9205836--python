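"""Breeding-program orchestration: PS and GS pipelines over cycles.

One breeding cycle runs from crossing to the selection of the next cycle's
parents.  The phenotypic-selection (PS) pipeline is: 150 parents by
phenotype index -> 300 primary crosses by random mating (usage cap 4) ->
20 F2 seeds per family -> family bulk-up to F5 -> 30% single-plant cull on
low seed yield -> 800 random lines to PYT -> 400 (phenotype index) ->
Stage 1 -> 200 -> Stage 2 -> 80 into the germplasm pool.  The genomic
pipeline replaces random mating with OHV-optimized crosses and F1
intercrosses, advances 4000 F2 seeds by single-seed descent to F6,
genotypes them, applies GEBV selection at the bulk-up exit, PYT and
Stage 2 (phenotype index at Stage 1), and recycles 80 parents to the pool
from a configurable stage (Stage 2, F6, F2 or F1).

The simulated calendar is the source of truth: early parent recycling
(F2/F1) launches a new crossing cycle every year (half year for F1) while
trial phenotypes need the full product track, so their training sets stay
frozen at the warm-start cycles — unless F2 family phenotyping refreshes
them.  Generation intervals per scenario reproduce the nine canonical
values (PS 8 y; GS SSD: 8.5/5/1/0.5 y; GS aSSD: 6/2.5/1/0.5 y for parents
from Stage 2, F6, F2, F1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import (
    GAParams,
    diversity_report,
    ga_select_parents,
    selection_index,
    truncate_select,
)
from .founders import simulate_founders
from .genmap import build_map
from .meiosis import cross_pairs, ssd_advance
from .ohv import build_segments, select_intercrosses, select_primary_crosses
from .population import Population, concat
from .prediction import (
    MarkerEffects,
    TrainingArchive,
    TrainingSet,
    accuracy,
    add_f2_family_records,
    assemble_training,
    estimate_marker_effects,
    gebv,
)
from .traits import (
    INDEX_WEIGHTS,
    TRAITS,
    TraitArchitecture,
    partition_loci,
    sample_architecture,
    trial_entry_means,
)

__all__ = [
    "ScenarioConfig",
    "Preset",
    "PRESETS",
    "SCENARIO_NAMES",
    "scenario",
    "timeline",
    "run_ps_cycle",
    "run_gs_cycle",
    "run_experiment",
    "per_year_rates",
]

# stage durations in years
_YEARS = {
    "crossing": 0.5,       # primary crosses -> F1 seed
    "f2": 0.5,             # F2 selfing (PS) or intercrossing + F2 seed (GS)
    "bulkup_ps": 4.0,      # family bulk-up F3-F5 + single-plant F5 evaluation
    "bulkup_ssd": 4.0,     # SSD F3-F6 in the field
    "bulkup_assd": 1.5,    # accelerated SSD F3-F6 in the glasshouse
    "genotyping": 0.5,     # genotype the bulk-up output, GEBV selection
    "pyt": 1.0,
    "stage1": 1.0,
    "stage2": 1.0,
}


@dataclass
class ScenarioConfig:
    """A fully specified breeding strategy."""

    name: str = "PS_STG2"
    selection_method: str = "PS"  # PS | GS
    bulkup: str = "family_bulkup"  # family_bulkup | SSD | aSSD
    parent_stage: str = "STG2"  # STG2 | F6 | F2 | F1
    n_parents: int = 150
    n_primary_crosses: int = 300
    parent_usage_cap: int = 4
    n_intercross_families: int = 200
    n_f1i_per_family: int = 10
    seeds_per_family: int = 20  # F2 seeds per intercross family (GS)
    ps_seeds_per_family: int = 20  # F2 seeds per F1 family (PS)
    f2_phenotyping: bool = False
    n_f2_phenotype_families: int = 50
    diversity_preservation: bool = False
    lambda1: float = 1.0
    lambda2: float = 1e-6
    ga: GAParams = field(default_factory=GAParams)
    pyt_size: int = 800
    stage1_size: int = 400
    stage2_size: int = 200
    pool_additions: int = 80
    f5_cull_fraction: float = 0.3
    single_plant_inflation: float = 2.0
    pyt_rep_fraction: float = 0.2
    training_per_cycle: int = 400
    training_window: int = 3
    intercross_prefilter: float = 1.0
    n_virtual_progeny: int = 20
    intercross_criterion: str = "mean_plus_sd"
    mutation_rate: float = 0.001
    segments_per_chrom: int = 5
    random_selection: bool = False  # diagnostic: drift-only advancement

    @property
    def generation_interval_years(self) -> float:
        return timeline(self)

    @property
    def product_track_years(self) -> float:
        """Crossing to the end of Stage 2 trials (training-phenotype lag)."""
        if self.selection_method == "PS":
            return _YEARS["crossing"] + _YEARS["f2"] + _YEARS["bulkup_ps"] + 3.0
        bulk = _YEARS["bulkup_ssd"] if self.bulkup == "SSD" else _YEARS["bulkup_assd"]
        return _YEARS["crossing"] + _YEARS["f2"] + bulk + _YEARS["genotyping"] + 3.0


SCENARIO_NAMES = (
    "PS_STG2",
    "GS_SSD_STG2", "GS_SSD_F6", "GS_SSD_F2", "GS_SSD_F1",
    "GS_aSSD_STG2", "GS_aSSD_F6", "GS_aSSD_F2", "GS_aSSD_F1",
)


def scenario(name: str, **overrides) -> ScenarioConfig:
    """Build one of the named scenarios (suffix ``_PH`` adds F2 family
    phenotyping, ``_DP`` the diversity-preservation GA)."""
    base = name
    opts: dict = {}
    if base.endswith("_PH"):
        base = base[:-3]
        opts["f2_phenotyping"] = True
    if base.endswith("_DP"):
        base = base[:-3]
        opts["diversity_preservation"] = True
    if base not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}")
    if base == "PS_STG2":
        opts.update(selection_method="PS", bulkup="family_bulkup", parent_stage="STG2")
    else:
        _, bulk, stage = base.split("_", 2)
        opts.update(selection_method="GS", bulkup=bulk, parent_stage=stage)
    opts.update(overrides)
    return ScenarioConfig(name=name, **opts)


def timeline(config: ScenarioConfig | str) -> float:
    """Generation interval in years: crossing to next-cycle parent selection."""
    if isinstance(config, str):
        config = scenario(config)
    if config.parent_stage == "F1":
        return _YEARS["crossing"]
    at_f2 = _YEARS["crossing"] + _YEARS["f2"]
    if config.parent_stage == "F2":
        return at_f2
    if config.selection_method == "PS":
        if config.parent_stage != "STG2":
            raise ValueError("PS recycles parents from Stage 2 only")
        return at_f2 + _YEARS["bulkup_ps"] + 3.0
    bulk = _YEARS["bulkup_ssd"] if config.bulkup == "SSD" else _YEARS["bulkup_assd"]
    if config.parent_stage == "F6":
        return at_f2 + bulk
    if config.parent_stage == "STG2":
        return at_f2 + bulk + _YEARS["genotyping"] + 3.0
    raise ValueError(f"unknown parent stage {config.parent_stage!r}")


# ------------------------------------------------------------------ presets


@dataclass
class Preset:
    """Problem sizes for an experiment (genome, founders, scenario overrides)."""

    n_chromosomes: int = 7
    snp_range: tuple[int, int] = (7800, 8600)
    length_range: tuple[float, float] = (192.7, 429.7)
    n_founders: int = 1568
    burn_in: int = 50
    n_markers: int = 30000
    n_qtl: int = 1000
    scenario_overrides: dict = field(default_factory=dict)


PRESETS = {
    # Maps are drawn larger than the marker panel: simulated loci host the
    # panel plus the reserved QTL pool, and the founder MAF filter prunes
    # roughly 40-45% of drawn loci under the Beta ancestral spectrum.
    "full": Preset(),
    # desk scale: small genome and cohorts for replicated desk runs
    "desk": Preset(
        snp_range=(750, 820),
        n_founders=500,
        burn_in=50,
        n_markers=2000,
        n_qtl=300,
        scenario_overrides=dict(
            seeds_per_family=5,
            n_f1i_per_family=5,
            ps_seeds_per_family=4,
            intercross_prefilter=0.1,
            ga=GAParams(pop_size=200, iterations=100),
        ),
    ),
}


# ------------------------------------------------------------------ state


@dataclass
class PoolState:
    """Germplasm pool plus the training archive of one program branch."""

    pool: Population
    pheno_means: np.ndarray  # (n_pool, T); NaN rows lack phenotypes
    archive: TrainingArchive
    effects: MarkerEffects | None = None
    effects_key: tuple | None = None

    def clone(self) -> "PoolState":
        return PoolState(
            pool=Population(
                map=self.pool.map,
                haps=self.pool.haps.copy(),
                ids=self.pool.ids.copy(),
                generation_label=self.pool.generation_label,
                family=self.pool.family.copy(),
            ),
            pheno_means=self.pheno_means.copy(),
            archive=TrainingArchive(
                stage_blocks=list(self.archive.stage_blocks),
                f2_blocks=list(self.archive.f2_blocks),
            ),
            effects=self.effects,
            effects_key=self.effects_key,
        )

    def add_lines(self, lines: Population, pheno: np.ndarray | None) -> None:
        self.pool = concat([self.pool, lines], label="pool")
        if pheno is None:
            pheno = np.full((len(lines), len(TRAITS)), np.nan)
        self.pheno_means = np.concatenate([self.pheno_means, pheno], axis=0)


@dataclass
class ExperimentContext:
    """Shared fixed inputs of one experiment replicate."""

    arch: TraitArchitecture
    markers: np.ndarray
    config: ScenarioConfig
    base_freqs: np.ndarray | None = None  # founder allele freqs at markers


# ---------------------------------------------------------------- selection


def _index_select(values: np.ndarray, n: int, ids: np.ndarray,
                  rng: np.random.Generator, random_selection: bool) -> np.ndarray:
    if random_selection:
        return rng.choice(len(values), size=n, replace=False)
    return truncate_select(selection_index(values), n, ids)


def _select_parents(state: PoolState, ctx: ExperimentContext,
                    rng: np.random.Generator, by: str) -> Population:
    cfg = ctx.config
    pool = state.pool
    if by == "random":
        idx = rng.choice(len(pool), size=cfg.n_parents, replace=False)
        return pool.subset(idx, label="parent")
    if by == "phenotype":
        values = state.pheno_means
        if np.isnan(values).any():
            raise RuntimeError("phenotype-based parent selection needs a fully "
                               "phenotyped pool")
        idx = _index_select(values, cfg.n_parents, pool.ids, rng, cfg.random_selection)
        return pool.subset(idx, label="parent")
    # GEBV-based (optionally GA diversity-preserving)
    u = gebv(state.effects, pool)
    if cfg.diversity_preservation:
        ps = ga_select_parents(
            pool, selection_index(u), ctx.markers, n_parents=cfg.n_parents,
            lambda1=cfg.lambda1, lambda2=cfg.lambda2, ga=cfg.ga, rng=rng,
            freqs=ctx.base_freqs,
        )
        return pool.subset(ps.indices, label="parent")
    idx = _index_select(u, cfg.n_parents, pool.ids, rng, cfg.random_selection)
    return pool.subset(idx, label="parent")


def _random_mating_pairs(n_parents: int, n_crosses: int, cap: int,
                         rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random pairs under a per-parent usage cap (no selfing)."""
    if 2 * n_crosses > n_parents * cap:
        raise ValueError("usage cap infeasible for the requested cross count")
    slots = np.repeat(np.arange(n_parents), cap)
    for _ in range(200):
        chosen = rng.choice(len(slots), size=2 * n_crosses, replace=False)
        pairs = slots[chosen].reshape(n_crosses, 2)
        if np.all(pairs[:, 0] != pairs[:, 1]):
            return pairs[:, 0], pairs[:, 1]
    raise RuntimeError("failed to draw self-free random pairs")


# ---------------------------------------------------------------- metrics


def _metrics_row(parents: Population, ctx: ExperimentContext, scenario_name: str,
                 replicate: int, cycle: int, year: float) -> dict:
    from .traits import tbv_matrix

    arch = ctx.arch
    g = tbv_matrix(parents, arch).mean(axis=2)  # (n, T) env-averaged
    gain = (g.mean(axis=0) - arch.base_mean) / arch.base_sd
    rep = diversity_report(parents, arch, ctx.markers, freqs=ctx.base_freqs)
    row = {
        "scenario": scenario_name, "replicate": replicate, "cycle": cycle,
        "year": year, "gain_aggregate": float(INDEX_WEIGHTS @ gain),
        "mean_rel": rep.mean_offdiag_grm, "pct_fixed": rep.pct_alleles_fixed,
        "naf": rep.n_alleles_fixed,
        "tbv_var_aggregate": rep.aggregate_tbv_variance,
    }
    for ti, t in enumerate(TRAITS):
        row[f"gain_{t}"] = float(gain[ti])
        row[f"tbv_var_{t}"] = rep.tbv_variance[t]
        row[f"acc_{t}"] = np.nan
    return row


# ---------------------------------------------------------------- trials


def _stage_entry_means(pop: Population, ctx: ExperimentContext,
                       rng: np.random.Generator) -> np.ndarray:
    return trial_entry_means(pop, "stage_trial_2rep_2env", ctx.arch, rng)


def _training_block(stage1_pop: Population, s1_means: np.ndarray,
                    stage2_idx: np.ndarray, s2_means: np.ndarray,
                    ctx: ExperimentContext, cycle: int) -> TrainingSet:
    """Training records of one cycle's advanced-trial lines.

    Default: the Stage-1 entrants with entry means over their Stage-1 and
    (for survivors) Stage-2 records; `training_per_cycle` at the Stage-2
    size restricts the block to Stage-2 entrants only.
    """
    Y = s1_means.copy()
    Y[stage2_idx] = 0.5 * (s1_means[stage2_idx] + s2_means)
    X = stage1_pop.allele_counts(ctx.markers).astype(np.float32)
    ids = stage1_pop.ids.copy()
    if ctx.config.training_per_cycle < len(stage1_pop):
        keep = stage2_idx[:ctx.config.training_per_cycle]
        X, Y, ids = X[keep], Y[keep], ids[keep]
    n = len(ids)
    return TrainingSet(
        X=X, Y=Y, cycles=np.full(n, cycle),
        source=np.array(["stage_trial"] * n), ids=ids,
    )


def _product_track(candidates: Population, ctx: ExperimentContext,
                   state: PoolState, rng: np.random.Generator, cycle: int,
                   year: float, genomic: bool
                   ) -> tuple[Population, np.ndarray]:
    """PYT -> Stage 1 -> Stage 2; archives the training block; returns the
    80 pool additions and their phenotype means."""
    cfg = ctx.config
    # PYT entry: PS takes a random subset upstream; GS selects on GEBV here
    if genomic:
        u = gebv(state.effects, candidates)
        idx = _index_select(u, cfg.pyt_size, candidates.ids, rng, cfg.random_selection)
        pyt = candidates.subset(idx, label="PYT")
        # GEBV selection at PYT (records not used for training)
        u = gebv(state.effects, pyt)
        idx = _index_select(u, cfg.stage1_size, pyt.ids, rng, cfg.random_selection)
    else:
        pyt = candidates
        means = trial_entry_means(pyt, "PYT_partial_rep", ctx.arch, rng,
                                  pyt_rep_fraction=cfg.pyt_rep_fraction)
        idx = _index_select(means, cfg.stage1_size, pyt.ids, rng, cfg.random_selection)
    stage1 = pyt.subset(idx, label="STG1")

    s1_means = _stage_entry_means(stage1, ctx, rng)
    idx2 = _index_select(s1_means, cfg.stage2_size, stage1.ids, rng,
                         cfg.random_selection)
    stage2 = stage1.subset(idx2, label="STG2")
    s2_means = _stage_entry_means(stage2, ctx, rng)

    block = _training_block(stage1, s1_means, idx2, s2_means, ctx, cycle)
    state.archive.add_stage(cycle, year + ctx.config.product_track_years, block)

    if genomic:
        u = gebv(state.effects, stage2)
        idx3 = _index_select(u, cfg.pool_additions, stage2.ids, rng,
                             cfg.random_selection)
    else:
        idx3 = _index_select(s2_means, cfg.pool_additions, stage2.ids, rng,
                             cfg.random_selection)
    additions = stage2.subset(idx3, label="STG2")
    add_pheno = 0.5 * (s1_means[idx2][idx3] + s2_means[idx3])
    return additions, add_pheno


# ---------------------------------------------------------------- PS cycle


def run_ps_cycle(state: PoolState, ctx: ExperimentContext,
                 rng: np.random.Generator, cycle: int, year: float,
                 replicate: int = 0, parents: Population | None = None) -> dict:
    """One phenotypic-selection cycle; mutates ``state``, returns metrics."""
    cfg = ctx.config
    if len(state.pool) < cfg.n_parents:
        raise ValueError("germplasm pool smaller than the parent count")
    if parents is None:
        by = "random" if cycle == 1 else "phenotype"
        parents = _select_parents(state, ctx, rng, by)
    row = _metrics_row(parents, ctx, cfg.name, replicate, cycle, year)

    mi, fi = _random_mating_pairs(len(parents), cfg.n_primary_crosses,
                                  cfg.parent_usage_cap, rng)
    f1 = cross_pairs(parents, mi, fi, rng, cfg.mutation_rate, label="F1",
                     cycle=cycle)
    # F2 seeds within F1 families
    k = cfg.ps_seeds_per_family
    f1_idx = np.repeat(np.arange(len(f1)), k)
    fam = np.repeat(np.arange(len(f1)), k)
    f2 = cross_pairs(f1, f1_idx, f1_idx, rng, cfg.mutation_rate, label="F2",
                     cycle=cycle, family=fam)
    # family bulk-up F2 -> F5: seeds drawn from random plants of the family
    cur = f2
    for gen_label in ("F3", "F4", "F5"):
        within = rng.integers(0, k, size=len(cur))
        parent_idx = (np.arange(len(cur)) // k) * k + within
        cur = cross_pairs(cur, parent_idx, parent_idx, rng, cfg.mutation_rate,
                          label=gen_label, cycle=cycle, family=cur.family)
    # 30% single-plant cull on low seed yield, then random PYT entry
    yield_pheno = trial_entry_means(
        cur, "single_plant", ctx.arch, rng,
        single_plant_inflation=cfg.single_plant_inflation,
    )[:, TRAITS.index("grain_yield")]
    n_keep = int(round((1.0 - cfg.f5_cull_fraction) * len(cur)))
    keep = truncate_select(yield_pheno, n_keep, cur.ids)
    survivors = cur.subset(keep, label="F5")
    pick = rng.choice(len(survivors), size=cfg.pyt_size, replace=False)
    pyt = survivors.subset(pick, label="PYT")

    additions, add_pheno = _product_track(pyt, ctx, state, rng, cycle, year,
                                          genomic=False)
    state.add_lines(additions, add_pheno)
    return row


# ---------------------------------------------------------------- GS cycle


def _fit_effects(state: PoolState, ctx: ExperimentContext, year: float,
                 cycle: int) -> None:
    cfg = ctx.config
    cycles = tuple(state.archive.available_stage_cycles(year)[-cfg.training_window:])
    n_f2 = sum(1 for _, yr, _ in state.archive.f2_blocks if yr <= year)
    key = (cycles, n_f2)
    if key == state.effects_key and state.effects is not None:
        return
    training = assemble_training(state.archive, year, cfg.training_window)
    state.effects = estimate_marker_effects(
        training, ctx.markers, fitted_at_cycle=cycle)
    state.effects_key = key


def _record_accuracy(row: dict, cohort: Population, state: PoolState,
                     ctx: ExperimentContext) -> None:
    for t in TRAITS:
        row[f"acc_{t}"] = accuracy(state.effects, cohort, ctx.arch, t)


def run_gs_cycle(state: PoolState, ctx: ExperimentContext,
                 rng: np.random.Generator, cycle: int, year: float,
                 replicate: int = 0, scheme=None) -> dict:
    """One genomic-selection cycle; mutates ``state``, returns metrics."""
    cfg = ctx.config
    _fit_effects(state, ctx, year, cycle)
    if state.effects is None:
        raise RuntimeError("marker effects unavailable; warm-start required")
    if scheme is None:
        scheme = build_segments(state.pool.map, ctx.markers, cfg.segments_per_chrom)

    parents = _select_parents(state, ctx, rng, by="gebv")
    row = _metrics_row(parents, ctx, cfg.name, replicate, cycle, year)

    crosses = select_primary_crosses(
        parents, state.effects, scheme, n_crosses=cfg.n_primary_crosses,
        usage_cap=cfg.parent_usage_cap)
    mi = np.array([c.parents[0] for c in crosses])
    fi = np.array([c.parents[1] for c in crosses])
    f1 = cross_pairs(parents, mi, fi, rng, cfg.mutation_rate, label="F1",
                     cycle=cycle)

    inter = select_intercrosses(
        f1, state.effects, rng, n_select=cfg.n_intercross_families,
        criterion=cfg.intercross_criterion, n_virtual=cfg.n_virtual_progeny,
        prefilter_fraction=cfg.intercross_prefilter)
    ia = np.repeat([c.parents[0] for c in inter], cfg.n_f1i_per_family)
    ib = np.repeat([c.parents[1] for c in inter], cfg.n_f1i_per_family)
    fam = np.repeat(np.arange(len(inter)), cfg.n_f1i_per_family)
    f1i = cross_pairs(f1, ia, ib, rng, cfg.mutation_rate, label="F1i",
                      cycle=cycle, family=fam)

    if cfg.parent_stage == "F1":
        u = gebv(state.effects, f1i)
        idx = _index_select(u, cfg.pool_additions, f1i.ids, rng,
                            cfg.random_selection)
        _record_accuracy(row, f1i, state, ctx)
        state.add_lines(f1i.subset(idx, label="F1i"), None)
        return row

    # F2 seeds: per family, seeds taken round-robin from its F1i plants
    per_plant = cfg.seeds_per_family // cfg.n_f1i_per_family
    extra = cfg.seeds_per_family % cfg.n_f1i_per_family
    plant_of_seed = []
    for f in range(len(inter)):
        base = f * cfg.n_f1i_per_family
        reps = np.full(cfg.n_f1i_per_family, per_plant)
        reps[:extra] += 1
        plant_of_seed.append(np.repeat(base + np.arange(cfg.n_f1i_per_family), reps))
    plant_of_seed = np.concatenate(plant_of_seed)
    fam2 = f1i.family[plant_of_seed]
    f2 = cross_pairs(f1i, plant_of_seed, plant_of_seed, rng, cfg.mutation_rate,
                     label="F2", cycle=cycle, family=fam2)

    if cfg.f2_phenotyping:
        families = [f2.subset(np.flatnonzero(fam2 == f))
                    for f in range(len(inter))]
        empty = TrainingSet(
            X=np.empty((0, len(ctx.markers)), dtype=np.float32),
            Y=np.empty((0, len(TRAITS))), cycles=np.empty(0, dtype=int),
            source=np.empty(0, dtype=object), ids=np.empty(0, dtype=np.int64))
        block = add_f2_family_records(
            empty, families, ctx.arch, ctx.markers, rng,
            n_families=min(cfg.n_f2_phenotype_families, len(families)),
            cycle=cycle)
        state.archive.add_f2(cycle, year + 1.0, block)

    if cfg.parent_stage == "F2":
        u = gebv(state.effects, f2)
        idx = _index_select(u, cfg.pool_additions, f2.ids, rng,
                            cfg.random_selection)
        _record_accuracy(row, f2, state, ctx)
        state.add_lines(f2.subset(idx, label="F2"), None)
        return row

    f6 = ssd_advance(f2, 4, rng, cfg.mutation_rate, label="F6")
    _record_accuracy(row, f6, state, ctx)

    if cfg.parent_stage == "F6":
        u = gebv(state.effects, f6)
        idx = _index_select(u, cfg.pool_additions, f6.ids, rng,
                            cfg.random_selection)
        state.add_lines(f6.subset(idx, label="F6"), None)
        # the product track still runs: it feeds future training sets
        _product_track(f6, ctx, state, rng, cycle, year, genomic=True)
        return row

    additions, add_pheno = _product_track(f6, ctx, state, rng, cycle, year,
                                          genomic=True)
    state.add_lines(additions, add_pheno)
    return row


# ------------------------------------------------------------- experiment


def _initial_state(founders: Population, ctx: ExperimentContext,
                   rng: np.random.Generator) -> PoolState:
    baseline = _stage_entry_means(founders, ctx, rng)
    return PoolState(pool=founders, pheno_means=baseline,
                     archive=TrainingArchive())


def run_experiment(
    scenarios: list[str],
    replicates: int = 50,
    base_seed: int = 0,
    preset: str = "desk",
    n_cycles: int = 8,
    gs_start_cycle: int = 4,
    overrides: dict | None = None,
) -> pd.DataFrame:
    """Replicated comparison of breeding scenarios from a common warm start.

    Per replicate: 150 cycle-1 parents are resampled from the base
    population, PS runs cycles 1..3, and every requested scenario branches
    from the end of PS cycle 3 with its own random stream.  The PS
    benchmark is always simulated.  Returns tidy per-cycle metrics
    (the row at ``n_cycles + 1`` records the final parent selection).
    """
    pre = PRESETS[preset]
    master = np.random.SeedSequence(base_seed)
    s_map, s_found, *_ = master.spawn(4)
    gmap = build_map(pre.n_chromosomes, pre.snp_range, pre.length_range,
                     seed=int(s_map.generate_state(1)[0] % 2**31))
    fp = simulate_founders(gmap, n_lines=pre.n_founders, burn_in_generations=pre.burn_in,
                           seed=int(s_found.generate_state(1)[0] % 2**31))
    founders = fp.population
    markers, qtl_pool = partition_loci(
        founders.map, pre.n_markers,
        seed=int(master.spawn(1)[0].generate_state(1)[0] % 2**31))
    base_freqs = founders.allele_frequencies(markers).astype(np.float64)

    names = list(dict.fromkeys(["PS_STG2"] + list(scenarios)))
    all_over = dict(pre.scenario_overrides)
    all_over.update(overrides or {})
    rows: list[dict] = []

    for r in range(replicates):
        rep_seq = np.random.SeedSequence(entropy=base_seed, spawn_key=(100 + r,))
        seeds = rep_seq.spawn(3 + len(names))
        arch = sample_architecture(
            founders.map, qtl_pool, n_qtl=pre.n_qtl,
            seed=int(seeds[0].generate_state(1)[0] % 2**31), founders=founders)

        ps_cfg = scenario("PS_STG2", **{k: v for k, v in all_over.items()
                                        if k in ScenarioConfig.__dataclass_fields__})
        ps_ctx = ExperimentContext(arch=arch, markers=markers, config=ps_cfg,
                                   base_freqs=base_freqs)
        rng_warm = np.random.default_rng(seeds[1])
        state = _initial_state(founders, ps_ctx, rng_warm)
        warm_rows = []
        for c in range(1, gs_start_cycle):
            yr = (c - 1) * timeline(ps_cfg)
            warm_rows.append(run_ps_cycle(state, ps_ctx, rng_warm, c, yr, r))
        snapshot = state
        branch_year0 = (gs_start_cycle - 1) * timeline(ps_cfg)

        for si, name in enumerate(names):
            cfg = scenario(name, **{k: v for k, v in all_over.items()
                                    if k in ScenarioConfig.__dataclass_fields__})
            ctx = ExperimentContext(arch=arch, markers=markers, config=cfg,
                                    base_freqs=base_freqs)
            st = snapshot.clone()
            rng_b = np.random.default_rng(seeds[3 + si])
            interval = timeline(cfg)
            scheme = (build_segments(founders.map, markers, cfg.segments_per_chrom)
                      if cfg.selection_method == "GS" else None)
            if cfg.selection_method == "PS":
                rows.extend(dict(w, scenario=cfg.name) for w in warm_rows)
            for c in range(gs_start_cycle, n_cycles + 1):
                yr = branch_year0 + (c - gs_start_cycle) * interval
                if cfg.selection_method == "PS":
                    rows.append(run_ps_cycle(st, ctx, rng_b, c, yr, r))
                else:
                    rows.append(run_gs_cycle(st, ctx, rng_b, c, yr, r,
                                             scheme=scheme))
            # terminal parent selection closes the gain series
            yr = branch_year0 + (n_cycles + 1 - gs_start_cycle) * interval
            if cfg.selection_method == "PS":
                parents = _select_parents(st, ctx, rng_b, by="phenotype")
            else:
                _fit_effects(st, ctx, yr, n_cycles + 1)
                parents = _select_parents(st, ctx, rng_b, by="gebv")
            rows.append(_metrics_row(parents, ctx, cfg.name, r, n_cycles + 1, yr))
    return pd.DataFrame(rows)


def per_year_rates(metrics: pd.DataFrame, start_cycle: int = 4) -> pd.DataFrame:
    """Annual rates over the GS phase and percentage comparisons vs PS.

    Rate = (end - start of the metric) / elapsed years per replicate,
    averaged; ``pct_vs_ps`` = (rate - rate_PS) / rate_PS x 100 on the
    aggregate-gain rate.
    """
    end_cycle = metrics["cycle"].max()
    out = []
    for (name, rep), grp in metrics.groupby(["scenario", "replicate"]):
        g = grp.set_index("cycle")
        if start_cycle not in g.index or end_cycle not in g.index:
            continue
        years = g.loc[end_cycle, "year"] - g.loc[start_cycle, "year"]
        if years <= 0:
            raise ValueError("zero elapsed years in the reporting window")
        row = {"scenario": name, "replicate": rep}
        for col in ("gain_aggregate", "mean_rel", "pct_fixed",
                    "tbv_var_aggregate"):
            row[f"rate_{col}"] = (g.loc[end_cycle, col] - g.loc[start_cycle, col]) / years
        out.append(row)
    per_rep = pd.DataFrame(out)
    summary = per_rep.groupby("scenario").mean(numeric_only=True).drop(
        columns=["replicate"]).reset_index()
    ps = summary.loc[summary["scenario"] == "PS_STG2", "rate_gain_aggregate"]
    if len(ps) and ps.iloc[0] != 0:
        summary["pct_vs_ps"] = (
            (summary["rate_gain_aggregate"] - ps.iloc[0]) / ps.iloc[0] * 100.0)
    return summary
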