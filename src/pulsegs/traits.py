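"""Multi-trait, multi-environment QTL architecture, breeding values, trials.

Three traits (disease resistance, grain weight, grain yield; narrow-sense
heritabilities 0.5 / 0.75 / 0.25) are simulated in two environments.  Each
trait x environment combination is controlled by ~``n_qtl`` additive QTL
with N(0, 1) substitution effects.  Seventy per cent of QTL loci are shared
between traits within an environment and between environments within a
trait; effect pairs of QTL shared across environments are correlated (0.8
for disease resistance and grain weight, 0.4 for grain yield — a high level
of GxE), while effects are independent between traits.

The true breeding value is g = M a (allele counts times effects).  A plot
phenotype adds a residual with variance sigma_e^2 = ((1 - h2)/h2) sigma_g^2,
where sigma_g^2 is frozen at the founder-population additive variance so
residual noise does not shrink as selection depletes variance.  Genetic
gains are reported in units of the founder population's additive SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genmap import GeneticMap
from .population import Individual, Population

__all__ = [
    "TRAITS",
    "ENVS",
    "INDEX_WEIGHTS",
    "DEFAULT_H2",
    "DEFAULT_ENV_COR",
    "TraitArchitecture",
    "partition_loci",
    "sample_architecture",
    "tbv",
    "tbv_matrix",
    "phenotype",
    "run_trial",
    "trial_entry_means",
]

TRAITS = ("disease_resistance", "grain_weight", "grain_yield")
ENVS = ("env1", "env2")
INDEX_WEIGHTS = np.array([0.3, 0.3, 0.4])
DEFAULT_H2 = {"disease_resistance": 0.5, "grain_weight": 0.75, "grain_yield": 0.25}
DEFAULT_ENV_COR = {"disease_resistance": 0.8, "grain_weight": 0.8, "grain_yield": 0.4}


@dataclass
class TraitArchitecture:
    """QTL loci and effects per (trait, environment), plus base-population scale."""

    qtl_loci: dict[tuple[str, str], np.ndarray]
    effects: dict[tuple[str, str], np.ndarray]
    h2: dict[str, float]
    env_cor: dict[str, float]
    overlap: float
    # founder-population calibration (filled by `calibrate`)
    sigma_g2: dict[tuple[str, str], float] = field(default_factory=dict)
    base_mean: np.ndarray | None = None  # per trait, env-averaged TBV
    base_sd: np.ndarray | None = None

    @property
    def all_qtl(self) -> np.ndarray:
        return np.unique(np.concatenate(list(self.qtl_loci.values())))

    def calibrate(self, founders: Population) -> "TraitArchitecture":
        """Freeze base-population variances and the gain unit on ``founders``."""
        g = tbv_matrix(founders, self)  # (n, T, E)
        for ti, t in enumerate(TRAITS):
            for ei, e in enumerate(ENVS):
                self.sigma_g2[(t, e)] = float(g[:, ti, ei].var())
        env_avg = g.mean(axis=2)
        self.base_mean = env_avg.mean(axis=0)
        self.base_sd = env_avg.std(axis=0)
        if np.any(self.base_sd <= 0):
            raise ValueError("founder population has zero additive variance")
        return self

    def residual_sd(self, trait: str, env: str, h2: float | None = None) -> float:
        h = self.h2[trait] if h2 is None else h2
        if not 0 < h <= 1:
            raise ValueError("h2 must lie in (0, 1]")
        return float(np.sqrt((1.0 - h) / h * self.sigma_g2[(trait, env)]))


def partition_loci(
    gmap: GeneticMap, n_markers: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Split map loci into a marker panel and the reserved QTL pool.

    QTL are simulated loci excluded from the prediction panel; markers act
    on predictions only through linkage disequilibrium with QTL.
    """
    if n_markers >= gmap.n_loci:
        raise ValueError("marker panel must leave loci free for QTL")
    rng = np.random.default_rng(seed)
    markers = np.sort(rng.choice(gmap.n_loci, size=n_markers, replace=False))
    pool = np.setdiff1d(np.arange(gmap.n_loci), markers)
    return markers, pool


def sample_architecture(
    gmap: GeneticMap,
    qtl_pool: np.ndarray,
    n_qtl: int = 1000,
    overlap: float = 0.7,
    h2: dict[str, float] | None = None,
    env_cor: dict[str, float] | None = None,
    seed: int = 0,
    founders: Population | None = None,
) -> TraitArchitecture:
    """Sample QTL loci and effects under the nested overlap scheme.

    Loci are drawn without replacement from ``qtl_pool`` into blocks:
    a core shared by all traits and both environments (fraction
    ``overlap**2`` of each set), trait-shared/env-specific and
    trait-specific/env-shared blocks (fraction ``overlap * (1 - overlap)``
    each) and fully private remainders — which realises the ``overlap``
    locus-sharing rate simultaneously for every trait pair within an
    environment and for the environment pair within every trait.  Effects
    are N(0, 1); pairs at env-shared loci are bivariate normal with the
    trait's environmental correlation; effects are independent between
    traits everywhere.
    """
    h2 = dict(DEFAULT_H2 if h2 is None else h2)
    env_cor = dict(DEFAULT_ENV_COR if env_cor is None else env_cor)
    s = float(overlap)
    if not 0 <= s <= 1:
        raise ValueError("overlap must be a fraction")
    r1 = round(s * s * n_qtl)
    r2 = round(s * (1 - s) * n_qtl)
    r3 = r2
    r4 = n_qtl - r1 - r2 - r3
    T = len(TRAITS)
    need = r1 + 2 * r2 + T * (r3 + 2 * r4)
    if need > len(qtl_pool):
        raise ValueError(
            f"QTL pool too small: need {need} loci, have {len(qtl_pool)}"
        )
    rng = np.random.default_rng(seed)
    drawn = rng.choice(qtl_pool, size=need, replace=False)
    it = iter(np.split(drawn, np.cumsum([r1, r2, r2] + [r3, r4, r4] * T)[:-1]))
    b_core = next(it)          # all traits, both envs
    b_env = [next(it), next(it)]  # all traits, env-specific
    b_trait, b_trait_env = [], []
    for _ in TRAITS:
        b_trait.append(next(it))             # trait-specific, both envs
        b_trait_env.append([next(it), next(it)])

    qtl_loci: dict[tuple[str, str], np.ndarray] = {}
    effects: dict[tuple[str, str], np.ndarray] = {}
    for ti, t in enumerate(TRAITS):
        rho = env_cor[t]
        cov = np.array([[1.0, rho], [rho, 1.0]])
        shared = np.concatenate([b_core, b_trait[ti]])
        eff_shared = rng.multivariate_normal([0, 0], cov, size=len(shared))
        for ei, e in enumerate(ENVS):
            private = np.concatenate([b_env[ei], b_trait_env[ti][ei]])
            eff_private = rng.standard_normal(len(private))
            qtl_loci[(t, e)] = np.concatenate([shared, private])
            effects[(t, e)] = np.concatenate([eff_shared[:, ei], eff_private])

    arch = TraitArchitecture(
        qtl_loci=qtl_loci, effects=effects, h2=h2, env_cor=env_cor, overlap=s
    )
    if founders is not None:
        arch.calibrate(founders)
    return arch


def tbv_matrix(pop: Population, arch: TraitArchitecture) -> np.ndarray:
    """True breeding values, shape ``(n, n_traits, n_envs)``."""
    counts = pop.haps.sum(axis=1)  # (n, L) int8
    out = np.empty((len(pop), len(TRAITS), len(ENVS)))
    for ti, t in enumerate(TRAITS):
        for ei, e in enumerate(ENVS):
            loci = arch.qtl_loci[(t, e)]
            out[:, ti, ei] = counts[:, loci].astype(np.float64) @ arch.effects[(t, e)]
    return out


def tbv(ind: Individual, arch: TraitArchitecture, trait: str, environment: str) -> float:
    """g = M a for one individual: sum of allele count x effect over QTL."""
    counts = ind.allele_counts[arch.qtl_loci[(trait, environment)]]
    return float(counts.astype(np.float64) @ arch.effects[(trait, environment)])


def phenotype(
    ind: Individual,
    arch: TraitArchitecture,
    trait: str,
    environment: str,
    rng: np.random.Generator,
    h2: float | None = None,
    residual_inflation: float = 1.0,
) -> float:
    """One plot record: TBV plus a normal residual on the frozen base scale."""
    g = tbv(ind, arch, trait, environment)
    sd = arch.residual_sd(trait, environment, h2) * np.sqrt(residual_inflation)
    return g + float(rng.normal(0.0, sd)) if sd > 0 else g


def _plot_matrix(
    pop: Population,
    arch: TraitArchitecture,
    env_idx: int,
    rng: np.random.Generator,
    inflation: float = 1.0,
    g: np.ndarray | None = None,
) -> np.ndarray:
    """One plot record per individual per trait for one environment, (n, T)."""
    if g is None:
        g = tbv_matrix(pop, arch)
    out = np.empty((len(pop), len(TRAITS)))
    for ti, t in enumerate(TRAITS):
        sd = arch.residual_sd(t, ENVS[env_idx]) * np.sqrt(inflation)
        out[:, ti] = g[:, ti, env_idx] + rng.normal(0.0, sd, size=len(pop))
    return out


_DESIGNS = ("PYT_partial_rep", "stage_trial_2rep_2env", "single_plant", "f2_family_plot")


def run_trial(
    pop: Population,
    design: str,
    arch: TraitArchitecture,
    rng: np.random.Generator,
    pyt_rep_fraction: float = 0.2,
    single_plant_inflation: float = 2.0,
    stage: str = "",
    cycle: int = 0,
) -> pd.DataFrame:
    """Phenotype a cohort under a named trial design; tidy plot records.

    ``PYT_partial_rep``: one environment, a fraction of entries duplicated;
    ``stage_trial_2rep_2env``: 2 replicates x 2 environments for every entry;
    ``single_plant`` / ``f2_family_plot``: one record per plant with an
    inflated residual mimicking low single-plant heritability.
    """
    if len(pop) == 0:
        raise ValueError("empty population")
    if design not in _DESIGNS:
        raise ValueError(f"unknown design {design!r}")
    g = tbv_matrix(pop, arch)
    frames = []

    def emit(values: np.ndarray, env: str, rep: int, mask: np.ndarray | None = None):
        ids = pop.ids if mask is None else pop.ids[mask]
        vals = values if mask is None else values[mask]
        for ti, t in enumerate(TRAITS):
            frames.append(pd.DataFrame({
                "id": ids, "trait": t, "environment": env, "rep": rep,
                "value": vals[:, ti], "stage": stage, "cycle": cycle,
            }))

    if design == "stage_trial_2rep_2env":
        for ei, e in enumerate(ENVS):
            for rep in range(2):
                emit(_plot_matrix(pop, arch, ei, rng, g=g), e, rep)
    elif design == "PYT_partial_rep":
        emit(_plot_matrix(pop, arch, 0, rng, g=g), ENVS[0], 0)
        n_dup = int(round(pyt_rep_fraction * len(pop)))
        if n_dup:
            mask = np.zeros(len(pop), dtype=bool)
            mask[rng.choice(len(pop), size=n_dup, replace=False)] = True
            emit(_plot_matrix(pop, arch, 0, rng, g=g), ENVS[0], 1, mask)
    else:  # single_plant, f2_family_plot
        emit(_plot_matrix(pop, arch, 0, rng, single_plant_inflation, g=g), ENVS[0], 0)
    return pd.concat(frames, ignore_index=True)


def trial_entry_means(
    pop: Population,
    design: str,
    arch: TraitArchitecture,
    rng: np.random.Generator,
    pyt_rep_fraction: float = 0.2,
    single_plant_inflation: float = 2.0,
) -> np.ndarray:
    """Entry-mean phenotypes per trait, ``(n, T)``; fast path for selection.

    Means are taken over every plot of an entry, environments pooled —
    the aggregation rule used for phenotype-based selection.
    """
    if design not in _DESIGNS:
        raise ValueError(f"unknown design {design!r}")
    g = tbv_matrix(pop, arch)
    if design == "stage_trial_2rep_2env":
        acc = np.zeros((len(pop), len(TRAITS)))
        for ei in range(2):
            for _ in range(2):
                acc += _plot_matrix(pop, arch, ei, rng, g=g)
        return acc / 4.0
    if design == "PYT_partial_rep":
        vals = _plot_matrix(pop, arch, 0, rng, g=g)
        n_dup = int(round(pyt_rep_fraction * len(pop)))
        if n_dup:
            dup = rng.choice(len(pop), size=n_dup, replace=False)
            vals2 = _plot_matrix(pop, arch, 0, rng, g=g)
            vals[dup] = 0.5 * (vals[dup] + vals2[dup])
        return vals
    return _plot_matrix(pop, arch, 0, rng, single_plant_inflation, g=g)
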