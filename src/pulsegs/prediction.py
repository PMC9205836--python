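"""Marker-effect estimation (SNP-BLUP ridge), GEBVs, training sets, accuracy.

Marker effects per trait are the posterior mean of a Bayesian ridge
regression with a known variance ratio, i.e. the SNP-BLUP solution of

    y = 1 mu + X beta + e,     (X'X + lambda I) beta = X'(y - y_bar)

with lambda = m (1 - h2) / h2 for an m-marker panel and the entry-mean
heritability h2.  The closed-form solve is deterministic; a posterior
sampling backend exists for fidelity checks.  GEBVs are X beta.  Training
records are the entry means of advanced-trial lines from the three most
recent *phenotyped* breeding cycles — the simulated calendar decides which
cycles those are, which is what makes early parent recycling run ahead of
its training data — optionally augmented with F2 family-mean records.
Accuracy is cor(GEBV, TBV) on cohorts whose phenotypes never entered the
fit (enforced).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .population import Population
from .traits import ENVS, TRAITS, TraitArchitecture, tbv_matrix

__all__ = [
    "TrainingSet",
    "MarkerEffects",
    "TrainingArchive",
    "entry_mean_h2",
    "estimate_marker_effects",
    "gebv",
    "assemble_training",
    "add_f2_family_records",
    "accuracy",
]


def entry_mean_h2(h2_plot: float, n_plots: int = 4) -> float:
    """Heritability of an entry mean over ``n_plots`` plot records."""
    return n_plots * h2_plot / (1.0 + (n_plots - 1) * h2_plot)


@dataclass
class TrainingSet:
    """Genotype/phenotype records over the marker panel.

    ``X`` holds allele counts (fractional in [0, 2] for F2 family means),
    ``Y`` one entry-mean phenotype per trait, plus cycle-of-origin, source
    tag (``stage_trial`` or ``f2_family``) and the originating line ids.
    """

    X: np.ndarray  # (n, m) float32
    Y: np.ndarray  # (n, T)
    cycles: np.ndarray
    source: np.ndarray
    ids: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float32)
        n = self.X.shape[0]
        if not (len(self.Y) == len(self.cycles) == len(self.source) == len(self.ids) == n):
            raise ValueError("record arrays must align")

    def __len__(self) -> int:
        return self.X.shape[0]

    def appended(self, other: "TrainingSet") -> "TrainingSet":
        return TrainingSet(
            X=np.concatenate([self.X, other.X]),
            Y=np.concatenate([self.Y, other.Y]),
            cycles=np.concatenate([self.cycles, other.cycles]),
            source=np.concatenate([self.source, other.source]),
            ids=np.concatenate([self.ids, other.ids]),
        )


@dataclass
class MarkerEffects:
    """Estimated marker substitution effects per trait (panel-aligned)."""

    beta: np.ndarray  # (m, T)
    intercept: np.ndarray  # (T,)
    marker_loci: np.ndarray  # flat locus indices of the panel
    fitted_at_cycle: int = -1
    training_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))


def _ridge_solve(Xc: np.ndarray, yc: np.ndarray, lam: float) -> np.ndarray:
    n, m = Xc.shape
    if n <= m:
        K = (Xc @ Xc.T).astype(np.float64)
        K[np.diag_indices_from(K)] += lam
        alpha = np.linalg.solve(K, yc)
        return Xc.T.astype(np.float64) @ alpha
    A = Xc.T.astype(np.float64) @ Xc
    A[np.diag_indices_from(A)] += lam
    return np.linalg.solve(A, Xc.T @ yc)


def _ridge_sample(
    Xc: np.ndarray, yc: np.ndarray, lam: float, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Posterior-sampling backend: draws from N(beta_hat, sigma2 C^-1), averaged."""
    m = Xc.shape[1]
    A = Xc.T.astype(np.float64) @ Xc
    A[np.diag_indices_from(A)] += lam
    L = np.linalg.cholesky(A)
    mean = np.linalg.solve(A, Xc.T @ yc)
    resid = yc - Xc @ mean
    sigma2 = float(resid @ resid) / max(len(yc) - 1, 1)
    z = rng.standard_normal((m, n_samples))
    draws = mean[:, None] + np.sqrt(sigma2) * np.linalg.solve(L.T, z)
    return draws.mean(axis=1)


def estimate_marker_effects(
    training: TrainingSet,
    marker_loci: np.ndarray,
    h2_eff: dict[str, float] | None = None,
    backend: str = "closed_form",
    n_samples: int = 200,
    rng: np.random.Generator | None = None,
    fitted_at_cycle: int = -1,
) -> MarkerEffects:
    """Fit ridge marker effects for every trait on one training set.

    ``lambda = m (1 - h2_eff) / h2_eff`` per trait; ``h2_eff`` defaults to
    the entry-mean heritability of a 4-plot stage trial for each trait.
    """
    if len(training) < 2:
        raise ValueError("need at least 2 training records")
    from .traits import DEFAULT_H2

    if h2_eff is None:
        h2_eff = {t: entry_mean_h2(DEFAULT_H2[t]) for t in TRAITS}
    m = training.X.shape[1]
    if len(marker_loci) != m:
        raise ValueError("marker panel does not align with training genotypes")
    Xmean = training.X.mean(axis=0)
    n = len(training)
    # single precision for large Gram matrices; beta is only used to rank
    big = n * m > 500_000
    Xc = (training.X - Xmean).astype(np.float32 if big else np.float64)
    # the Gram matrix is shared across traits; only lambda differs
    K = (Xc @ Xc.T).astype(np.float64) if (backend == "closed_form" and n <= m) else None
    beta = np.zeros((m, len(TRAITS)))
    intercept = np.zeros(len(TRAITS))
    for ti, t in enumerate(TRAITS):
        y = training.Y[:, ti]
        intercept[ti] = y.mean()
        yc = y - y.mean()
        if np.allclose(yc, 0):
            warnings.warn(f"constant phenotypes for {t}; zero effects returned")
            continue
        h = h2_eff[t]
        lam = m * (1.0 - h) / h
        if backend == "closed_form":
            if K is not None:
                Kl = K.copy()
                Kl[np.diag_indices_from(Kl)] += lam
                beta[:, ti] = Xc.T @ np.linalg.solve(Kl, yc)
            else:
                beta[:, ti] = _ridge_solve(Xc, yc, lam)
        elif backend == "gibbs":
            r = rng if rng is not None else np.random.default_rng(0)
            beta[:, ti] = _ridge_sample(Xc, yc, lam, n_samples, r)
        else:
            raise ValueError(f"unknown backend {backend!r}")
    return MarkerEffects(
        beta=beta,
        intercept=intercept,
        marker_loci=np.asarray(marker_loci),
        fitted_at_cycle=fitted_at_cycle,
        training_ids=np.unique(training.ids),
    )


def gebv(effects: MarkerEffects, pop_or_X: Population | np.ndarray) -> np.ndarray:
    """GEBVs ``X beta`` per trait, shape ``(n, T)``; no intercept (centred fit)."""
    if isinstance(pop_or_X, Population):
        X = pop_or_X.allele_counts(effects.marker_loci).astype(np.float32)
    else:
        X = np.asarray(pop_or_X, dtype=np.float32)
    if X.shape[1] != effects.beta.shape[0]:
        raise ValueError("genotypes do not align with the marker panel")
    return X @ effects.beta.astype(np.float32)


@dataclass
class TrainingArchive:
    """Per-cycle phenotype records with calendar availability.

    Each stage-trial block carries the simulated year at which its records
    become usable; ``assemble`` at a given year sees only matured blocks.
    """

    stage_blocks: list[tuple[int, float, TrainingSet]] = field(default_factory=list)
    f2_blocks: list[tuple[int, float, TrainingSet]] = field(default_factory=list)

    def add_stage(self, cycle: int, available_year: float, records: TrainingSet) -> None:
        self.stage_blocks.append((cycle, available_year, records))

    def add_f2(self, cycle: int, available_year: float, records: TrainingSet) -> None:
        self.f2_blocks.append((cycle, available_year, records))

    def available_stage_cycles(self, now_year: float) -> list[int]:
        return sorted({c for c, yr, _ in self.stage_blocks if yr <= now_year})


def assemble_training(
    history: TrainingArchive, now_year: float, window: int = 3
) -> TrainingSet:
    """Collect training records available on the calendar at ``now_year``.

    Stage-trial records come from the ``window`` most recent phenotyped
    cycles; F2 family records accumulate without a window (they exist to
    refresh an otherwise frozen training set).
    """
    cycles = history.available_stage_cycles(now_year)
    if not cycles:
        raise RuntimeError(
            "no phenotyped cycles available yet; warm-start the program with "
            "phenotypic-selection cycles before fitting marker effects"
        )
    keep = set(cycles[-window:])
    parts = [rec for c, yr, rec in history.stage_blocks if yr <= now_year and c in keep]
    parts += [rec for c, yr, rec in history.f2_blocks if yr <= now_year]
    out = parts[0]
    for p in parts[1:]:
        out = out.appended(p)
    return out


def add_f2_family_records(
    training: TrainingSet,
    families: list[Population],
    arch: TraitArchitecture,
    marker_loci: np.ndarray,
    rng: np.random.Generator,
    n_families: int = 50,
    cycle: int = -1,
) -> TrainingSet:
    """Append one family-mean record per phenotyped F2 family.

    The family's genotype record is the mean allele count across members
    (fractional, in [0, 2]); its phenotype is the mean of the members'
    field plot records per trait — one family behaving as one individual.
    """
    from .traits import trial_entry_means

    if n_families > len(families):
        warnings.warn("fewer families available than requested; using all")
        n_families = len(families)
    chosen = list(rng.choice(len(families), size=n_families, replace=False))
    X, Y, ids = [], [], []
    for fi in chosen:
        fam = families[fi]
        if len(fam) == 0:
            raise ValueError("family without phenotyped members")
        pheno = trial_entry_means(fam, "f2_family_plot", arch, rng)
        X.append(fam.allele_counts(marker_loci).mean(axis=0))
        Y.append(pheno.mean(axis=0))
        ids.append(fam.ids[0])
    add = TrainingSet(
        X=np.asarray(X, dtype=np.float32),
        Y=np.asarray(Y),
        cycles=np.full(n_families, cycle),
        source=np.array(["f2_family"] * n_families),
        ids=np.asarray(ids, dtype=np.int64),
    )
    return training.appended(add)


def accuracy(
    effects: MarkerEffects,
    cohort: Population,
    arch: TraitArchitecture,
    trait: str,
    env_handling: str = "mean",
) -> float:
    """Pearson correlation of GEBV with TBV on an untrained cohort.

    TBV is averaged over the two environments by default.  Raises if any
    cohort member's phenotypes entered the marker-effect fit (the
    leave-cycle-out evaluation discipline).
    """
    if len(cohort) < 3:
        raise ValueError("cohort must have at least 3 members")
    if np.intersect1d(cohort.ids, effects.training_ids).size:
        raise ValueError("cohort overlaps the training records; accuracy would leak")
    ti = TRAITS.index(trait)
    u = gebv(effects, cohort)[:, ti]
    g = tbv_matrix(cohort, arch)
    gt = g[:, ti, :].mean(axis=1) if env_handling == "mean" else g[:, ti, ENVS.index(env_handling)]
    if u.std() == 0 or gt.std() == 0:
        warnings.warn("zero-variance GEBVs or TBVs; accuracy undefined")
        return float("nan")
    return float(np.corrcoef(u, gt)[0, 1])
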