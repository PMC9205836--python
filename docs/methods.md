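# Methods

`pulsegs` is a stochastic simulator of an inbred (self-pollinating) pulse
breeding program.  It compares conventional phenotypic selection (PS) with
genomic-selection (GS) strategies that shorten the breeding cycle by
recycling crossing parents earlier, and with strategies that manage the
accompanying loss of genetic diversity.  This note documents the model, the
defaults and the design choices.

## Genome and founder population

The genome is purely genetic: seven chromosomes with map lengths drawn
uniformly in 192.7–429.7 cM and loci placed uniformly along each
chromosome.  Physical coordinates are never used; every module addresses a
locus as a (chromosome, index) pair or a flat index.

The reference breeding pool is a large set of fully homozygous inbred
lines.  Because real genotypes are rarely at hand, the canonical input is
synthetic: ancestral allele frequencies are drawn from a symmetric
Beta(0.2, 0.2) (a U-shaped spectrum typical of SNP discovery panels), a
random-mating population of twice the target line count is gene-dropped
for 50 burn-in generations to build within-chromosome linkage
disequilibrium, and each line is finished by doubling a single sampled
gamete — instant, complete inbreeding.  Loci with realized minor allele
frequency below 0.01 are dropped, which removes roughly 40–45% of drawn
loci under this spectrum; maps are therefore drawn larger than the marker
panel plus QTL pool they must host.  A loading path for real data (VCF or
a 0/1/2 matrix) applies the same filters (call rate ≥ 0.5, MAF ≥ 0.01) and
a seeded uniform subsample to the marker budget (30,000 by default).

The retained loci are partitioned once per experiment into the observed
marker panel and a reserved pool from which QTL are sampled.  QTL are thus
never observed directly; markers act on predictions only through linkage
disequilibrium — standard practice for genomic-selection simulation.

## Traits, environments and phenotypes

Three traits are simulated in two environments: disease resistance
(h² = 0.5), grain weight (h² = 0.75) and grain yield (h² = 0.25).  Each
trait × environment combination is controlled by ~1,000 additive QTL
(300 at desk scale) with N(0, 1) substitution effects; only additive
action is modelled.  Seventy per cent of QTL loci are shared between
traits within an environment and between environments within a trait.
Effect pairs at environment-shared loci are bivariate normal with
correlation 0.8 (disease resistance, grain weight) or 0.4 (grain yield —
strong genotype-by-environment interaction); effects are independent
between traits.

The two overlap requirements are realized simultaneously by a nested
block scheme: a core of fraction `overlap²` of each QTL set is shared by
all traits and both environments, blocks of fraction `overlap·(1−overlap)`
are trait-shared/environment-specific and trait-specific/environment-
shared, and the remainder is fully private.  This gives the exact 70%
pairwise locus overlap for every trait pair and environment pair at once
(the product structure of two independent sharing events), which we prefer
over per-pair constructions that cannot hold for three traits jointly.

The true breeding value is g = M a.  A plot phenotype adds a normal
residual with variance σ²ₑ = ((1 − h²)/h²)·σ²_g, where σ²_g is frozen at
the founder-population additive variance per trait × environment, so
residual noise does not shrink as selection depletes variance.  Genetic
gain is reported in units of the founder population's additive SD of the
environment-averaged TBV, weighted 0.3/0.3/0.4 across traits for the
aggregate.

Trial designs: the preliminary yield trial (PYT) is a partially replicated
single-environment trial (20% of entries duplicated); Stage 1 and Stage 2
are 2-replicate × 2-environment trials; single-plant records (the F5 cull,
F2 family plots) carry a residual inflated 2× to mimic low single-plant
heritability.  Phenotype-based selection always uses the entry mean over
all of an entry's plots, environments pooled.

## Marker-effect estimation and prediction

Marker effects per trait are the posterior mean of a Bayesian ridge
regression with a known variance ratio — the SNP-BLUP solution
(X'X + λI)β = X'(y − ȳ) with λ = m·(1 − h²ₑ)/h²ₑ and h²ₑ the entry-mean
heritability of a four-plot stage trial.  The closed-form solve is exact
and deterministic (solved in whichever of the primal/dual spaces is
smaller; the Gram matrix is shared across traits, in single precision for
large problems where β is used only to rank candidates); a posterior-
sampling backend exists for fidelity checks.  GEBVs are Xβ without
intercept; all selection is on cohort-standardized indices, so centring
constants are irrelevant.

The training set holds the 400 Stage-1 entrants of each breeding cycle
with entry means over their Stage-1 (and, for survivors, Stage-2)
records, from the three most recently *phenotyped* cycles.  Which cycles
are phenotyped is decided by the simulated calendar: a cycle's trial
phenotypes become available `product_track_years` (8 PS, 8.5 field-SSD,
6 glasshouse) after its crossing date.  Early parent recycling therefore
runs ahead of its training data — with one-year F2 cycles, no new trial
phenotypes mature within the simulated horizon and the training set stays
frozen at the warm-start cycles, which is what drives the observed
accuracy decay.  Optionally, 50 F2 families are field-phenotyped each
cycle (family-mean genotype in [0, 2] and family-mean phenotype acting as
one training individual, available after one season).  F2-family records
accumulate without a window: a strict three-cycle window would evict the
only deeply phenotyped records and defeat the purpose of the augmentation.

Prediction accuracy is cor(GEBV, TBV) with TBV averaged over environments,
measured on the cohort to which GEBV selection for parent recycling was
applied; the implementation refuses cohorts whose phenotypes entered the
fit (leave-cycle-out discipline).

## Optimal haploid value and cross selection

Each chromosome's marker panel is split into five contiguous segments of
equal marker count (±1).  The haplotype value of a segment is Σ h_k β_k;
the OHV of an individual is the sum over segments of its better haplotype
value — the score of the best inbred line extractable from that genotype.
For a fully inbred individual, twice the OHV equals the GEBV.

Primary crosses: all C(150, 2) parent pairs are scored by the OHV index
of the virtual F1 (the union of the parental haplotypes, so the pair's
best per-segment value is the elementwise max of the parents' bests;
heterozygous parents are handled identically).  Index weights are
0.3/0.3/0.4 with per-trait standardization by the parent cohort's OHV SD.
The top 300 pairs are accepted greedily under a four-uses-per-parent cap;
because 300 crosses exhaust 150 × 4 slots exactly, the greedy pass can
strand capacity, and the selector then permits repeating a pair (two F1
plants of the same cross) and finally relaxes the cap one use at a time —
deterministic and near-optimal, verified against exhaustive search on
small instances.

F1 intercrosses (four-way crosses): all C(300, 2) F1 pairs are candidates,
optionally pre-filtered to the top fraction by mid-parent GEBV index.
Each candidate is projected in silico: 20 virtual descendants are pushed
from the intercross to F8 by single-seed descent (mutation off) and scored
by GEBV index; the 200 families with the highest progeny mean + 1 SD are
kept.  Projection uses a breakpoint-mosaic representation — each virtual
haplotype is a list of (segment end, source) references to the four F1
parental haplotypes, recombined in O(segments) per meiosis and scored via
per-source prefix sums of β, with an exact early exit once a chromosome's
two haplotypes become the same mosaic (every later gamete equals it).  An
explicit locus-array backend implements the identical stochastic model and
serves as the cross-check oracle in the tests.

## Selection, diversity metrics and the GA

Truncation selection ranks candidates on the standardized index with ties
broken by id.  Diversity of a cohort is tracked as per-trait TBV variance,
the number of marker alleles fixed (NAF — loci with no allelic variation
in the cohort), and the mean off-diagonal of VanRaden's genomic
relationship matrix G = ZZ′/(2Σp(1−p)).  G is centred with the *base
population's* allele frequencies: relationships must accumulate against a
fixed reference as inbreeding builds, whereas cohort-centred Z has zero
column sums, pinning the mean off-diagonal at −(1 + F)/(n − 1) for any
cohort — a degenerate statistic.  Cohort centring remains available as an
option.

The diversity-preserving parent selector maximizes
f = Ī − λ₁·REL̄ − λ₂·NAF over subsets of exactly 150 candidates
(λ₁ = 1, λ₂ = 10⁻⁶), where Ī is the subset's mean standardized GEBV index,
REL̄ its mean off-diagonal relationship and NAF its fixed-marker count.  A
genetic algorithm searches membership bit-vectors: population 2,000,
1,000 iterations, per-bit mutation 0.001, the top 20% by fitness surviving
unchanged and serving as crossover parents (one-point crossover), and a
repair step restoring cardinality by toggling the lowest/highest-index
bits.  The initial population is seeded with the truncation-selection
subset, so the penalty-free limit provably recovers plain top-150
selection and elitism keeps the best-ever subset.  NAF and REL̄ are
evaluated with packed allele-presence bitmasks and a precomputed
relationship matrix.

## Breeding programs and the calendar

PS cycle: 150 parents by phenotype index (cycle 1: a random resample of
the base population) → 300 primary crosses by random mating under the
usage cap → 20 F2 seeds per family → family bulk-up to F5 (each
generation's seeds drawn from random plants of the same family) → 30% of
F5 single plants culled on a low single-plant grain-yield record → 800
random survivors to PYT → 400 by phenotype index → Stage 1 → 200 →
Stage 2 → 80 into the germplasm pool.

GS cycle: OHV-selected crosses and intercrosses as above → 200 families ×
10 F1i plants; 20 F2 seeds per family (drawn round-robin from the family's
F1i plants) → 4,000 seeds → single-seed descent to F6 (field SSD, 4 years,
or glasshouse aSSD, 1.5 years — genetically identical processes that
differ only on the calendar) → genotyping and GEBV selection of 800 → GS
at PYT and Stage 2, phenotype index at Stage 1 → 80 pool additions.
Parents are recycled from Stage 2, F6, F2 or F1i depending on the
scenario; recycled F1i/F2 individuals may be heterozygous and are treated
like any other genotype.  For F2/F1 recycling the product track is not
simulated: its phenotypes cannot mature within the five-cycle horizon
(8.5-year pipeline vs 1-year cycles) and so cannot affect any reported
quantity.

Stage durations (years): crossing 0.5; intercross/F2 seed 0.5; bulk-up 4
(PS and field SSD) or 1.5 (glasshouse); genotyping 0.5 (GS only); one year
each for PYT, Stage 1 and Stage 2.  These reproduce the nine canonical
generation intervals exactly (PS 8; GS-SSD 8.5/5/1/0.5; GS-aSSD
6/2.5/1/0.5 for Stage-2/F6/F2/F1 recycling).

Experiments run 8 breeding cycles with 50 replicates at full scale.  Each
replicate resamples the 150 cycle-1 parents from the base population,
runs PS for cycles 1–3 and branches every scenario from the end of PS
cycle 3 with its own random stream, so all branches of a replicate share
the warm start bit-exactly.  Metrics are recorded on the 150 crossing
parents at each cycle start (plus a terminal parent selection closing the
series); annual rates are (end − start)/(elapsed years) over the GS phase,
and scenario comparisons are (rate − rate_PS)/rate_PS × 100.

## Problem sizes

The full preset mirrors the reference program: 1,568 founder lines,
30,000 markers, ~1,000 QTL per trait × environment, 4,000 bulk-up lines,
50 replicates.  The desk preset is the scale used by the bundled tests and
the reproduction script: 500 founders, 2,000 markers, 300 QTL per trait ×
environment, 1,000 bulk-up lines (200 intercross families × 5 seeds, PS
300 families × 4 seeds), mid-parent pre-filter 0.1 for intercross
projection, GA 200 × 100, 10 replicates.  Desk-scale estimates preserve
the qualitative structure (strategy ordering, accuracy dynamics,
diversity trade-offs) while relative magnitudes carry the distortion of
reduced marker density, founder number and selection-candidate counts.

## What the synthetic data does and does not capture

The generator reproduces the two properties the downstream methods depend
on — a realistic allele-frequency spectrum after MAF filtering and
within-chromosome LD from finite-population burn-in — but not population
structure, breeding-history kinship, genotyping error or imputation
artefacts of real panels.  Passing tests demonstrate internal consistency
of the machinery and reproduction of the published *relative* strategy
comparisons under these idealized conditions, not calibrated absolute
gains for any real crop program.

## Numerical choices and degenerate inputs

Poisson(1) crossovers per chromosome with uniform positions and no
interference; zero-crossover chromosomes transmit an intact haplotype.
Mutation flips each allele independently with probability 0.001 per locus
per gamete (both markers and QTL; the rate's unit is configurable since a
per-chromosome reading is also defensible), and is off inside in-silico
projections.  Ridge systems are solved by Cholesky-backed dense solves;
zero-variance phenotypes yield zero effects with a warning; zero-SD index
traits drop out of the index with a warning; cohorts of one individual
report 100% fixation and an undefined relationship.  Selection ties break
by ascending id everywhere, making every run bit-reproducible from
(configuration, seed); projection means/SDs use shift-invariant
accumulation so identical parents give exactly zero SD.

## Known limitations

No dominance or epistasis; no crossover interference or sex-specific
maps; no genotyping error or missingness downstream of loading; economic
costs, multi-program germplasm exchange and variety-trial stages are out
of scope.  The GA is a heuristic: it is exact on enumerable pools and
directionally validated at scale, but optimality at 150-of-1,500 is not
guaranteed.  The F1i seed bookkeeping admits two readings (seeds per
family vs seeds per F1i plant); the default is 20 F2 seeds per intercross
family (4,000 bulk-up seeds in total), with the per-plant reading
available through configuration.
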