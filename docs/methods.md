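# Methods

## Model

The evaluation model is a single-trait repeatability animal model:
`y = Xβ + Za + Wp + e` with `a ~ N(0, H σ²a)`, `p ~ N(0, I σ²p)`,
`e ~ N(0, I σ²e)`. Fixed effects are four class factors (year-season,
station, collection-interval class, collection-number class) and an age
covariate in months. The permanent-environment effect `p` carries the
covariance among repeated records of one animal; `a` runs over every
pedigree animal, so recordless ancestors and ungenotyped relatives are
estimated through relationships.

Assumptions: a single residual variance across stations and years;
additive gene action only; variance components known (they are inputs,
not estimated — no REML/Gibbs machinery is included); unrelated base
population with unknown parents contributing Mendelian-sampling variance
adjusted for known-parent inbreeding.

## Relationship matrices

* `A` — tabular method on a topologically sorted pedigree.
* `F` — Meuwissen–Luo path tracing; never forms dense `A`. The
  Mendelian-sampling variance of animal *i* is `0.5 − 0.25(F_s + F_d)`
  with `F = −1` substituted for an unknown parent (so founders get 1,
  one-known-parent animals `0.75 − 0.25 F_known`).
* `A⁻¹` — Henderson's rules with those variances, assembled sparse.
* `G = ZDZ′q` — VanRaden form: `Z` is the 0/1/2 marker matrix centered
  by `2pᵢ`, `D` the diagonal SNP weights, `q = 1/Σ 2pᵢ(1−pᵢ)`. Allele
  frequencies are the observed frequencies among genotyped animals
  (base-population frequencies are not available in practice). Note a
  consequence: with observed-frequency centering every column of `Z`
  sums to zero, so the unblended `G` has rank at most n−1. The default
  blend `G ← 0.95·G_raw + 0.05·A22` restores invertibility; blend 0 is
  allowed for the exact algebraic checks, which therefore construct
  their panels with known base frequencies.
* `H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A22⁻¹]` — correction confined to the
  genotyped block, no τ/ω reweighting of the two inverses.

## Solving and backsolving

The mixed-model equations are solved by direct sparse LU factorization
(`scipy.sparse.linalg.spsolve`); at the package's intended scale
(thousands of animals, tens of thousands of records) this is exact,
deterministic, and fast, so no iterative solver is used by default. The
reported `convergence` is the relative residual of the linear system
(typically ~1e-15). Fixed factors use reference-level (first level
dropped) dummy coding plus an intercept; estimable functions — level
contrasts and GEBVs — are the supported surface, not raw coefficients.

GEBVs of genotyped animals convert to SNP effects as
`û = λ D Z′ G⁻¹ â_g` with `λ = q`, the G scaling constant. This choice
makes the conversion the exact BLUP backsolve: with an unblended G,
`Zû = ZDZ′q (ZDZ′q)⁻¹ â_g = â_g`. Any other λ breaks this projection
identity, which is verified to 1e-8 in the tests. With a blended G the
identity holds only approximately; the gap shrinks monotonically as the
blend weight decreases (checked at 0.10/0.05/0.01).

## Weighting iterations

Weights update as `dᵢ = ûᵢ²·2pᵢ(1−pᵢ)` and are normalized to
`Σd = m` (the SNP count, i.e. the trace of the first iteration's
identity D), keeping the total genetic variance expressed by G constant
across iterations. Each iteration rebuilds `G` and `H⁻¹` from scratch
rather than low-rank-updating them — affordable at this scale and free
of update-drift risk. `n_iter` counts solves: 1 is plain single-step
GBLUP plus a backsolve; the default 2 performs one reweighting pass,
the variant generally reported to balance resolution against the
runaway concentration of weight that further iterations cause. No
ceilings or floors are applied to weights.

## Window report

Explained variance per window of 10 consecutive SNPs (sliding step 1,
both configurable): the window genetic value `g = Σⱼ zⱼûⱼ` is computed
across genotyped individuals and its sample variance divided by the
configured σ²a, ×100. Windows never span chromosomes; a chromosome
shorter than the window yields one truncated window with a warning.
Because sliding windows produce ~10 near-copies of every peak, the
top-N list greedily prunes any window sharing a SNP with a
higher-ranked selection, so the reported top regions are distinct. The
four variance classes (>1 %, 0.5–1 %, 0.1–0.5 %, <0.1 %) assign boundary
values to the lower class; the summary reports both the count share and
the variance share of each class, the two readings such summaries admit.
Cross-trait overlap requires same-chromosome inclusive bp-interval
intersection; merely adjacent windows do not overlap.

## Synthetic data generator

The generator emulates the statistical structure the model assumes, at
desk scale (defaults: 80 founders + 3 discrete generations × 70 matings
× 2 offspring = 500 animals; 2,000 SNPs evenly spaced at 60 kb on 5
autosomes; 20 QTLs carrying half of σ²a; 30 % of animals ungenotyped;
5–60 records per animal; σ²a = 0.2, σ²p = 0.2, σ²e = 0.6, i.e. h² = 0.2
and repeatability 0.4, inside the range published for semen traits;
four fixed factors with 5 levels each, level effects N(0, 0.5²); age
uniform on 12–120 months with slope 0.01 per month; trait mean 15).

Genotypes descend by gene dropping: founder alleles are Bernoulli draws
at per-SNP frequencies uniform on [0.05, 0.5]; each offspring inherits
one uniformly chosen allele per parent per locus. Loci are unlinked, so
the only linkage disequilibrium is pedigree cosegregation — exactly the
signal the single-step backsolve exploits. QTL effects are scaled
against each column's realized variance so every QTL contributes an
equal, known share of σ²a; the remaining genetic variance is a
polygenic term dropped through the pedigree with inbreeding-adjusted
Mendelian-sampling variances.

What the generator does **not** emulate: chip-scale background LD (a
real 50K chip tags QTLs through many neighboring markers; here only the
QTL column itself carries marker signal), selection, assortative
mating, genotyping error, missing-call patterns, or heterogeneous
record counts by age. Passing recovery tests therefore demonstrates the
machinery is correct and the weighting behaves as designed, not that
real-chip power equals the simulated power; with dense LD the windowed
signal around a QTL would be stronger than simulated here.

A consequence worth stating: because the polygenic share of σ²a is
transmitted only through the pedigree, it is invisible to the markers,
and the GEBV component it dominates is smeared by the backsolve across
all windows. In the three-QTL recovery study (each QTL ~16.7 % of σ²a)
this caps the top-10 recovery rate at roughly 0.75–0.85 of seed × QTL
draws; the weight-rank improvement rate from iteration 1 to 2 measures
~0.85–0.90.

## Numerical choices

* HWE filter: 1-df chi-square goodness of fit of genotype counts
  against p², 2pq, q² on observed calls; monomorphic SNPs fit trivially
  (they fail the MAF filter instead). The three QC filters evaluate
  jointly on the input matrix, so the report attributes each SNP to
  every filter it fails.
* Missing calls surviving QC are mean-imputed (to 2p) with a logged
  warning.
* Ranking ties break by (chromosome, start position); weight ranks are
  dense argsort ranks.
* Degenerate inputs raise early with context: all SNPs failing QC, zero
  surviving phenotype records, all-zero weight vectors, parentage
  cycles, duplicate animals, non-finite design entries.
* Determinism: a single `numpy` Generator chain per simulation seed;
  rerunning any pipeline configuration reproduces outputs byte for
  byte.

## Problem sizes used in verification

Oracle comparisons use 50 random overlapping-generation pedigrees of
20–200 animals (dense tabular A + `numpy` inversion vs sparse
Henderson assembly), a 30-animal fixture against a dense GLS solver,
and 10 random 12 × 50 marker panels for the projection identity. The
recovery study runs the 500-animal preset with a 3-QTL architecture for
20 seeds; the variance-partition check uses 500 founders × 60 SNPs so
that the sampling covariance between windows, which the partition
identity neglects, is small relative to the window variances.

## Known limitations

Variance components must be supplied; single-trait analyses only; no
genotype imputation (records with missing calls rely on mean
imputation); no X-chromosome handling; no gene annotation or enrichment
of detected windows; sparse direct factorization assumes desk-scale
problems (≲ 50k mixed-model equations).
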