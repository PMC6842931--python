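"""Synthetic pedigree, genotype, and repeated-record phenotype generator.

Emulates the statistical structure the single-step repeatability model
assumes: a multi-generation pedigree with ungenotyped animals, biallelic
SNPs on several autosomes transmitted by gene dropping (unlinked loci, so
the only LD is pedigree cosegregation), a sparse QTL architecture embedded
among the markers, and per-record phenotypes driven by fixed-effect
classes, an age covariate, additive genetic, permanent-environment, and
residual terms.

Writes the same file formats :mod:`singlestep.io_formats` reads, so
synthetic and real modes are interchangeable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import (
    UNKNOWN,
    GenotypeMatrix,
    Pedigree,
    PhenotypeTable,
)
from .mme_solver import VarianceComponents
from .relationships import _mendelian_variance, inbreeding

#: base-pair spacing between evenly placed SNPs (about the density of a
#: 50K bovine chip across ~2.5 Gb)
SNP_SPACING_BP = 60_000

FACTOR_NAMES = ("year_season", "station", "interval_class", "collection_class")


@dataclass
class SimConfig:
    """All knobs of the generator; ``desk_preset`` gives the default scale."""

    n_founders: int = 80
    n_generations: int = 3
    matings_per_generation: int = 70
    offspring_per_mating: int = 2
    n_snps: int = 2000
    n_chromosomes: int = 5
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtl: int = 20
    qtl_variance_fraction: float = 0.5
    varcomp: VarianceComponents = field(
        default_factory=lambda: VarianceComponents(0.2, 0.2, 0.6)
    )
    records_per_animal_range: tuple[int, int] = (5, 60)
    n_levels_per_factor: int = 5
    fixed_effect_sd: float = 0.5
    age_range_months: tuple[float, float] = (12.0, 120.0)
    age_slope: float = 0.01
    trait_mean: float = 15.0
    trait: str = "VE"
    ungenotyped_fraction: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_founders < 2:
            raise ValueError("n_founders must be >= 2")
        for frac in (self.qtl_variance_fraction, self.ungenotyped_fraction):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        if self.qtl_variance_fraction > 1.0:
            raise ValueError("qtl_variance_fraction must be <= 1")
        if self.n_qtl > self.n_snps:
            raise ValueError("n_qtl must be <= n_snps")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        lo, hi = self.records_per_animal_range
        if not (1 <= lo <= hi):
            raise ValueError("records_per_animal_range must satisfy 1 <= min <= max")


def desk_preset(seed: int = 0) -> SimConfig:
    """Desk-scale default: ~500 animals over 3 discrete generations,
    2,000 SNPs on 5 chromosomes, 20 QTLs, 30 % ungenotyped."""
    return SimConfig(seed=seed)


@dataclass
class TruthSet:
    """Ground truth of one simulation for recovery tests."""

    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    true_bv: pd.Series          # additive genetic value per animal
    true_pe: pd.Series          # permanent-environment value per animal
    poly_bv: pd.Series          # polygenic (non-marker) part of true_bv
    varcomp_used: VarianceComponents
    seed: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "animal": self.true_bv.index,
            "true_bv": self.true_bv.to_numpy(),
            "true_pe": self.true_pe.to_numpy(),
            "poly_bv": self.poly_bv.to_numpy(),
        })
        return df

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(cfg: SimConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Discrete-generation pedigree: founders with unknown parents, then
    ``matings_per_generation`` matings per generation drawn (sire != dam)
    from the previous generation, each producing ``offspring_per_mating``
    offspring."""
    cfg.validate()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    ids: list[str] = []
    sire: list[int] = []
    dam: list[int] = []
    prev = list(range(cfg.n_founders))
    for i in range(cfg.n_founders):
        ids.append(f"A{i + 1}")
        sire.append(UNKNOWN)
        dam.append(UNKNOWN)
    for _ in range(cfg.n_generations):
        current: list[int] = []
        for _ in range(cfg.matings_per_generation):
            s, d = rng.choice(prev, size=2, replace=False)
            for _ in range(cfg.offspring_per_mating):
                idx = len(ids)
                ids.append(f"A{idx + 1}")
                sire.append(int(s))
                dam.append(int(d))
                current.append(idx)
        prev = current
    ped = Pedigree(ids, np.array(sire), np.array(dam))
    ped.validate()
    return ped


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _snp_map(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Evenly spaced positions on ``n_chromosomes`` autosomes."""
    base = cfg.n_snps // cfg.n_chromosomes
    extra = cfg.n_snps % cfg.n_chromosomes
    chrom = np.concatenate([
        np.full(base + (1 if c < extra else 0), c + 1, dtype=np.int64)
        for c in range(cfg.n_chromosomes)
    ])
    pos = np.concatenate([
        (np.arange(np.sum(chrom == c + 1)) + 1) * SNP_SPACING_BP
        for c in range(cfg.n_chromosomes)
    ])
    return chrom, pos


def simulate_genotypes(
    ped: Pedigree, cfg: SimConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Gene-drop biallelic genotypes through the pedigree.

    Founder alleles are Bernoulli draws at per-SNP frequencies sampled
    uniformly from ``maf_range``; every non-founder inherits one uniformly
    chosen allele from each parent per locus.  Loci are unlinked.
    """
    cfg.validate()
    ped.validate()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n, m = len(ped), cfg.n_snps
    founder_maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    hap = np.zeros((n, m, 2), dtype=np.int8)
    for i in range(n):
        for k, parent in enumerate((ped.sire[i], ped.dam[i])):
            if parent == UNKNOWN:
                hap[i, :, k] = rng.random(m) < founder_maf
            else:
                pick = rng.integers(0, 2, size=m)
                hap[i, :, k] = hap[parent, np.arange(m), pick]
    chrom, pos = _snp_map(cfg)
    return GenotypeMatrix(
        individual_ids=list(ped.animal_ids),
        snp_ids=[f"snp{j + 1}" for j in range(m)],
        calls=hap.sum(axis=2).astype(np.int16),
        chrom=chrom,
        pos_bp=pos,
    )


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    ped: Pedigree,
    g: GenotypeMatrix,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[PhenotypeTable, TruthSet]:
    """Simulate repeated records y = fixed + b_age*age + a_i + p_i + e.

    The additive value a_i is the sum of a marker part (QTL columns,
    scaled so they jointly contribute ``qtl_variance_fraction`` of
    sigma2_a, split equally across QTLs) and a pedigree-transmitted
    polygenic part carrying the remainder.
    """
    cfg.validate()
    if g.individual_ids != list(ped.animal_ids):
        raise ValueError("genotypes must cover all pedigree animals before masking")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    vc = cfg.varcomp
    n, m = len(ped), g.n_snps

    # --- QTL architecture: equal variance share per QTL ----------------
    calls = g.calls.astype(float)
    col_var = calls.var(axis=0)
    eligible = np.nonzero(col_var > 1e-8)[0]
    if len(eligible) < cfg.n_qtl:
        raise ValueError("not enough polymorphic SNPs to place QTLs")
    qtl_idx = np.sort(rng.choice(eligible, size=cfg.n_qtl, replace=False))
    effects = np.zeros(cfg.n_qtl)
    if cfg.n_qtl > 0 and cfg.qtl_variance_fraction > 0:
        target = cfg.qtl_variance_fraction * vc.sigma2_a / cfg.n_qtl
        signs = rng.choice([-1.0, 1.0], size=cfg.n_qtl)
        effects = signs * np.sqrt(target / col_var[qtl_idx])
    z_qtl = calls[:, qtl_idx] - calls[:, qtl_idx].mean(axis=0)
    marker_bv = z_qtl @ effects

    # --- polygenic remainder, dropped through the pedigree --------------
    sigma2_poly = (1.0 - cfg.qtl_variance_fraction) * vc.sigma2_a
    poly = np.zeros(n)
    if sigma2_poly > 0:
        F = inbreeding(ped)
        sd = np.sqrt(sigma2_poly)
        for i in range(n):
            s, d = ped.sire[i], ped.dam[i]
            mid = 0.0
            if s != UNKNOWN:
                mid += 0.5 * poly[s]
            if d != UNKNOWN:
                mid += 0.5 * poly[d]
            mvar = _mendelian_variance(i, ped.sire, ped.dam, F)
            poly[i] = mid + rng.normal(0.0, sd * np.sqrt(mvar))
    true_bv = marker_bv + poly
    true_pe = rng.normal(0.0, np.sqrt(vc.sigma2_p), size=n)

    # --- fixed-effect machinery ----------------------------------------
    level_effects = {
        fac: rng.normal(0.0, cfg.fixed_effect_sd, size=cfg.n_levels_per_factor)
        for fac in FACTOR_NAMES
    }

    lo, hi = cfg.records_per_animal_range
    n_rec = rng.integers(lo, hi + 1, size=n)
    rows = []
    for i, animal in enumerate(ped.animal_ids):
        k = int(n_rec[i])
        labels = {
            fac: rng.integers(0, cfg.n_levels_per_factor, size=k)
            for fac in FACTOR_NAMES
        }
        ages = rng.uniform(*cfg.age_range_months, size=k)
        e = rng.normal(0.0, np.sqrt(vc.sigma2_e), size=k)
        fixed = sum(level_effects[fac][labels[fac]] for fac in FACTOR_NAMES)
        y = (cfg.trait_mean + fixed + cfg.age_slope * ages
             + true_bv[i] + true_pe[i] + e)
        for r in range(k):
            rows.append((
                animal, cfg.trait, y[r],
                *(f"{fac[:2]}{labels[fac][r]}" for fac in FACTOR_NAMES),
                ages[r],
            ))
    df = pd.DataFrame(rows, columns=list(PhenotypeTable.COLUMNS))
    truth = TruthSet(
        qtl_indices=qtl_idx,
        qtl_effects=effects,
        true_bv=pd.Series(true_bv, index=list(ped.animal_ids)),
        true_pe=pd.Series(true_pe, index=list(ped.animal_ids)),
        poly_bv=pd.Series(poly, index=list(ped.animal_ids)),
        varcomp_used=vc,
        seed=cfg.seed,
    )
    return PhenotypeTable(df), truth


def mask_genotypes(
    g: GenotypeMatrix, fraction: float, seed: int | np.random.Generator = 0
) -> tuple[GenotypeMatrix, list[str]]:
    """Remove a uniform random subset of individuals from the genotype
    matrix (they stay in pedigree and phenotypes), mimicking the
    ungenotyped share of a real evaluation."""
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = g.n_individuals
    n_drop = int(round(fraction * n))
    drop = set(rng.choice(n, size=n_drop, replace=False).tolist())
    keep_ids = [a for i, a in enumerate(g.individual_ids) if i not in drop]
    dropped = [a for i, a in enumerate(g.individual_ids) if i in drop]
    return g.subset_individuals(keep_ids), dropped


@dataclass
class SyntheticDataset:
    """One complete simulated study: pedigree, full and masked genotypes,
    phenotypes, and the generating truth."""

    pedigree: Pedigree
    genotypes_full: GenotypeMatrix
    genotypes: GenotypeMatrix       # after masking
    ungenotyped: list[str]
    phenotypes: PhenotypeTable
    truth: TruthSet
    config: SimConfig


def simulate_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Run the whole generator under one seed chain."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ped = simulate_pedigree(cfg, rng)
    geno = simulate_genotypes(ped, cfg, rng)
    phen, truth = simulate_phenotypes(ped, geno, cfg, rng)
    masked, dropped = mask_genotypes(geno, cfg.ungenotyped_fraction, rng)
    return SyntheticDataset(ped, geno, masked, dropped, phen, truth, cfg)


def with_qtl_architecture(cfg: SimConfig, n_qtl: int,
                          qtl_variance_fraction: float) -> SimConfig:
    """Convenience: same config with a different QTL architecture."""
    return replace(cfg, n_qtl=n_qtl, qtl_variance_fraction=qtl_variance_fraction)
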