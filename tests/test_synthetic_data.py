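"""Generator behavior: construction arithmetic, Mendelian consistency,
variance calibration, and determinism."""

import numpy as np
import pytest

from singlestep.io_formats import UNKNOWN
from singlestep.mme_solver import VarianceComponents
from singlestep.synthetic_data import (
    SimConfig,
    mask_genotypes,
    simulate_dataset,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
)


def small_cfg(**kw) -> SimConfig:
    base = dict(
        n_founders=20, n_generations=2, matings_per_generation=10,
        offspring_per_mating=2, n_snps=100, n_chromosomes=2,
        n_qtl=4, records_per_animal_range=(2, 5), seed=0,
    )
    base.update(kw)
    return SimConfig(**base)


class TestSimulatePedigree:
    def test_founders_only(self):
        ped = simulate_pedigree(SimConfig(n_founders=10, n_generations=0))
        assert len(ped) == 10 and ped.n_founders == 10

    def test_count_by_construction(self):
        cfg = SimConfig(n_founders=10, n_generations=2,
                        matings_per_generation=5, offspring_per_mating=2)
        ped = simulate_pedigree(cfg)
        assert len(ped) == 10 + 2 * 5 * 2

    def test_deterministic(self):
        cfg = small_cfg(seed=42)
        a, b = simulate_pedigree(cfg), simulate_pedigree(cfg)
        assert a.animal_ids == b.animal_ids
        np.testing.assert_array_equal(a.sire, b.sire)
        np.testing.assert_array_equal(a.dam, b.dam)

    def test_no_self_mating(self):
        ped = simulate_pedigree(small_cfg(seed=3))
        nonf = (ped.sire != UNKNOWN)
        assert not np.any(ped.sire[nonf] == ped.dam[nonf])

    def test_invalid_cfg(self):
        with pytest.raises(ValueError):
            simulate_pedigree(SimConfig(n_founders=1))


class TestSimulateGenotypes:
    def test_mendelian_consistency(self):
        cfg = small_cfg(seed=5)
        ped = simulate_pedigree(cfg)
        g = simulate_genotypes(ped, cfg)
        calls = g.calls
        for i in range(len(ped)):
            s, d = ped.sire[i], ped.dam[i]
            if s == UNKNOWN or d == UNKNOWN:
                continue
            # a child's call must be attainable from its parents' calls
            lo = (calls[s] == 2).astype(int) + (calls[d] == 2).astype(int)
            hi = 2 - (calls[s] == 0).astype(int) - (calls[d] == 0).astype(int)
            assert np.all(calls[i] >= lo) and np.all(calls[i] <= hi)

    def test_founder_frequency_binomial(self):
        # large founder panel at fixed MAF: sample frequency within 4 SD
        cfg = SimConfig(n_founders=500, n_generations=0, n_snps=50,
                        n_chromosomes=1, maf_range=(0.5, 0.5), seed=11)
        ped = simulate_pedigree(cfg)
        g = simulate_genotypes(ped, cfg)
        p = g.allele_frequencies()
        se = np.sqrt(0.5 * 0.5 / (2 * 500))
        assert np.all(np.abs(p - 0.5) < 4 * se)

    def test_deterministic(self):
        cfg = small_cfg(seed=9)
        ped = simulate_pedigree(cfg)
        g1 = simulate_genotypes(ped, cfg)
        g2 = simulate_genotypes(ped, cfg)
        np.testing.assert_array_equal(g1.calls, g2.calls)

    def test_map_sorted_and_sized(self):
        cfg = small_cfg()
        ped = simulate_pedigree(cfg)
        g = simulate_genotypes(ped, cfg)
        assert g.n_snps == cfg.n_snps
        order = np.lexsort((g.pos_bp, g.chrom))
        np.testing.assert_array_equal(order, np.arange(g.n_snps))


class TestSimulatePhenotypes:
    def test_degenerate_noise_gives_breeding_value(self):
        # variances must be positive, so use negligibly small noise terms
        cfg = small_cfg(
            varcomp=VarianceComponents(0.3, 1e-12, 1e-12),
            records_per_animal_range=(1, 1), fixed_effect_sd=0.0,
            age_slope=0.0, trait_mean=0.0, seed=2,
        )
        ped = simulate_pedigree(cfg)
        g = simulate_genotypes(ped, cfg)
        phen, truth = simulate_phenotypes(ped, g, cfg)
        y = phen.records.set_index("bull_id")["value"]
        for animal in ped.animal_ids:
            assert y[animal] == pytest.approx(truth.true_bv[animal], abs=1e-4)

    def test_additive_variance_calibrated(self):
        # Var(a) across animals ~= sigma2_a within 3 SE over >=20 seeds
        vals = []
        for seed in range(20):
            cfg = small_cfg(seed=seed, n_founders=40,
                            matings_per_generation=20)
            ped = simulate_pedigree(cfg)
            g = simulate_genotypes(ped, cfg)
            _, truth = simulate_phenotypes(ped, g, cfg)
            vals.append(truth.true_bv.to_numpy().var(ddof=1))
        mean, se = np.mean(vals), np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(mean - 0.2) <= 3 * se + 0.02

    def test_repeated_record_difference_variance(self):
        # two records of one animal share a+p; their difference ~ 2 sigma2_e
        cfg = small_cfg(
            n_founders=150, n_generations=0,
            records_per_animal_range=(2, 2), fixed_effect_sd=0.0,
            age_slope=0.0, seed=4,
        )
        ped = simulate_pedigree(cfg)
        g = simulate_genotypes(ped, cfg)
        phen, _ = simulate_phenotypes(ped, g, cfg)
        diffs = phen.records.groupby("bull_id")["value"].agg(
            lambda v: v.iloc[0] - v.iloc[1]
        )
        target = 2 * cfg.varcomp.sigma2_e
        se = target * np.sqrt(2 / (len(diffs) - 1))
        assert abs(diffs.var(ddof=1) - target) < 4 * se

    def test_truth_decomposition(self):
        cfg = small_cfg(seed=6)
        ped = simulate_pedigree(cfg)
        g = simulate_genotypes(ped, cfg)
        _, truth = simulate_phenotypes(ped, g, cfg)
        z = g.calls.astype(float)
        z -= z.mean(axis=0)
        marker = z[:, truth.qtl_indices] @ truth.qtl_effects
        np.testing.assert_allclose(
            truth.true_bv.to_numpy(), marker + truth.poly_bv.to_numpy(),
            atol=1e-10,
        )

    def test_phenotypic_variance_decomposition(self):
        # Var(y) ~= Var(fixed part) + sigma2_a + sigma2_p + sigma2_e
        cfg = small_cfg(
            n_founders=300, n_generations=0, n_snps=60,
            records_per_animal_range=(4, 4), age_slope=0.0, seed=8,
        )
        ped = simulate_pedigree(cfg)
        g = simulate_genotypes(ped, cfg)
        phen, _ = simulate_phenotypes(ped, g, cfg)
        vy = phen.records["value"].var(ddof=1)
        vc = cfg.varcomp
        fixed_var = 4 * cfg.fixed_effect_sd**2  # 4 factors
        expected = fixed_var + vc.sigma2_a + vc.sigma2_p + vc.sigma2_e
        assert abs(vy - expected) / expected < 0.35

    def test_heritability_by_midparent_regression(self):
        # regression of offspring BV on midparent BV ~= 1 for true BVs
        slopes = []
        for seed in range(10):
            cfg = small_cfg(seed=seed, n_founders=60,
                            matings_per_generation=40, n_generations=1)
            ped = simulate_pedigree(cfg)
            g = simulate_genotypes(ped, cfg)
            _, truth = simulate_phenotypes(ped, g, cfg)
            bv = truth.true_bv.to_numpy()
            kids = np.nonzero(ped.sire != UNKNOWN)[0]
            mid = 0.5 * (bv[ped.sire[kids]] + bv[ped.dam[kids]])
            slopes.append(np.polyfit(mid, bv[kids], 1)[0])
        mean, se = np.mean(slopes), np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(mean - 1.0) <= 3 * se + 0.05


class TestMaskGenotypes:
    def test_fraction_zero_unchanged(self):
        cfg = small_cfg()
        ped = simulate_pedigree(cfg)
        g = simulate_genotypes(ped, cfg)
        masked, dropped = mask_genotypes(g, 0.0, 1)
        assert dropped == [] and masked.n_individuals == g.n_individuals

    def test_fraction_counts(self):
        cfg = small_cfg(n_founders=100, n_generations=0)
        ped = simulate_pedigree(cfg)
        g = simulate_genotypes(ped, cfg)
        masked, dropped = mask_genotypes(g, 0.3, 1)
        assert masked.n_individuals == 70 and len(dropped) == 30

    def test_deterministic_and_full_mask_rejected(self):
        cfg = small_cfg()
        ped = simulate_pedigree(cfg)
        g = simulate_genotypes(ped, cfg)
        m1, d1 = mask_genotypes(g, 0.3, 7)
        m2, d2 = mask_genotypes(g, 0.3, 7)
        assert d1 == d2 and m1.individual_ids == m2.individual_ids
        with pytest.raises(ValueError):
            mask_genotypes(g, 1.0, 7)


def test_simulate_dataset_deterministic():
    cfg = small_cfg(seed=13)
    a, b = simulate_dataset(cfg), simulate_dataset(cfg)
    np.testing.assert_array_equal(a.genotypes.calls, b.genotypes.calls)
    assert a.ungenotyped == b.ungenotyped
    np.testing.assert_array_equal(
        a.phenotypes.records["value"].to_numpy(),
        b.phenotypes.records["value"].to_numpy(),
    )
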