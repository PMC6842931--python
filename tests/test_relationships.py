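"""A, F, A inverse, A22, G, and H inverse against textbook values and
dense oracles."""

import numpy as np
import pytest

from singlestep.io_formats import GenotypeMatrix
from singlestep.relationships import (
    RelationshipMatrix,
    SnpWeights,
    build_A,
    build_A_inverse,
    build_G,
    build_H_inverse,
    extract_A22,
    inbreeding,
)
from singlestep.synthetic_data import SimConfig, simulate_genotypes, simulate_pedigree

from conftest import make_random_pedigree


class TestBuildA:
    def test_unrelated_founders_identity(self, trio):
        founders = make_random_pedigree(2, 0, p_known=0.0)
        A = build_A(founders)
        np.testing.assert_allclose(A.values, np.eye(2))

    def test_trio_textbook(self, trio):
        A = build_A(trio)
        o = 2
        assert A.values[o, 0] == A.values[o, 1] == 0.5
        assert A.values[o, o] == 1.0
        assert A.values[0, 1] == 0.0

    def test_parent_offspring_mating_inbred_diagonal(self):
        from singlestep.io_formats import UNKNOWN, Pedigree
        ped = Pedigree(["p", "q", "o", "x"],
                       np.array([UNKNOWN, UNKNOWN, 0, 0]),
                       np.array([UNKNOWN, UNKNOWN, 1, 2]))
        A = build_A(ped)
        assert A.values[3, 3] == pytest.approx(1.25)

    def test_positive_semidefinite_on_random_pedigrees(self):
        for seed in range(5):
            ped = make_random_pedigree(80, seed)
            w = np.linalg.eigvalsh(build_A(ped).values)
            assert w.min() >= -1e-8


class TestInbreeding:
    def test_founder_zero(self, trio):
        assert inbreeding(trio)[0] == 0.0

    def test_full_sib_mating(self, full_sib_mating):
        F = inbreeding(full_sib_mating)
        assert F[full_sib_mating.index["x"]] == pytest.approx(0.25)

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_tabular_diagonal(self, seed):
        ped = make_random_pedigree(60, seed)
        F = inbreeding(ped)
        np.testing.assert_allclose(F, np.diag(build_A(ped).values) - 1.0,
                                   atol=1e-12)


class TestAInverse:
    def test_founders_identity(self):
        ped = make_random_pedigree(4, 0, p_known=0.0)
        np.testing.assert_allclose(build_A_inverse(ped).toarray(), np.eye(4))

    def test_trio_henderson_values(self, trio):
        Ainv = build_A_inverse(trio).toarray()
        np.testing.assert_allclose(
            Ainv,
            np.array([[1.5, 0.5, -1.0], [0.5, 1.5, -1.0], [-1.0, -1.0, 2.0]]),
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_inverse_of_tabular_A(self, seed):
        ped = make_random_pedigree(200, seed)
        A = build_A(ped).values
        Ainv = build_A_inverse(ped).toarray()
        err = np.abs(Ainv @ A - np.eye(len(ped))).max()
        assert err < 1e-8


class TestExtractA22:
    def test_all_genotyped_is_A(self, trio):
        A = build_A(trio)
        A22 = extract_A22(A, list(trio.animal_ids))
        np.testing.assert_array_equal(A22.values, A.values)

    def test_single_founder(self, trio):
        A22 = extract_A22(build_A(trio), ["s"])
        np.testing.assert_array_equal(A22.values, [[1.0]])

    def test_unknown_id_raises(self, trio):
        with pytest.raises(KeyError):
            extract_A22(build_A(trio), ["nope"])

    def test_order_follows_genotype_file(self, full_sib_mating):
        A = build_A(full_sib_mating)
        A22 = extract_A22(A, ["c2", "s"])
        assert A22.ids == ["c2", "s"]
        assert A22.values[0, 1] == A.values[full_sib_mating.index["c2"],
                                            full_sib_mating.index["s"]]


def _toy_genotypes(calls, freqs=None):
    calls = np.asarray(calls, dtype=np.int16)
    n, m = calls.shape
    return GenotypeMatrix([f"i{k}" for k in range(n)],
                          [f"s{j}" for j in range(m)], calls,
                          np.ones(m, dtype=np.int64),
                          (np.arange(m) + 1) * 100)


class TestBuildG:
    def test_single_snp_hand_computed(self):
        g = _toy_genotypes([[2], [1], [0]])
        w = SnpWeights.identity(np.array([0.5]))
        assert w.q == pytest.approx(2.0)
        G = build_G(g, w, blend_alpha=0.0)
        z = np.array([1.0, 0.0, -1.0])
        np.testing.assert_allclose(G.values, 2.0 * np.outer(z, z))
        np.testing.assert_allclose(np.diag(G.values), [2.0, 0.0, 2.0])

    def test_zero_weights_zero_G(self):
        g = _toy_genotypes([[2, 0], [1, 1], [0, 2]])
        w = SnpWeights(d=np.zeros(2), q=1.0, freqs=np.array([0.5, 0.5]))
        G = build_G(g, w, blend_alpha=0.0)
        np.testing.assert_allclose(G.values, 0.0)

    def test_mean_diagonal_near_one_on_hwe_panel(self):
        cfg = SimConfig(n_founders=400, n_generations=0, n_snps=800,
                        n_chromosomes=4, seed=21)
        ped = simulate_pedigree(cfg)
        g = simulate_genotypes(ped, cfg)
        w = SnpWeights.identity(g.allele_frequencies())
        G = build_G(g, w, blend_alpha=0.0)
        assert abs(np.diag(G.values).mean() - 1.0) < 0.05

    def test_monomorphic_frequency_rejected(self):
        g = _toy_genotypes([[2], [2]])
        w = SnpWeights(d=np.ones(1), q=1.0, freqs=np.array([1.0]))
        with pytest.raises(ValueError, match="strictly in"):
            build_G(g, w, blend_alpha=0.0)

    def test_column_order_invariance(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, size=(30, 40)).astype(np.int16)
        g = _toy_genotypes(calls)
        w = SnpWeights.identity(g.allele_frequencies())
        G1 = build_G(g, w, blend_alpha=0.0)
        perm = rng.permutation(40)
        g2 = _toy_genotypes(calls[:, perm])
        w2 = SnpWeights.identity(g2.allele_frequencies())
        G2 = build_G(g2, w2, blend_alpha=0.0)
        np.testing.assert_allclose(G1.values, G2.values, atol=1e-12)

    def test_scale_consistency_double_d_half_q(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 3, size=(20, 30)).astype(np.int16)
        g = _toy_genotypes(calls)
        w = SnpWeights.identity(g.allele_frequencies())
        G1 = build_G(g, w, blend_alpha=0.0)
        w2 = SnpWeights(d=2 * w.d, q=w.q / 2, freqs=w.freqs)
        G2 = build_G(g, w2, blend_alpha=0.0)
        np.testing.assert_allclose(G1.values, G2.values, atol=1e-12)

    def test_blend_requires_A22_and_valid_alpha(self):
        g = _toy_genotypes([[2], [1], [0]])
        w = SnpWeights.identity(np.array([0.5]))
        with pytest.raises(ValueError):
            build_G(g, w, blend_alpha=0.05)
        with pytest.raises(ValueError):
            build_G(g, w, blend_alpha=1.0)


class TestHInverse:
    def _setup(self, seed, n=100, n_geno=40):
        ped = make_random_pedigree(n, seed)
        A = build_A(ped)
        Ainv = build_A_inverse(ped)
        genotyped = list(np.array(ped.animal_ids)[-n_geno:]) if n_geno else []
        A22 = extract_A22(A, genotyped) if n_geno else None
        return ped, A, Ainv, A22, genotyped

    def test_no_genotyped_equals_A_inverse(self):
        ped, A, Ainv, _, _ = self._setup(0, n_geno=0)
        H = build_H_inverse(Ainv, None, None, [], list(ped.animal_ids))
        np.testing.assert_allclose(H.values.toarray(), Ainv.toarray())

    def test_G_equal_A22_cancels(self):
        ped, A, Ainv, A22, genotyped = self._setup(1)
        G = RelationshipMatrix(list(genotyped), A22.values.copy(), kind="G")
        H = build_H_inverse(Ainv, A22, G, genotyped, list(ped.animal_ids))
        np.testing.assert_allclose(H.values.toarray(), Ainv.toarray(),
                                   atol=1e-8)

    def test_correction_confined_to_genotyped_block(self):
        ped, A, Ainv, A22, genotyped = self._setup(2)
        rng = np.random.default_rng(0)
        B = rng.normal(size=(len(genotyped), len(genotyped)))
        G = RelationshipMatrix(
            list(genotyped), A22.values + 0.1 * (B @ B.T) / len(genotyped),
            kind="G",
        )
        H = build_H_inverse(Ainv, A22, G, genotyped, list(ped.animal_ids))
        Hd = H.values.toarray()
        assert np.abs(Hd - Hd.T).max() < 1e-10
        diff = Hd - Ainv.toarray()
        mask = np.zeros(len(ped), dtype=bool)
        mask[H.genotyped_idx] = True
        assert np.abs(diff[~mask][:, ~mask]).max() < 1e-12
        assert np.abs(diff[np.ix_(mask, mask)]).max() > 0
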