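"""Shared fixtures: hand-built pedigrees, a random-pedigree factory for
oracle comparisons, and a 20-SNP QC fixture with hand-counted violations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from singlestep.io_formats import (
    UNKNOWN,
    GenotypeMatrix,
    Pedigree,
    PhenotypeTable,
)


@pytest.fixture
def trio() -> Pedigree:
    """Two unrelated founders and their offspring."""
    return Pedigree(["s", "d", "o"], np.array([UNKNOWN, UNKNOWN, 0]),
                    np.array([UNKNOWN, UNKNOWN, 1]))


@pytest.fixture
def full_sib_mating() -> Pedigree:
    """Founders, two full sibs, and a full-sib-mating offspring (F=0.25)."""
    return Pedigree(
        ["s", "d", "c1", "c2", "x"],
        np.array([UNKNOWN, UNKNOWN, 0, 0, 2]),
        np.array([UNKNOWN, UNKNOWN, 1, 1, 3]),
    )


def make_random_pedigree(n: int, seed: int, p_known: float = 0.8) -> Pedigree:
    """Overlapping-generation random pedigree: each animal after the first
    few draws each parent (independently, with probability ``p_known``)
    uniformly among earlier animals."""
    rng = np.random.default_rng(seed)
    sire = np.full(n, UNKNOWN, dtype=np.int64)
    dam = np.full(n, UNKNOWN, dtype=np.int64)
    for i in range(2, n):
        if rng.random() < p_known:
            sire[i] = rng.integers(0, i)
        if rng.random() < p_known:
            d = rng.integers(0, i)
            # avoid an animal being both sire and dam of the same offspring
            dam[i] = d if d != sire[i] else (d - 1 if d > 0 else UNKNOWN)
    return Pedigree([f"P{i}" for i in range(n)], sire, dam)


@pytest.fixture
def random_pedigree_factory():
    return make_random_pedigree


def make_qc_fixture() -> tuple[GenotypeMatrix, dict[str, set[str]]]:
    """100 individuals x 20 SNPs with hand-counted QC violations.

    * qcsnp1..qcsnp17: exact HWE proportions at p = 0.3 (49/42/9), complete
      calls -> pass all filters;
    * qcsnp18: 11 missing calls (call rate 0.89 < 0.90) -> fails call rate,
      observed calls in HWE at p ~= 0.3;
    * qcsnp19: monomorphic (all 0) -> fails MAF;
    * qcsnp20: 50 x AA and 50 x BB, no heterozygotes -> chi-square 100,
      p << 1e-6 -> fails HWE.
    """
    n = 100
    cols = []
    good = np.array([0] * 49 + [1] * 42 + [2] * 9)
    for _ in range(17):
        cols.append(good.copy())
    cr = np.array([GenotypeMatrix.MISSING] * 11 + [0] * 44 + [1] * 36 + [2] * 9)
    cols.append(cr)
    cols.append(np.zeros(n, dtype=int))
    cols.append(np.array([0] * 50 + [2] * 50))
    calls = np.column_stack(cols).astype(np.int16)
    g = GenotypeMatrix(
        individual_ids=[f"I{i}" for i in range(n)],
        snp_ids=[f"qcsnp{j + 1}" for j in range(20)],
        calls=calls,
        chrom=np.ones(20, dtype=np.int64),
        pos_bp=(np.arange(20) + 1) * 1000,
    )
    expected = {
        "callrate": {"qcsnp18"},
        "maf": {"qcsnp19"},
        "hwe": {"qcsnp20"},
    }
    return g, expected


@pytest.fixture
def qc_fixture():
    return make_qc_fixture()


@pytest.fixture
def tiny_phenotypes() -> PhenotypeTable:
    rows = [
        ("b1", "VE", 6.5, "ys1", "st1", "i1", "c1", 30.0),
        ("b1", "VE", 35.0, "ys1", "st2", "i1", "c2", 31.0),
        ("b2", "VE", 8.0, "ys2", "st1", "i2", "c1", 40.0),
        ("b2", "MS", 0.70, "ys1", "st1", "i1", "c1", 40.0),
        ("b2", "MS", 1.20, "ys1", "st1", "i1", "c1", 41.0),
    ]
    return PhenotypeTable(pd.DataFrame(rows, columns=list(PhenotypeTable.COLUMNS)))
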