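"""Weighted single-step GWAS: backsolve SNP effects from GEBVs, reweight,
rebuild G, re-solve.

The loop starts at D = I, solves the single-step MME, converts the
genotyped animals' GEBVs into SNP effects via u = q D Z' G⁻¹ a_g (the
conversion factor is the G scaling constant q, so that at blend 0 the
projection identity Z u = a_g holds exactly), derives weights
d_i = u_i² 2p_i(1−p_i), normalizes them to keep the total genetic
variance constant, and repeats.  One reweighting pass (two solves,
``n_iter = 2``) is the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, Pedigree, PhenotypeTable
from .mme_solver import (
    ModelFit,
    ModelSpec,
    VarianceComponents,
    build_design,
    solve_mme,
)
from .relationships import (
    RelationshipMatrix,
    SnpWeights,
    build_A,
    build_A_inverse,
    build_G,
    build_H_inverse,
    extract_A22,
)

log = logging.getLogger(__name__)


@dataclass
class SnpEffectSet:
    """Per-SNP effects and weights of one iteration.

    ``weights`` holds the D actually used in this iteration's G;
    ``d_next`` is the normalized weight vector derived from this
    iteration's effects (what the next iteration would use).
    """

    u_hat: np.ndarray
    weights: SnpWeights
    d_next: np.ndarray
    iteration: int          # 1 == D = I

    def to_frame(self, g: GenotypeMatrix) -> pd.DataFrame:
        return pd.DataFrame({
            "snp_id": g.snp_ids,
            "chrom": g.chrom,
            "pos_bp": g.pos_bp,
            "u_hat": self.u_hat,
            "d_used": self.weights.d,
            "d_next": self.d_next,
        })


@dataclass
class WssgwasResult:
    """All iterations of the weighting loop plus the final model fit."""

    iterations: list[SnpEffectSet]
    final_fit: ModelFit
    genotyped_ids: list[str]
    n_iter: int
    blend_alpha: float
    seed: int | None = None

    @property
    def final_effects(self) -> SnpEffectSet:
        return self.iterations[-1]


def backsolve_snp_effects(
    a_g: np.ndarray,
    Z: np.ndarray,
    w: SnpWeights,
    G: RelationshipMatrix,
) -> np.ndarray:
    """Convert genotyped animals' GEBVs to SNP effects: u = q D Z' G⁻¹ a_g.

    ``G`` must be the matrix used in the solve.  With an unblended G this
    is the exact BLUP backsolve: Z u = Z D Z' q (Z D Z' q)⁻¹ a_g = a_g.
    """
    a_g = np.asarray(a_g, dtype=float)
    if Z.shape[0] != len(a_g):
        raise ValueError(
            f"Z has {Z.shape[0]} rows but a_g has {len(a_g)} entries"
        )
    if Z.shape[1] != len(w.d):
        raise ValueError("weight vector length does not match SNP count")
    rhs = np.linalg.solve(G.values, a_g)
    return w.q * w.d * (Z.T @ rhs)


def update_weights(u_hat: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Raw SNP weights d_i = u_i² · 2 p_i (1 − p_i)."""
    u_hat = np.asarray(u_hat, dtype=float)
    p = np.asarray(freqs, dtype=float)
    return u_hat**2 * 2.0 * p * (1.0 - p)


def normalize_weights(d_raw: np.ndarray) -> np.ndarray:
    """Rescale weights so their sum equals the SNP count m.

    Keeps the total genetic variance constant across iterations:
    sum(d) = m = trace of the iteration-1 identity D.
    """
    d_raw = np.asarray(d_raw, dtype=float)
    total = d_raw.sum()
    if total <= 0:
        raise ValueError("all SNP weights zero; no genetic signal to normalize")
    return d_raw * (len(d_raw) / total)


def run_wssgwas(
    ped: Pedigree,
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    vc: VarianceComponents,
    n_iter: int = 2,
    blend_alpha: float = 0.05,
    model: ModelSpec = ModelSpec(),
    seed: int | None = None,
) -> WssgwasResult:
    """Run the full weighting loop on a prepared (QC-passed) dataset.

    ``n_iter`` counts solves: 1 is plain ssGBLUP plus one backsolve, the
    default 2 adds one reweighting pass.  G and H⁻¹ are rebuilt from
    scratch each iteration.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    ped.validate()
    genotyped_ids = list(genotypes.individual_ids)

    A = build_A(ped)
    Ainv = build_A_inverse(ped)
    A22 = extract_A22(A, genotyped_ids)
    freqs = genotypes.allele_frequencies()
    Z = genotypes.centered(freqs)
    X, Z_a, W, y, x_names, rec_animals = build_design(phenotypes, ped, model)

    gidx_in_ped = [ped.index[a] for a in genotyped_ids]
    weights = SnpWeights.identity(freqs)
    iterations: list[SnpEffectSet] = []
    fit: ModelFit | None = None
    for it in range(1, n_iter + 1):
        G = build_G(genotypes, weights, blend_alpha=blend_alpha, A22=A22)
        Hinv = build_H_inverse(Ainv, A22, G, genotyped_ids, list(ped.animal_ids))
        fit = solve_mme(X, Z_a, W, y, Hinv, vc,
                        x_names=x_names, record_animals=rec_animals)
        a_g = fit.gebv.to_numpy()[gidx_in_ped]
        u_hat = backsolve_snp_effects(a_g, Z, weights, G)
        d_next = normalize_weights(update_weights(u_hat, freqs))
        iterations.append(SnpEffectSet(
            u_hat=u_hat, weights=weights, d_next=d_next, iteration=it,
        ))
        log.info("iteration %d: |u| max %.4g, MME residual %.2e",
                 it, np.abs(u_hat).max(), fit.convergence)
        weights = SnpWeights(d=d_next, q=weights.q, freqs=freqs)
    assert fit is not None
    return WssgwasResult(
        iterations=iterations,
        final_fit=fit,
        genotyped_ids=genotyped_ids,
        n_iter=n_iter,
        blend_alpha=blend_alpha,
        seed=seed,
    )


def write_effects(result: WssgwasResult, g: GenotypeMatrix, path,
                  config_echo: dict | None = None) -> None:
    """Write per-iteration SNP effects/weights as TSV with a config header."""
    with open(path, "w") as fh:
        for key, val in (config_echo or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write("iteration\tsnp_id\tchrom\tpos_bp\tu_hat\td_used\td_next\n")
        for eff in result.iterations:
            frame = eff.to_frame(g)
            for row in frame.itertuples(index=False):
                fh.write(
                    f"{eff.iteration}\t{row.snp_id}\t{row.chrom}\t{row.pos_bp}\t"
                    f"{row.u_hat:.10g}\t{row.d_used:.10g}\t{row.d_next:.10g}\n"
                )
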