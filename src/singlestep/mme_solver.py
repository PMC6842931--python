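"""Mixed-model equations for the repeatability animal model.

Model: y = Xb + Za + Wp + e with a ~ N(0, H sigma2_a),
p ~ N(0, I sigma2_p), e ~ N(0, I sigma2_e).  Fixed effects are the
combined year-season class, station (AI center), collection-interval
class, collection-number class, and an age covariate; the random animal
effect runs over every pedigree animal (recordless ancestors included)
through H, and the permanent-environment effect over animals with
records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .io_formats import Pedigree, PhenotypeTable
from .relationships import HInverse

log = logging.getLogger(__name__)


@dataclass
class VarianceComponents:
    """Additive (sigma2_a), permanent-environment (sigma2_p) and residual
    (sigma2_e) variances in squared trait units; all must be positive."""

    sigma2_a: float
    sigma2_p: float
    sigma2_e: float

    def __post_init__(self) -> None:
        for name in ("sigma2_a", "sigma2_p", "sigma2_e"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def lambda_a(self) -> float:
        return self.sigma2_e / self.sigma2_a

    @property
    def lambda_p(self) -> float:
        return self.sigma2_e / self.sigma2_p


@dataclass
class ModelSpec:
    """Fixed factors and covariates of the repeatability model."""

    factors: tuple[str, ...] = (
        "year_season", "station", "interval_class", "collection_class",
    )
    covariates: tuple[str, ...] = ("age_months",)


@dataclass
class ModelFit:
    """Solutions of the mixed-model equations."""

    beta: pd.Series                 # indexed by fixed-effect column name
    gebv: pd.Series                 # indexed by animal id, all pedigree animals
    pe: pd.Series                   # indexed by recorded-animal id
    convergence: float              # relative residual of the linear system
    record_animals: list[str] = field(default_factory=list)


def build_design(
    t: PhenotypeTable,
    ped: Pedigree,
    spec: ModelSpec = ModelSpec(),
) -> tuple[sparse.csr_matrix, sparse.csr_matrix, sparse.csr_matrix,
           np.ndarray, list[str], list[str]]:
    """Assemble X (fixed), Z_a (animal) and W (permanent environment).

    X uses reference-level (first-level-dropped) dummy coding per factor
    plus an intercept and the covariate columns; factors with a single
    observed level are dropped with a warning.  Returns
    (X, Z_a, W, y, x_names, record_animals).
    """
    df = t.records
    n = len(df)
    unknown = sorted(set(df["bull_id"].astype(str)) - set(ped.animal_ids))
    if unknown:
        raise KeyError(f"records for animals not in pedigree: {unknown[:5]}")

    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    for fac in spec.factors:
        levels = sorted(df[fac].astype(str).unique())
        if len(levels) < 2:
            log.warning("factor %s has a single level; dropped", fac)
            continue
        for lev in levels[1:]:   # first level is the reference
            cols.append((df[fac].astype(str) == lev).to_numpy(float))
            names.append(f"{fac}={lev}")
    for cov in spec.covariates:
        cols.append(df[cov].to_numpy(float))
        names.append(cov)
    X = sparse.csr_matrix(np.column_stack(cols))

    bulls = df["bull_id"].astype(str).to_numpy()
    animal_col = np.array([ped.index[b] for b in bulls])
    Z_a = sparse.coo_matrix(
        (np.ones(n), (np.arange(n), animal_col)), shape=(n, len(ped))
    ).tocsr()

    record_animals = sorted(set(bulls), key=lambda b: ped.index[b])
    rec_index = {b: k for k, b in enumerate(record_animals)}
    W = sparse.coo_matrix(
        (np.ones(n), (np.arange(n), [rec_index[b] for b in bulls])),
        shape=(n, len(record_animals)),
    ).tocsr()

    y = df["value"].to_numpy(float)
    return X, Z_a, W, y, names, record_animals


def solve_mme(
    X: sparse.spmatrix,
    Z_a: sparse.spmatrix,
    W: sparse.spmatrix,
    y: np.ndarray,
    Hinv: HInverse,
    vc: VarianceComponents,
    x_names: list[str] | None = None,
    record_animals: list[str] | None = None,
) -> ModelFit:
    """Solve Henderson's mixed-model equations by direct sparse factorization.

    The coefficient matrix carries lambda_a = sigma2_e/sigma2_a on H⁻¹ and
    lambda_p = sigma2_e/sigma2_p on the permanent-environment identity
    block.  The reported convergence is the relative residual of the
    solved linear system.
    """
    for m in (X, Z_a, W):
        if not np.all(np.isfinite(m.data if sparse.issparse(m) else m)):
            raise ValueError("non-finite entries in design matrices")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite entries in y")

    X = sparse.csr_matrix(X)
    Z_a = sparse.csr_matrix(Z_a)
    W = sparse.csr_matrix(W)
    n_f, n_a, n_p = X.shape[1], Z_a.shape[1], W.shape[1]
    lam_a, lam_p = vc.lambda_a, vc.lambda_p

    C = sparse.bmat(
        [
            [X.T @ X, X.T @ Z_a, X.T @ W],
            [Z_a.T @ X, Z_a.T @ Z_a + lam_a * Hinv.values, Z_a.T @ W],
            [W.T @ X, W.T @ Z_a, W.T @ W + lam_p * sparse.identity(n_p)],
        ],
        format="csc",
    )
    rhs = np.concatenate([X.T @ y, Z_a.T @ y, W.T @ y])
    sol = spsolve(C, rhs)
    if not np.all(np.isfinite(sol)):
        raise FloatingPointError("mixed-model equations produced non-finite solutions")
    resid = np.linalg.norm(C @ sol - rhs)
    denom = np.linalg.norm(rhs)
    convergence = resid / denom if denom > 0 else resid

    beta = pd.Series(sol[:n_f], index=x_names or [f"b{i}" for i in range(n_f)])
    gebv = pd.Series(sol[n_f:n_f + n_a], index=Hinv.ids)
    pe = pd.Series(
        sol[n_f + n_a:],
        index=record_animals or [f"pe{i}" for i in range(n_p)],
    )
    return ModelFit(beta=beta, gebv=gebv, pe=pe, convergence=convergence,
                    record_animals=list(record_animals or []))


def reliability_proxy(fit: ModelFit, t: PhenotypeTable) -> pd.DataFrame:
    """Per-animal diagnostic summary: record counts and solution sizes.

    Not a prediction-error-variance computation; animals without records
    are flagged (their GEBV rests entirely on relationships).
    """
    counts = t.records["bull_id"].astype(str).value_counts()
    rows = []
    for animal in fit.gebv.index:
        n_rec = int(counts.get(animal, 0))
        rows.append({
            "animal": animal,
            "n_records": n_rec,
            "gebv": fit.gebv[animal],
            "pe": fit.pe.get(animal, np.nan),
            "no_records": n_rec == 0,
        })
    return pd.DataFrame(rows)
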