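"""Pedigree and genomic relationship matrices for single-step evaluation.

Implements the tabular numerator relationship matrix A, Meuwissen-Luo
inbreeding coefficients, Henderson-rule sparse A inverse, the VanRaden
genomic matrix G = ZDZ'q with centered 0/1/2 coding, and the single-step
inverse H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A22⁻¹].
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .io_formats import UNKNOWN, GenotypeMatrix, Pedigree


@dataclass
class RelationshipMatrix:
    """Dense symmetric relationship matrix with its animal-id index."""

    ids: list[str]
    values: np.ndarray
    kind: str = "A"     # one of {A, A22, G, G_blended}

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("relationship matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("relationship matrix not symmetric")


@dataclass
class HInverse:
    """Sparse H⁻¹ over all pedigree animals.

    Equals A⁻¹ plus a correction confined to the genotyped x genotyped
    block (``genotyped_idx`` in pedigree order).
    """

    ids: list[str]
    values: sparse.csr_matrix
    genotyped_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


@dataclass
class SnpWeights:
    """Diagonal SNP weights D, scaling factor q, and allele frequencies."""

    d: np.ndarray
    q: float
    freqs: np.ndarray

    @classmethod
    def identity(cls, freqs: np.ndarray) -> "SnpWeights":
        """Iteration-1 weights: D = I, q = 1 / sum 2p(1-p)."""
        freqs = np.asarray(freqs, dtype=float)
        denom = float(np.sum(2.0 * freqs * (1.0 - freqs)))
        if denom <= 0:
            raise ValueError("all SNPs monomorphic; q undefined")
        return cls(d=np.ones_like(freqs), q=1.0 / denom, freqs=freqs)


def _mendelian_variance(i: int, sire: np.ndarray, dam: np.ndarray,
                        F: np.ndarray) -> float:
    """Variance of the Mendelian sampling term of animal i.

    Equals 0.5 − 0.25(F_s + F_d) with F = −1 substituted for an unknown
    parent, giving 1 for founders and 0.75 − 0.25 F for one known parent.
    """
    fs = F[sire[i]] if sire[i] != UNKNOWN else -1.0
    fd = F[dam[i]] if dam[i] != UNKNOWN else -1.0
    return 0.5 - 0.25 * (fs + fd)


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Meuwissen-Luo inbreeding coefficients, F_i = ½ a_{sire(i),dam(i)}.

    Traces each animal's ancestor list with path coefficients L, never
    forming the dense A.
    """
    n = len(ped)
    sire, dam = ped.sire, ped.dam
    F = np.zeros(n)
    for i in range(n):
        if sire[i] == UNKNOWN or dam[i] == UNKNOWN:
            F[i] = 0.0
            continue
        # F_i = sum_j L_j^2 d_j - 1 over ancestors j of i (incl. i)
        L: dict[int, float] = {i: 1.0}
        heap = [-i]
        queued = {i}
        acc = -1.0
        while heap:
            j = -heapq.heappop(heap)
            queued.discard(j)
            lj = L.pop(j)
            acc += lj * lj * _mendelian_variance(j, sire, dam, F)
            for par in (sire[j], dam[j]):
                if par != UNKNOWN:
                    L[par] = L.get(par, 0.0) + 0.5 * lj
                    if par not in queued:
                        heapq.heappush(heap, -par)
                        queued.add(par)
        F[i] = acc
    return F


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Dense numerator relationship matrix by the tabular method."""
    ped.validate()
    n = len(ped)
    a = np.zeros((n, n))
    for j in range(n):
        s, d = ped.sire[j], ped.dam[j]
        for i in range(j):
            v = 0.0
            if s != UNKNOWN:
                v += 0.5 * a[i, s]
            if d != UNKNOWN:
                v += 0.5 * a[i, d]
            a[i, j] = a[j, i] = v
        a[j, j] = 1.0 + (0.5 * a[s, d] if s != UNKNOWN and d != UNKNOWN else 0.0)
    return RelationshipMatrix(list(ped.animal_ids), a, kind="A")


def build_A_inverse(ped: Pedigree) -> sparse.csr_matrix:
    """Sparse A⁻¹ by Henderson's rules with Meuwissen-Luo inbreeding.

    Never forms the dense A: each animal contributes 1/m_i to its own
    diagonal and the usual −½ / ¼ cross terms with its known parents,
    where m_i is its Mendelian sampling variance.
    """
    ped.validate()
    n = len(ped)
    F = inbreeding(ped)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(r: int, c: int, v: float) -> None:
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        alpha = 1.0 / _mendelian_variance(i, ped.sire, ped.dam, F)
        parents = [p for p in (ped.sire[i], ped.dam[i]) if p != UNKNOWN]
        add(i, i, alpha)
        for p in parents:
            add(i, p, -0.5 * alpha)
            add(p, i, -0.5 * alpha)
        for p in parents:
            for r in parents:
                add(p, r, 0.25 * alpha)
    return sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def extract_A22(A: RelationshipMatrix, genotyped_ids: list[str]) -> RelationshipMatrix:
    """Principal submatrix of A for the genotyped animals, in their order."""
    index = {a: i for i, a in enumerate(A.ids)}
    missing = [g for g in genotyped_ids if g not in index]
    if missing:
        raise KeyError(f"genotyped ids not in pedigree: {missing[:5]}")
    idx = np.array([index[g] for g in genotyped_ids])
    return RelationshipMatrix(
        list(genotyped_ids), A.values[np.ix_(idx, idx)].copy(), kind="A22"
    )


def build_G(
    g: GenotypeMatrix,
    w: SnpWeights,
    blend_alpha: float = 0.05,
    A22: RelationshipMatrix | None = None,
) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix G = ZDZ'q, optionally blended.

    Z is the marker matrix centered by twice the allele frequency, D the
    diagonal SNP weights, and q = 1/Σ 2p(1−p).  With ``blend_alpha`` > 0
    the result is (1−α)·G_raw + α·A22, which guarantees invertibility.
    """
    if not (0.0 <= blend_alpha < 1.0):
        raise ValueError("blend_alpha must be in [0, 1)")
    p = np.asarray(w.freqs, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("allele frequencies must be strictly in (0,1); run QC first")
    Z = g.centered(p)
    G_raw = (Z * w.d) @ Z.T * w.q
    if blend_alpha > 0.0:
        if A22 is None:
            raise ValueError("A22 required when blend_alpha > 0")
        if A22.ids != g.individual_ids:
            raise ValueError("A22 id order must match genotype matrix")
        values = (1.0 - blend_alpha) * G_raw + blend_alpha * A22.values
        kind = "G_blended"
    else:
        values = G_raw
        kind = "G"
    values = 0.5 * (values + values.T)   # kill asymmetric rounding noise
    return RelationshipMatrix(list(g.individual_ids), values, kind=kind)


def build_H_inverse(
    Ainv: sparse.spmatrix,
    A22: RelationshipMatrix,
    G: RelationshipMatrix,
    genotyped_ids: list[str],
    pedigree_ids: list[str],
) -> HInverse:
    """Single-step inverse H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A22⁻¹].

    The correction is added only on the genotyped x genotyped block, in
    pedigree index order.
    """
    index = {a: i for i, a in enumerate(pedigree_ids)}
    gidx = np.array([index[a] for a in genotyped_ids], dtype=int)
    n = len(pedigree_ids)
    if len(genotyped_ids) == 0:
        return HInverse(list(pedigree_ids), sparse.csr_matrix(Ainv), gidx)
    if G.ids != list(genotyped_ids) or A22.ids != list(genotyped_ids):
        raise ValueError("G and A22 must be indexed by genotyped_ids in order")
    try:
        Ginv = np.linalg.inv(G.values)
        A22inv = np.linalg.inv(A22.values)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular G or A22; blend G toward A22 or deepen the pedigree"
        ) from err
    corr = Ginv - A22inv
    rows = np.repeat(gidx, len(gidx))
    cols = np.tile(gidx, len(gidx))
    corr_sp = sparse.coo_matrix((corr.ravel(), (rows, cols)), shape=(n, n))
    H = (sparse.csr_matrix(Ainv) + corr_sp.tocsr()).tocsr()
    return HInverse(list(pedigree_ids), H, gidx)
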