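"""Readers, writers, and quality-control filters for pedigree, genotype,
and phenotype files.

File dialects are deliberately plain text so fixtures stay hand-editable:

* pedigree: three columns (animal, sire, dam), whitespace- or
  comma-delimited, ``0`` or empty meaning unknown parent;
* genotypes: one row per individual (id followed by 0/1/2/NA calls) plus a
  three-column SNP map (snp_id, chromosome, position_bp);
* phenotypes: delimited text with a header
  (bull_id, trait, value, year_season, station, interval_class,
  collection_class, age_months).
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

UNKNOWN = -1  # internal parent index for an unknown sire/dam

#: legal value range per trait after error-data removal.  MS is recorded as
#: a fraction (1.0 == 100 %); NSP = VE*SC and NMSP = NSP*MS inherit the
#: product of their factors' ranges and must be non-negative.
TRAIT_RANGES: dict[str, tuple[float, float]] = {
    "VE": (0.0, 30.0),
    "SC": (0.0, 40.0),
    "MS": (0.0, 1.0),
    "NSP": (0.0, 1200.0),
    "NMSP": (0.0, 1200.0),
}

_SPLIT = re.compile(r"[,\s]+")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Pedigree:
    """Topologically ordered pedigree (parents precede offspring).

    ``sire``/``dam`` hold integer indices into ``animal_ids`` or
    :data:`UNKNOWN` (-1) for an unknown parent.
    """

    animal_ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {a: i for i, a in enumerate(self.animal_ids)}

    def __len__(self) -> int:
        return len(self.animal_ids)

    @property
    def n_founders(self) -> int:
        return int(np.sum((self.sire == UNKNOWN) & (self.dam == UNKNOWN)))

    def validate(self) -> None:
        """Check the topological invariant: parents precede offspring."""
        for i in range(len(self)):
            for p in (self.sire[i], self.dam[i]):
                if p != UNKNOWN and p >= i:
                    raise ValueError(
                        f"pedigree not topologically sorted: parent "
                        f"{self.animal_ids[p]!r} of {self.animal_ids[i]!r} "
                        "does not precede it"
                    )


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs in 0/1/2 coding; missing calls are ``-9``.

    ``chrom``/``pos_bp`` form the SNP map and are sorted by
    (chromosome, position); columns of ``calls`` follow the map order.
    """

    individual_ids: list[str]
    snp_ids: list[str]
    calls: np.ndarray           # int16, entries in {0,1,2,MISSING}
    chrom: np.ndarray           # int, 1..29
    pos_bp: np.ndarray          # int, 1-based

    MISSING = -9

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def allele_frequencies(self) -> np.ndarray:
        """Observed frequency of the '2' allele per SNP, missing excluded."""
        obs = self.calls != self.MISSING
        counts = np.where(obs, self.calls, 0).sum(axis=0)
        n_obs = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p = counts / (2.0 * n_obs)
        return p

    def centered(self, freqs: np.ndarray | None = None) -> np.ndarray:
        """Column-centered marker matrix Z (call - 2p).

        Missing calls are mean-imputed (to 2p, i.e. centered value 0); the
        number of imputed cells is logged.
        """
        if freqs is None:
            freqs = self.allele_frequencies()
        z = self.calls.astype(float)
        miss = self.calls == self.MISSING
        n_miss = int(miss.sum())
        if n_miss:
            log.warning("mean-imputing %d missing genotype calls", n_miss)
            z[miss] = (2.0 * freqs)[np.nonzero(miss)[1]]
        return z - 2.0 * freqs

    def subset_individuals(self, keep: list[str]) -> "GenotypeMatrix":
        idx = {a: i for i, a in enumerate(self.individual_ids)}
        rows = [idx[a] for a in keep]
        return GenotypeMatrix(
            individual_ids=list(keep),
            snp_ids=list(self.snp_ids),
            calls=self.calls[rows, :].copy(),
            chrom=self.chrom.copy(),
            pos_bp=self.pos_bp.copy(),
        )


@dataclass
class PhenotypeTable:
    """Repeated-record phenotypes with fixed-effect class labels.

    ``records`` columns: bull_id, trait, value, year_season, station,
    interval_class, collection_class, age_months.
    """

    records: pd.DataFrame

    COLUMNS = (
        "bull_id", "trait", "value", "year_season", "station",
        "interval_class", "collection_class", "age_months",
    )

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.records)

    def for_trait(self, trait: str) -> pd.DataFrame:
        return self.records[self.records["trait"] == trait]


@dataclass
class QcReport:
    """Per-filter accounting for SNP quality control.

    A SNP is attributed to every filter it fails (filters are evaluated
    jointly on the input matrix), so failure lists may overlap.
    """

    n_input_snps: int
    fail_callrate: list[str]
    fail_maf: list[str]
    fail_hwe: list[str]

    @property
    def n_fail_callrate(self) -> int:
        return len(self.fail_callrate)

    @property
    def n_fail_maf(self) -> int:
        return len(self.fail_maf)

    @property
    def n_fail_hwe(self) -> int:
        return len(self.fail_hwe)

    @property
    def failed(self) -> set[str]:
        return set(self.fail_callrate) | set(self.fail_maf) | set(self.fail_hwe)

    @property
    def n_pass(self) -> int:
        return self.n_input_snps - len(self.failed)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("input", self.n_input_snps),
            ("fail_callrate", self.n_fail_callrate),
            ("fail_maf", self.n_fail_maf),
            ("fail_hwe", self.n_fail_hwe),
            ("pass", self.n_pass),
        ]
        return pd.DataFrame(rows, columns=["stage", "n_snps"])


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _tokenize(line: str) -> list[str]:
    return [t for t in _SPLIT.split(line.strip()) if t]


def read_pedigree(path: str | Path | io.TextIOBase) -> Pedigree:
    """Parse a three-column pedigree file and topologically sort it.

    Unknown parents are coded ``0`` or empty.  Raises on duplicate animal
    rows and on parentage cycles (naming one member of the cycle).
    """
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
    else:
        lines = Path(path).read_text().splitlines()

    animals: dict[str, tuple[str | None, str | None]] = {}
    order: list[str] = []
    for ln, raw in enumerate(lines, 1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        tok = _tokenize(raw)
        if len(tok) == 2:
            tok.append("0")
        if len(tok) != 3:
            raise ValueError(f"line {ln}: expected 3 columns, got {len(tok)}")
        a, s, d = tok
        if a in animals:
            raise ValueError(f"duplicate animal row: {a!r} (line {ln})")
        animals[a] = (None if s in ("0", "") else s, None if d in ("0", "") else d)
        order.append(a)

    # parents referenced but never listed become founders
    for a in order:
        for p in animals[a]:
            if p is not None and p not in animals:
                animals[p] = (None, None)
                order.append(p)

    # Kahn topological sort, stable in input order
    indeg = {a: sum(p is not None for p in animals[a]) for a in animals}
    children: dict[str, list[str]] = {a: [] for a in animals}
    for a in order:
        for p in animals[a]:
            if p is not None:
                children[p].append(a)
    ready = [a for a in order if indeg[a] == 0]
    sorted_ids: list[str] = []
    seen = set()
    while ready:
        a = ready.pop(0)
        sorted_ids.append(a)
        seen.add(a)
        for c in children[a]:
            indeg[c] -= 1
            if indeg[c] == 0:
                ready.append(c)
    if len(sorted_ids) != len(animals):
        cyclic = sorted(set(animals) - seen)
        raise ValueError(f"cycle in parentage involving animal {cyclic[0]!r}")

    index = {a: i for i, a in enumerate(sorted_ids)}
    sire = np.full(len(sorted_ids), UNKNOWN, dtype=np.int64)
    dam = np.full(len(sorted_ids), UNKNOWN, dtype=np.int64)
    for a, (s, d) in animals.items():
        i = index[a]
        if s is not None:
            sire[i] = index[s]
        if d is not None:
            dam[i] = index[d]
    ped = Pedigree(sorted_ids, sire, dam, index)
    ped.validate()
    return ped


def read_genotypes(geno_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read an id + 0/1/2/NA row-matrix and its SNP map.

    The map file has columns snp_id, chromosome, position_bp; output
    columns are sorted by (chromosome, position).
    """
    mp = pd.read_csv(map_path, sep=r"[,\s]+", engine="python", header=None,
                     names=["snp_id", "chrom", "pos_bp"], comment="#")
    ids: list[str] = []
    rows: list[list[int]] = []
    for ln, raw in enumerate(Path(geno_path).read_text().splitlines(), 1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        tok = _tokenize(raw)
        ids.append(tok[0])
        row = []
        for j, t in enumerate(tok[1:]):
            if t.upper() in ("NA", "."):
                row.append(GenotypeMatrix.MISSING)
            elif t in ("0", "1", "2"):
                row.append(int(t))
            else:
                raise ValueError(
                    f"invalid genotype call {t!r} at row {ln} (individual "
                    f"{tok[0]!r}), SNP column {j + 1}"
                )
        rows.append(row)
    if not rows:
        raise ValueError(f"no genotype rows in {geno_path}")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"ragged genotype rows: widths {sorted(widths)}")
    calls = np.asarray(rows, dtype=np.int16)
    if calls.shape[1] != len(mp):
        raise ValueError(
            f"genotype columns ({calls.shape[1]}) do not match map length "
            f"({len(mp)})"
        )
    order = np.lexsort((mp["pos_bp"].to_numpy(), mp["chrom"].to_numpy()))
    mp = mp.iloc[order].reset_index(drop=True)
    return GenotypeMatrix(
        individual_ids=ids,
        snp_ids=mp["snp_id"].astype(str).tolist(),
        calls=calls[:, order],
        chrom=mp["chrom"].to_numpy(dtype=np.int64),
        pos_bp=mp["pos_bp"].to_numpy(dtype=np.int64),
    )


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read the delimited phenotype file (header required)."""
    df = pd.read_csv(path, sep=r"[,\t]+" if str(path).endswith(".csv") else r"[,\s]+",
                     engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    return PhenotypeTable(df)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def hwe_chisq_p(n_aa: np.ndarray, n_ab: np.ndarray, n_bb: np.ndarray) -> np.ndarray:
    """1-df chi-square goodness-of-fit p for genotype counts vs p2/2pq/q2."""
    n_aa = np.asarray(n_aa, dtype=float)
    n_ab = np.asarray(n_ab, dtype=float)
    n_bb = np.asarray(n_bb, dtype=float)
    n = n_aa + n_ab + n_bb
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * n_bb + n_ab) / (2 * n)
        q = 1.0 - p
        exp = np.stack([n * q**2, n * 2 * p * q, n * p**2])
        obsv = np.stack([n_aa, n_ab, n_bb])
        chi2 = np.where(exp > 0, (obsv - exp) ** 2 / exp, 0.0).sum(axis=0)
    pval = stats.chi2.sf(chi2, df=1)
    # monomorphic SNPs fit HWE trivially
    pval = np.where((p <= 0) | (p >= 1), 1.0, pval)
    return pval


def qc_filter_snps(
    g: GenotypeMatrix,
    call_rate_min: float = 0.90,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-6,
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop SNPs failing call-rate, MAF, or Hardy-Weinberg filters.

    All three filters are evaluated jointly on the input matrix (observed
    calls only), so the report attributes each SNP to every filter it
    fails.  Raises if no SNP survives.
    """
    if g.n_snps == 0 or g.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    obs = g.calls != g.MISSING
    call_rate = obs.mean(axis=0)
    p = g.allele_frequencies()
    maf = np.minimum(p, 1.0 - p)
    n_aa = ((g.calls == 0) & obs).sum(axis=0)
    n_ab = (g.calls == 1).sum(axis=0)
    n_bb = (g.calls == 2).sum(axis=0)
    hwe_p = hwe_chisq_p(n_aa, n_ab, n_bb)

    bad_cr = call_rate < call_rate_min
    bad_maf = ~(maf >= maf_min)      # NaN freq (all missing) also fails
    bad_hwe = hwe_p < hwe_p_min
    snp_arr = np.asarray(g.snp_ids)
    report = QcReport(
        n_input_snps=g.n_snps,
        fail_callrate=snp_arr[bad_cr].tolist(),
        fail_maf=snp_arr[bad_maf].tolist(),
        fail_hwe=snp_arr[bad_hwe].tolist(),
    )
    keep = ~(bad_cr | bad_maf | bad_hwe)
    if not keep.any():
        raise ValueError("all SNPs removed by QC; genomic matrix undefined")
    filtered = GenotypeMatrix(
        individual_ids=list(g.individual_ids),
        snp_ids=snp_arr[keep].tolist(),
        calls=g.calls[:, keep].copy(),
        chrom=g.chrom[keep].copy(),
        pos_bp=g.pos_bp[keep].copy(),
    )
    return filtered, report


def filter_phenotypes(t: PhenotypeTable, trait: str) -> PhenotypeTable:
    """Keep only records of ``trait`` whose values are in the legal range.

    Raises for unknown traits and when no record survives.
    """
    if trait not in TRAIT_RANGES:
        raise ValueError(
            f"unknown trait {trait!r}; valid traits: {sorted(TRAIT_RANGES)}"
        )
    lo, hi = TRAIT_RANGES[trait]
    df = t.for_trait(trait)
    if df.empty:
        raise ValueError(f"no records for trait {trait!r}")
    kept = df[(df["value"] >= lo) & (df["value"] <= hi)].reset_index(drop=True)
    if kept.empty:
        raise ValueError(f"no {trait} records survive the range filter [{lo}, {hi}]")
    log.info("%s: kept %d of %d records", trait, len(kept), len(df))
    return PhenotypeTable(kept)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, a in enumerate(ped.animal_ids):
            s = ped.animal_ids[ped.sire[i]] if ped.sire[i] != UNKNOWN else "0"
            d = ped.animal_ids[ped.dam[i]] if ped.dam[i] != UNKNOWN else "0"
            fh.write(f"{a} {s} {d}\n")


def write_genotypes(g: GenotypeMatrix, geno_path: str | Path,
                    map_path: str | Path) -> None:
    with open(geno_path, "w") as fh:
        for i, a in enumerate(g.individual_ids):
            calls = " ".join(
                "NA" if c == g.MISSING else str(c) for c in g.calls[i]
            )
            fh.write(f"{a} {calls}\n")
    with open(map_path, "w") as fh:
        for s, c, p in zip(g.snp_ids, g.chrom, g.pos_bp):
            fh.write(f"{s} {c} {p}\n")


def write_phenotypes(t: PhenotypeTable, path: str | Path) -> None:
    t.records.to_csv(path, sep="\t", index=False)


def write_window_results(windows: list, path: str | Path) -> None:
    """Write ranked window results as TSV (one row per window)."""
    with open(path, "w") as fh:
        fh.write("chromosome\tstart_Mb\tend_Mb\tstart_snp\tend_snp\tpct_variance\n")
        for w in sorted(windows, key=lambda w: w.rank):
            fh.write(
                f"{w.chromosome}\t{w.start_bp / 1e6:.6f}\t{w.end_bp / 1e6:.6f}\t"
                f"{w.start_snp}\t{w.end_snp}\t{w.pct_variance:.6f}\n"
            )
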