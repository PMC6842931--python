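"""Sliding-window partitioning of explained genetic variance.

For each window of consecutive SNPs on a chromosome the genetic value
g = sum_j z_j u_j is computed over genotyped individuals; the window's
share of additive variance is Var(g)/sigma2_a x 100 %.  Windows are
ranked, greedily pruned so the top list holds distinct regions, classed
into the four conventional bands (>1 %, 0.5-1 %, 0.1-0.5 %, <0.1 %), and
cross-trait overlaps detected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: class bands, closed on the lower edge (a window at exactly 0.5 % falls
#: in the 0.1-0.5 % class)
CLASS_BANDS = (">1%", "0.5-1%", "0.1-0.5%", "<0.1%")


@dataclass
class WindowResult:
    chromosome: int
    start_snp: int          # global column indices, inclusive
    end_snp: int
    start_bp: int
    end_bp: int
    pct_variance: float
    rank: int = 0

    @property
    def size(self) -> int:
        return self.end_snp - self.start_snp + 1

    def overlaps(self, other: "WindowResult") -> bool:
        """bp-interval intersection on the same chromosome (inclusive)."""
        return (self.chromosome == other.chromosome
                and self.start_bp <= other.end_bp
                and other.start_bp <= self.end_bp)


@dataclass
class VarianceClassSummary:
    counts: dict[str, int]
    proportions: dict[str, float]
    variance_share: dict[str, float]    # share of summed pct per class
    n_windows: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "class": list(CLASS_BANDS),
            "count": [self.counts[c] for c in CLASS_BANDS],
            "proportion": [self.proportions[c] for c in CLASS_BANDS],
            "variance_share": [self.variance_share[c] for c in CLASS_BANDS],
        })


def window_variance(
    Z: np.ndarray,
    u_hat: np.ndarray,
    chrom: np.ndarray,
    pos_bp: np.ndarray,
    sigma2_a: float,
    window_size: int = 10,
    step: int = 1,
) -> list[WindowResult]:
    """Percentage of sigma2_a explained by each sliding SNP window.

    ``Z`` is the centered marker matrix over genotyped individuals with
    columns sorted by (chromosome, position).  Windows never span
    chromosomes; a chromosome shorter than ``window_size`` yields a single
    truncated window with a warning.  Ranks (1 = largest) are assigned
    over all windows, ties broken by (chromosome, start_bp).
    """
    if sigma2_a <= 0:
        raise ValueError("sigma2_a must be > 0")
    if window_size < 1 or step < 1:
        raise ValueError("window_size and step must be >= 1")
    u_hat = np.asarray(u_hat, dtype=float)
    per_snp = Z * u_hat                       # n_ind x m contributions
    results: list[WindowResult] = []
    for c in np.unique(chrom):
        cols = np.nonzero(chrom == c)[0]
        if len(cols) < window_size:
            log.warning("chromosome %s has %d SNPs < window size %d; "
                        "single truncated window", c, len(cols), window_size)
            starts = [0]
            size = len(cols)
        else:
            starts = list(range(0, len(cols) - window_size + 1, step))
            size = window_size
        block = per_snp[:, cols]
        csum = np.cumsum(block, axis=1)
        for s in starts:
            e = s + size - 1
            gval = csum[:, e] - (csum[:, s - 1] if s > 0 else 0.0)
            pct = float(np.var(gval, ddof=1) / sigma2_a * 100.0)
            results.append(WindowResult(
                chromosome=int(c),
                start_snp=int(cols[s]),
                end_snp=int(cols[e]),
                start_bp=int(pos_bp[cols[s]]),
                end_bp=int(pos_bp[cols[e]]),
                pct_variance=pct,
            ))
    order = sorted(
        range(len(results)),
        key=lambda i: (-results[i].pct_variance,
                       results[i].chromosome, results[i].start_bp),
    )
    for rank, i in enumerate(order, 1):
        results[i].rank = rank
    return results


def top_windows(windows: list[WindowResult], n: int = 10) -> list[WindowResult]:
    """Top-``n`` distinct regions by explained variance.

    Sliding windows produce near-copies of each peak, so candidates are
    greedily pruned: a window is dropped if it shares at least one SNP
    with an already selected higher-ranked window.  Ties break by
    (chromosome, start_bp); returned ranks are 1..n.
    """
    if not windows:
        raise ValueError("empty window list")
    ordered = sorted(windows, key=lambda w: (-w.pct_variance, w.chromosome, w.start_bp))
    selected: list[WindowResult] = []
    for w in ordered:
        if any(
            w.chromosome == s.chromosome
            and w.start_snp <= s.end_snp and s.start_snp <= w.end_snp
            for s in selected
        ):
            continue
        selected.append(w)
        if len(selected) == n:
            break
    out = []
    for rank, w in enumerate(selected, 1):
        out.append(WindowResult(
            w.chromosome, w.start_snp, w.end_snp, w.start_bp, w.end_bp,
            w.pct_variance, rank=rank,
        ))
    return out


def classify_windows(windows: list[WindowResult]) -> VarianceClassSummary:
    """Count windows per explained-variance band.

    Reports both the count share and the variance share of each band (the
    two readings of a 'percentage of regions' summary); boundary values
    go to the lower band.
    """
    counts = {c: 0 for c in CLASS_BANDS}
    var_sum = {c: 0.0 for c in CLASS_BANDS}
    for w in windows:
        if w.pct_variance > 1.0:
            band = ">1%"
        elif w.pct_variance > 0.5:
            band = "0.5-1%"
        elif w.pct_variance > 0.1:
            band = "0.1-0.5%"
        else:
            band = "<0.1%"
        counts[band] += 1
        var_sum[band] += w.pct_variance
    n = len(windows)
    total_var = sum(var_sum.values())
    return VarianceClassSummary(
        counts=counts,
        proportions={c: counts[c] / n if n else 0.0 for c in CLASS_BANDS},
        variance_share={
            c: var_sum[c] / total_var if total_var > 0 else 0.0
            for c in CLASS_BANDS
        },
        n_windows=n,
    )


@dataclass
class OverlapRegion:
    chromosome: int
    start_bp: int
    end_bp: int
    traits: list[str] = field(default_factory=list)
    pct_by_trait: dict[str, float] = field(default_factory=dict)


def overlap_across_traits(
    results_per_trait: dict[str, list[WindowResult]],
) -> list[OverlapRegion]:
    """Merge top windows of different traits that intersect in bp.

    Two windows overlap iff they sit on the same chromosome and their
    (inclusive) bp intervals intersect; touching intervals
    (end_bp + 1 == start_bp) do not.  Only merged regions supported by at
    least two distinct traits are returned, ordered by genome position.
    """
    if len(results_per_trait) < 2:
        raise ValueError("need results for at least two traits")
    tagged = [
        (trait, w)
        for trait, wins in results_per_trait.items()
        for w in wins
    ]
    tagged.sort(key=lambda tw: (tw[1].chromosome, tw[1].start_bp, tw[1].end_bp))
    regions: list[OverlapRegion] = []
    cur: OverlapRegion | None = None
    cur_members: list[tuple[str, WindowResult]] = []
    for trait, w in tagged:
        if cur is not None and w.chromosome == cur.chromosome and w.start_bp <= cur.end_bp:
            cur.end_bp = max(cur.end_bp, w.end_bp)
            cur_members.append((trait, w))
        else:
            if cur is not None:
                _finalize(cur, cur_members, regions)
            cur = OverlapRegion(w.chromosome, w.start_bp, w.end_bp)
            cur_members = [(trait, w)]
    if cur is not None:
        _finalize(cur, cur_members, regions)
    return regions


def _finalize(region: OverlapRegion,
              members: list[tuple[str, "WindowResult"]],
              out: list[OverlapRegion]) -> None:
    traits = sorted({t for t, _ in members})
    if len(traits) < 2:
        return
    region.traits = traits
    region.pct_by_trait = {
        t: max(w.pct_variance for tt, w in members if tt == t) for t in traits
    }
    out.append(region)


def manhattan_export(
    windows: list[WindowResult],
    path,
    plot_path=None,
) -> pd.DataFrame:
    """Write per-window rows with a cumulative genome coordinate.

    The cumulative coordinate offsets each chromosome by the running sum
    of preceding chromosomes' maximum positions, so plotting pct against
    it yields a Manhattan-style panorama.  Optionally renders a plot.
    """
    if not windows:
        raise ValueError("no windows to export")
    chrom_max = {}
    for w in windows:
        chrom_max[w.chromosome] = max(chrom_max.get(w.chromosome, 0), w.end_bp)
    offsets = {}
    running = 0
    for c in sorted(chrom_max):
        offsets[c] = running
        running += chrom_max[c]
    rows = sorted(windows, key=lambda w: (w.chromosome, w.start_bp))
    df = pd.DataFrame({
        "chromosome": [w.chromosome for w in rows],
        "start_bp": [w.start_bp for w in rows],
        "end_bp": [w.end_bp for w in rows],
        "cumulative_bp": [offsets[w.chromosome] + w.start_bp for w in rows],
        "pct_variance": [w.pct_variance for w in rows],
    })
    df.to_csv(path, sep="\t", index=False)
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(10, 3.5))
        for i, c in enumerate(sorted(chrom_max)):
            sub = df[df["chromosome"] == c]
            ax.scatter(sub["cumulative_bp"] / 1e6, sub["pct_variance"],
                       s=6, color=f"C{i % 2}")
        ax.set_xlabel("cumulative position (Mb)")
        ax.set_ylabel("% of additive variance")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return df
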