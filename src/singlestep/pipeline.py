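"""End-to-end orchestration: QC -> relationships -> MME -> weighting loop
-> window report, in synthetic or files mode, with config validation,
stage logging, and a provenance manifest."""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .io_formats import (
    TRAIT_RANGES,
    GenotypeMatrix,
    Pedigree,
    PhenotypeTable,
    filter_phenotypes,
    qc_filter_snps,
    read_genotypes,
    read_pedigree,
    read_phenotypes,
    write_genotypes,
    write_pedigree,
    write_phenotypes,
    write_window_results,
)
from .mme_solver import ModelSpec, VarianceComponents
from .synthetic_data import SimConfig, simulate_dataset
from .windows_report import (
    classify_windows,
    manhattan_export,
    top_windows,
    window_variance,
)
from .wssgwas import run_wssgwas, write_effects

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    mode: str = "synthetic"                  # "synthetic" | "files"
    trait: str = "VE"
    sim: SimConfig | None = None
    pedigree_path: str | None = None
    genotype_path: str | None = None
    map_path: str | None = None
    phenotype_path: str | None = None
    varcomp: VarianceComponents = field(
        default_factory=lambda: VarianceComponents(0.2, 0.2, 0.6)
    )
    call_rate_min: float = 0.90
    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    n_iter: int = 2
    blend_alpha: float = 0.05
    window_size: int = 10
    step: int = 1
    top_n: int = 10
    seed: int = 0
    outdir: str = "results"
    make_plot: bool = False


def validate_config(cfg: dict | RunConfig) -> RunConfig:
    """Normalize a raw config (dict or RunConfig), filling defaults and
    collecting every violation into one error."""
    if isinstance(cfg, dict):
        raw = dict(cfg)
        if isinstance(raw.get("varcomp"), dict):
            raw["varcomp"] = VarianceComponents(**raw["varcomp"])
        if isinstance(raw.get("sim"), dict):
            raw["sim"] = SimConfig(**raw["sim"])
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = RunConfig(**raw)

    problems: list[str] = []
    if cfg.mode not in ("synthetic", "files"):
        problems.append(f"mode must be 'synthetic' or 'files', got {cfg.mode!r}")
    if cfg.trait not in TRAIT_RANGES:
        problems.append(
            f"unknown trait {cfg.trait!r}; valid traits: {sorted(TRAIT_RANGES)}"
        )
    if cfg.n_iter < 1:
        problems.append("n_iter must be >= 1")
    if not (0.0 <= cfg.blend_alpha < 1.0):
        problems.append("blend_alpha must be in [0, 1)")
    if cfg.window_size < 1:
        problems.append("window_size must be >= 1")
    if cfg.step < 1:
        problems.append("step must be >= 1")
    if cfg.top_n < 1:
        problems.append("top_n must be >= 1")
    if cfg.mode == "files":
        for name in ("pedigree_path", "genotype_path", "map_path", "phenotype_path"):
            p = getattr(cfg, name)
            if p is None:
                problems.append(f"files mode requires {name}")
            elif not Path(p).exists():
                problems.append(f"{name} does not exist: {p}")
    if cfg.mode == "synthetic" and cfg.sim is None:
        cfg.sim = SimConfig(seed=cfg.seed, trait=cfg.trait)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    return cfg


def _load_inputs(cfg: RunConfig) -> tuple[Pedigree, GenotypeMatrix, PhenotypeTable]:
    if cfg.mode == "synthetic":
        ds = simulate_dataset(cfg.sim)
        return ds.pedigree, ds.genotypes, ds.phenotypes
    ped = read_pedigree(cfg.pedigree_path)
    geno = read_genotypes(cfg.genotype_path, cfg.map_path)
    phen = read_phenotypes(cfg.phenotype_path)
    return ped, geno, phen


def run_pipeline(cfg: dict | RunConfig) -> Path:
    """Run every stage and write all artifacts under ``cfg.outdir``.

    Deterministic under a fixed seed; each stage logs its input/output
    dimensions and the manifest records the full config echo.
    """
    cfg = validate_config(cfg)
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    stage = "load"
    try:
        ped, geno, phen = _load_inputs(cfg)
        log.info("load: %d animals, %d genotyped x %d SNPs, %d records",
                 len(ped), geno.n_individuals, geno.n_snps, len(phen))

        stage = "qc"
        geno_qc, report = qc_filter_snps(
            geno, cfg.call_rate_min, cfg.maf_min, cfg.hwe_p_min
        )
        report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
        log.info("qc: %d -> %d SNPs", report.n_input_snps, report.n_pass)

        stage = "phenotype_filter"
        phen_f = filter_phenotypes(phen, cfg.trait)
        log.info("phenotypes: %d records for %s", len(phen_f), cfg.trait)

        stage = "wssgwas"
        result = run_wssgwas(
            ped, geno_qc, phen_f, cfg.varcomp,
            n_iter=cfg.n_iter, blend_alpha=cfg.blend_alpha,
            model=ModelSpec(), seed=cfg.seed,
        )
        echo = {"trait": cfg.trait, "n_iter": cfg.n_iter,
                "blend_alpha": cfg.blend_alpha, "seed": cfg.seed,
                "version": __version__}
        write_effects(result, geno_qc, out / "snp_effects.tsv", config_echo=echo)
        _write_solutions(result.final_fit, out / "solutions.tsv")

        stage = "windows"
        Z = geno_qc.centered()
        u = result.final_effects.u_hat
        wins = window_variance(
            Z, u, geno_qc.chrom, geno_qc.pos_bp, cfg.varcomp.sigma2_a,
            window_size=cfg.window_size, step=cfg.step,
        )
        write_window_results(wins, out / "windows.tsv")
        top = top_windows(wins, cfg.top_n)
        write_window_results(top, out / "top_windows.tsv")
        classify_windows(wins).to_frame().to_csv(
            out / "class_summary.tsv", sep="\t", index=False
        )
        manhattan_export(
            wins, out / "manhattan.tsv",
            plot_path=(out / "manhattan.png") if cfg.make_plot else None,
        )
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    manifest = {
        "version": __version__,
        "elapsed_s": round(time.time() - t0, 3),
        "config": _config_echo(cfg),
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
        "dimensions": {
            "n_animals": len(ped),
            "n_genotyped": geno_qc.n_individuals,
            "n_snps_input": report.n_input_snps,
            "n_snps_pass": report.n_pass,
            "n_records": len(phen_f),
            "n_windows": len(wins),
        },
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return out


def write_synthetic_files(cfg: SimConfig, outdir: str | Path) -> Path:
    """Materialize one simulated dataset in the on-disk formats the
    files-mode pipeline reads (plus the truth sidecar)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(cfg)
    write_pedigree(ds.pedigree, out / "pedigree.txt")
    write_genotypes(ds.genotypes, out / "genotypes.txt", out / "snp_map.txt")
    write_phenotypes(ds.phenotypes, out / "phenotypes.tsv")
    ds.truth.write(out / "truth.tsv")
    return out


def _write_solutions(fit, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("effect\tlevel\tsolution\n")
        for name, val in fit.beta.items():
            fh.write(f"fixed\t{name}\t{val:.10g}\n")
        for animal, val in fit.gebv.items():
            fh.write(f"animal\t{animal}\t{val:.10g}\n")
        for animal, val in fit.pe.items():
            fh.write(f"pe\t{animal}\t{val:.10g}\n")


def _config_echo(cfg: RunConfig) -> dict:
    echo = dataclasses.asdict(cfg)
    return echo
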