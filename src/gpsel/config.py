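"""Study-level configuration and orchestration.

A single YAML file describes the whole study: where the genotype panels
and phenotypes come from (files, or a synthetic-data block), which
(model, dataset) cells of the design grid to run, GWAS/pruning settings,
MCMC chain lengths and the cross-validation layout. ``run_study``
executes simulate -> QC -> per-fold GWAS -> fits -> evaluation and
writes a deterministic report: the same config and seed produce
byte-identical JSON.

Dataset tags follow the design grid: 1 = chip data, 2 = chip data plus
significant whole-genome-sequence SNPs, 3 = imputed whole-genome-sequence
data.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from . import io as gio
from .blup import TABLE1
from .core import qc_filter
from .evaluation import CVReport, FoldPlan, StudyData, compare_models, make_folds, plot_report, run_cv
from .simdata import (
    SimConfig,
    TraitArchitecture,
    inject_imputation_error,
    make_chip_subset,
    simulate_genotypes,
    simulate_traits,
)


class ConfigError(ValueError):
    pass


class SimBlock(BaseModel):
    n_individuals: int = 600
    n_chromosomes: int = 5
    snps_per_chromosome: int = 2000
    chip_fraction: float = 0.05
    ld_decay: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    error_rate: float = 0.03
    h2: tuple[float, float] = (0.323, 0.195)
    rg: float = 0.636
    n_large_qtl: tuple[int, int] = (5, 0)
    large_qtl_variance_share: tuple[float, float] = (0.5, 0.0)
    n_polygenes: int = 1000
    seed: int = 0


class PathsBlock(BaseModel):
    chip: str
    wgs: str
    format: str = "vcf"
    phenotypes: str


class ModelCell(BaseModel):
    name: str
    dataset: int

    @model_validator(mode="after")
    def _legal(self):
        if self.name not in TABLE1:
            raise ValueError(f"unknown model {self.name!r}")
        if self.dataset not in TABLE1[self.name]:
            raise ValueError(
                f"({self.name}, dataset {self.dataset}) is not a legal design-grid cell"
            )
        return self


class GwasBlock(BaseModel):
    k_pcs: int = 2
    loco: bool = True
    window_snps: int = 50
    step_snps: int = 10
    r2_threshold: float = 0.5


class ChainBlock(BaseModel):
    n_iter: int = 50_000
    burn_in: int = 25_000
    thin: int = 1

    @model_validator(mode="after")
    def _order(self):
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be below n_iter")
        return self


class CVBlock(BaseModel):
    k: int = 10
    seed: int = 42


class QCBlock(BaseModel):
    maf_min: float = 0.05
    dr2_min: float = 0.9


class StudyConfig(BaseModel):
    simdata: SimBlock | None = None
    paths: PathsBlock | None = None
    models: list[ModelCell] = Field(default_factory=list)
    gwas: GwasBlock = Field(default_factory=GwasBlock)
    chain: ChainBlock = Field(default_factory=ChainBlock)
    cv: CVBlock = Field(default_factory=CVBlock)
    qc: QCBlock = Field(default_factory=QCBlock)
    target_trait: int | None = None

    @model_validator(mode="after")
    def _source(self):
        if (self.simdata is None) == (self.paths is None):
            raise ValueError("exactly one of 'simdata' or 'paths' must be given")
        if not self.models:
            raise ValueError("at least one (model, dataset) cell is required")
        return self

    @field_validator("target_trait")
    @classmethod
    def _trait_range(cls, v):
        if v is not None and v not in (0, 1):
            raise ValueError("target_trait must be 0 or 1")
        return v

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def validate_config(path) -> StudyConfig:
    """Load, default and validate a study YAML; checks referenced files exist."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
    try:
        cfg = StudyConfig.model_validate(raw or {})
    except Exception as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    if cfg.paths is not None:
        for label in ("chip", "wgs", "phenotypes"):
            p = Path(getattr(cfg.paths, label))
            probe = p.with_suffix(".bim") if cfg.paths.format == "plink" else p
            if not probe.exists():
                raise ConfigError(f"{path}: {label} file not found: {p}")
    return cfg


def materialize_data(cfg: StudyConfig, seed_offset: int = 0) -> tuple[StudyData, object]:
    """Simulate or load the study's panels and phenotypes, then QC them."""
    truth = None
    if cfg.simdata is not None:
        sb = cfg.simdata
        sim = SimConfig(
            n_individuals=sb.n_individuals, n_chromosomes=sb.n_chromosomes,
            snps_per_chromosome=sb.snps_per_chromosome, chip_fraction=sb.chip_fraction,
            ld_decay=sb.ld_decay, maf_range=tuple(sb.maf_range),
            seed=sb.seed + seed_offset,
        )
        wgs = simulate_genotypes(sim)
        arch = TraitArchitecture(
            h2=tuple(sb.h2), rg=sb.rg, n_large_qtl=tuple(sb.n_large_qtl),
            large_qtl_variance_share=tuple(sb.large_qtl_variance_share),
            n_polygenes=sb.n_polygenes,
        )
        pheno, truth = simulate_traits(wgs, arch, seed=sim.seed + 1)
        chip = make_chip_subset(wgs, sb.chip_fraction)
        wgs = inject_imputation_error(
            wgs, sb.error_rate, seed=sim.seed + 2, chip_ids=list(chip.snp_map["id"])
        )
    else:
        chip = gio.read_panel(cfg.paths.chip, cfg.paths.format)
        chip.tag = "chip"
        chip.snp_map["dr2"] = chip.snp_map["dr2"].fillna(1.0)
        wgs = gio.read_panel(cfg.paths.wgs, cfg.paths.format)
        pheno = gio.read_phenotypes(cfg.paths.phenotypes)
    chip = qc_filter(chip, cfg.qc.maf_min, cfg.qc.dr2_min)
    wgs = qc_filter(wgs, cfg.qc.maf_min, cfg.qc.dr2_min)
    return StudyData(chip=chip, wgs=wgs, pheno=pheno), truth


def run_study(cfg: StudyConfig, outdir, seed: int | None = None) -> CVReport:
    """Execute the configured study end to end and write its artifacts.

    Writes ``report.json`` (canonical, byte-identical across same-seed
    reruns), ``cells.tsv``, ``accuracy.png`` and a non-canonical
    ``run_log.txt`` with wall-clock timings.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg.cv.seed if seed is None else seed
    t0 = time.time()
    data, truth = materialize_data(cfg)
    folds = make_folds(data.pheno["id"].to_numpy(), k=cfg.cv.k, seed=seed)
    report = run_cv(
        [(m.name, m.dataset) for m in cfg.models],
        data, folds,
        target_trait=cfg.target_trait,
        k_pcs=cfg.gwas.k_pcs, loco=cfg.gwas.loco,
        bayes_chain={"n_iter": cfg.chain.n_iter, "burn_in": cfg.chain.burn_in,
                     "thin": cfg.chain.thin},
        prune_params={"window_snps": cfg.gwas.window_snps, "step_snps": cfg.gwas.step_snps,
                      "r2_threshold": cfg.gwas.r2_threshold},
        seed=seed,
    )
    compare_models(report)
    report.provenance["config_hash"] = cfg.config_hash()
    (outdir / "report.json").write_text(report.to_json())
    report.cells.to_csv(outdir / "cells.tsv", sep="\t", index=False)
    plot_report(report, outdir / "accuracy.png")
    (outdir / "run_log.txt").write_text(
        f"study {cfg.config_hash()} seed={seed} wall={time.time() - t0:.1f}s\n"
    )
    return report
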