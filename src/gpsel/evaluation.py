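"""Cross-validation harness, prediction metrics and model comparison.

Individuals are split into k (default 10) near-equal folds, identical
across models for a given seed. In each fold the validation individuals'
phenotypes are masked; GWAS pre-selection, variance-component estimation
and BLUP/Bayesian fitting see training records only, and the validation
individuals' breeding values come through their marker relationships.

Accuracy is the Pearson correlation between predicted breeding values
and the fixed-effect-corrected phenotype of the validation individuals;
bias is the regression slope of corrected phenotype on breeding value
(1 = unbiased dispersion, >1 under-dispersed, <1 over-dispersed).
Corrected phenotypes are computed once over all individuals by ordinary
least squares. Models are compared by one-way ANOVA over fold accuracies
followed by Tukey's HSD; each model's fold biases are tested against 1
with a one-sample t-test.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import gwas as gwas_mod
from .blup import BAYES_FAMILIES, ModelPlan, build_model
from .core import compute_grm, ld_prune
from .panel import GenotypePanel

logger = logging.getLogger(__name__)


class MetricError(ValueError):
    pass


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    k: int
    assignments: np.ndarray      # fold index per individual, 0..k-1
    seed: int

    def validation_rows(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def training_rows(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


def make_folds(ids, k: int = 10, seed: int = 0) -> FoldPlan:
    """Random balanced partition into k folds (sizes differ by at most 1)."""
    n = len(ids)
    if k > n:
        raise ValueError(f"cannot split {n} individuals into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignments = np.empty(n, dtype=int)
    assignments[order] = np.arange(n) % k
    return FoldPlan(k=k, assignments=assignments, seed=seed)


# ---------------------------------------------------------------------------
# fixed-effect designs and corrected phenotypes
# ---------------------------------------------------------------------------

def trait_design(pheno: pd.DataFrame, trait: int):
    """Fixed-effect covariate block (no intercept) for one trait.

    Trait 0 (rib-number-like): sex + slaughter-batch factors.
    Trait 1 (carcass-length-like): carcass-weight record-type factor plus
    the centered carcass-weight covariate.
    """
    if trait == 0:
        sex = pheno["sex"].to_numpy(float)
        batches = pd.get_dummies(pheno["batch"], drop_first=True).to_numpy(float)
        names = ["sex"] + [f"batch_{b}" for b in sorted(pheno["batch"].unique())[1:]]
        return np.column_stack([sex, batches]), names
    cwt = pd.get_dummies(pheno["cw_type"], drop_first=True).to_numpy(float)
    cw = pheno["cw"].to_numpy(float)
    cw = cw - cw.mean()
    names = [f"cw_type_{t}" for t in sorted(pheno["cw_type"].unique())[1:]] + ["cw"]
    return np.column_stack([cwt, cw]), names


def ols_residuals(y: np.ndarray, X: np.ndarray, names=None) -> np.ndarray:
    """Least-squares residuals; raises naming aliased columns on rank deficiency."""
    X1 = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    rank = np.linalg.matrix_rank(X1)
    if rank < X1.shape[1]:
        # identify aliased columns by incremental rank
        aliased, cols = [], [X1[:, 0:1]]
        for j in range(1, X1.shape[1]):
            trial = np.column_stack(cols + [X1[:, j]])
            if np.linalg.matrix_rank(trial) == trial.shape[1]:
                cols.append(X1[:, j : j + 1])
            else:
                aliased.append(names[j - 1] if names else f"col{j - 1}")
        raise MetricError(f"rank-deficient fixed-effect design; aliased: {aliased}")
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    return y - X1 @ beta


def corrected_phenotype(pheno: pd.DataFrame, trait: int, split_groups: bool | None = None) -> np.ndarray:
    """Residual phenotype after global OLS correction for fixed effects.

    Trait 1 defaults to the split-group adjustment: carcass-weight
    batches 1-4 and batch 5 are corrected separately for sex, batch and
    carcass weight, mirroring the two record types.
    """
    y = pheno[f"trait{trait + 1}"].to_numpy(float)
    if trait == 0:
        X, names = trait_design(pheno, 0)
        return ols_residuals(y, X, names)
    if split_groups is None:
        split_groups = True
    out = np.empty(len(y))
    groups = [pheno["cw_type"].to_numpy() == v for v in sorted(pheno["cw_type"].unique())] if split_groups else [np.ones(len(y), bool)]
    for gmask in groups:
        sub = pheno.loc[gmask]
        cols, names = [], []
        sex = sub["sex"].to_numpy(float)
        if len(np.unique(sex)) > 1:
            cols.append(sex)
            names.append("sex")
        bt = pd.get_dummies(sub["batch"], drop_first=True)
        if bt.shape[1]:
            cols.append(bt.to_numpy(float))
            names.extend(f"batch_{b}" for b in bt.columns)
        cw = sub["cw"].to_numpy(float)
        cols.append(cw - cw.mean())
        names.append("cw")
        X = np.column_stack(cols)
        out[gmask] = ols_residuals(y[gmask], X, names)
    return out


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def accuracy(gebv, corrected) -> float:
    """Pearson correlation between predicted breeding value and corrected phenotype."""
    gebv = np.asarray(gebv, float)
    corrected = np.asarray(corrected, float)
    if len(gebv) < 3:
        raise MetricError("accuracy needs at least 3 validation individuals")
    if np.std(gebv) == 0:
        raise MetricError("accuracy undefined for constant breeding values")
    return float(np.corrcoef(gebv, corrected)[0, 1])


def bias(gebv, corrected) -> float:
    """Slope of corrected phenotype regressed on breeding value."""
    gebv = np.asarray(gebv, float)
    corrected = np.asarray(corrected, float)
    var = np.var(gebv, ddof=1)
    if var == 0:
        raise MetricError("bias undefined for constant breeding values")
    return float(np.cov(corrected, gebv, ddof=1)[0, 1] / var)


# ---------------------------------------------------------------------------
# cross-validation harness
# ---------------------------------------------------------------------------

@dataclass
class StudyData:
    """The panels and phenotypes one study runs on (identical individuals)."""

    chip: GenotypePanel
    wgs: GenotypePanel
    pheno: pd.DataFrame

    def __post_init__(self):
        if self.chip.n_individuals != self.wgs.n_individuals:
            raise ValueError("chip and sequence panels cover different individuals")
        if len(self.pheno) != self.chip.n_individuals:
            raise ValueError("phenotype table does not match panels")


@dataclass
class CVReport:
    cells: pd.DataFrame                     # model, dataset, trait, fold, accuracy, bias, failed
    aggregates: pd.DataFrame = field(default=None)
    tukey: dict = field(default_factory=dict)
    bias_tests: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def aggregate(self) -> pd.DataFrame:
        ok = self.cells[~self.cells["failed"]]
        agg = ok.groupby(["model", "dataset", "trait"]).agg(
            accuracy_mean=("accuracy", "mean"),
            accuracy_se=("accuracy", lambda s: s.std(ddof=1) / np.sqrt(len(s))),
            bias_mean=("bias", "mean"),
            bias_se=("bias", lambda s: s.std(ddof=1) / np.sqrt(len(s))),
            n_folds=("fold", "count"),
        ).reset_index()
        self.aggregates = agg
        return agg

    def to_json(self) -> str:
        obj = {
            "cells": self.cells.drop(columns=[c for c in self.cells.columns if c == "message"])
                              .to_dict(orient="records"),
            "aggregates": (self.aggregates if self.aggregates is not None else self.aggregate())
                              .to_dict(orient="records"),
            "tukey": self.tukey,
            "bias_tests": self.bias_tests,
            "provenance": self.provenance,
        }
        return json.dumps(obj, sort_keys=True, indent=1, default=float)


def _scan_covariates(design, pcs, n, train_rows):
    cov = np.zeros((n, design.shape[1] + pcs.shape[1]))
    cov[:, : design.shape[1]] = design
    cov[train_rows, design.shape[1] :] = pcs
    return cov


class _SelectionCache:
    """Per-fold, per-panel GWAS pre-selection shared across models."""

    def __init__(self, data: StudyData, folds: FoldPlan, designs, thresholds,
                 n_effective, k_pcs=2, loco=True, seed=0):
        self.data = data
        self.folds = folds
        self.designs = designs
        self.thresholds = thresholds
        self.n_effective = n_effective
        self.k_pcs = k_pcs
        self.loco = loco
        self._cache: dict = {}
        self._grms = {}

    def _panel(self, kind):
        return self.data.chip if kind == "chip" else self.data.wgs

    def _pcs(self, kind, fold):
        key = (kind, fold)
        if key not in self._grms:
            panel = self._panel(kind)
            train = self.folds.training_rows(fold)
            grm = compute_grm(panel.subset_individuals(train))
            self._grms[key] = gwas_mod.compute_pcs(grm, self.k_pcs) if self.k_pcs else np.zeros((len(train), 0))
        return self._grms[key]

    def get(self, kind: str, trait: int, fold: int) -> gwas_mod.SNPSelection:
        key = (kind, trait, fold)
        if key in self._cache:
            return self._cache[key]
        panel = self._panel(kind)
        train = self.folds.training_rows(fold)
        y = self.data.pheno[f"trait{trait + 1}"].to_numpy(float).copy()
        mask = np.ones(len(y), bool)
        mask[train] = False
        y[mask] = np.nan  # validation individuals never enter the scan
        design, _ = self.designs[trait]
        pcs = self._pcs(kind, fold)
        cov = _scan_covariates(design, pcs, len(y), train)
        result = gwas_mod.fit_mlm_scan(
            panel, y, cov, loco=self.loco,
            threshold=self.thresholds[kind], n_effective=self.n_effective[kind],
        )
        sel = gwas_mod.select_snps(result, trait=f"trait{trait + 1}", fold=fold)
        self._cache[key] = sel
        return sel


def _selection_needs(model_name: str, dataset: int, traits):
    if model_name in BAYES_FAMILIES:
        return [("wgs", t) for t in traits] if dataset == 2 else []
    base = model_name.split("-", 1)[1]
    if base == "GBLUP":
        return []
    if base == "MABLUP":
        kind = "chip" if dataset == 1 else "wgs"
        return [(kind, t) for t in traits]
    return [("wgs", t) for t in traits]  # OneBLUP / MultiBLUP


def run_cv(
    model_grid,
    data: StudyData,
    folds: FoldPlan,
    target_trait: int | None = None,
    k_pcs: int = 2,
    loco: bool = True,
    bayes_chain: dict | None = None,
    prune_params: dict | None = None,
    seed: int = 0,
) -> CVReport:
    """Run the full per-fold pipeline for a grid of (model, dataset) cells.

    Single-trait models run once per trait unless ``target_trait`` pins
    one; multi-trait models produce metrics for both traits from one fit.
    GWAS pre-selection is computed on training individuals only and
    cached across models within a fold. Failed cells are recorded and the
    run continues.
    """
    pheno = data.pheno
    n = len(pheno)
    designs = {t: trait_design(pheno, t) for t in (0, 1)}
    corrected = {t: corrected_phenotype(pheno, t) for t in (0, 1)}
    Y = {t: pheno[f"trait{t + 1}"].to_numpy(float) for t in (0, 1)}

    pruned = ld_prune(data.wgs, **(prune_params or {}))
    thresholds = {
        "chip": gwas_mod.significance_threshold(data.chip.n_snps, "chip"),
        "wgs": gwas_mod.significance_threshold(data.wgs.n_snps, "wgs", pruned_count=len(pruned)),
    }
    n_effective = {"chip": data.chip.n_snps, "wgs": len(pruned)}
    cache = _SelectionCache(data, folds, designs, thresholds, n_effective,
                            k_pcs=k_pcs, loco=loco, seed=seed)
    bayes_chain = bayes_chain or {}

    records = []
    for model_name, dataset in model_grid:
        mt = model_name.startswith("MT-")
        run_traits = [None] if mt else ([target_trait] if target_trait is not None else [0, 1])
        for tt in run_traits:
            traits = [0, 1] if mt else [tt]
            for fold in range(folds.k):
                try:
                    sels = {
                        (kind, t): cache.get(kind, t, fold)
                        for kind, t in _selection_needs(model_name, dataset, traits)
                    }
                    kwargs = {}
                    if model_name in BAYES_FAMILIES:
                        kwargs = dict(bayes_chain)
                        kwargs["seed"] = (seed * 1009 + fold * 31 + (tt or 0)) % (2**31 - 1)
                    plan = build_model(model_name, dataset, {"chip": data.chip, "wgs": data.wgs},
                                       selections=sels, target_trait=traits[0], **kwargs)
                    val = folds.validation_rows(fold)
                    if mt:
                        Ym = np.column_stack([Y[0], Y[1]]).astype(float)
                        Ym[val, :] = np.nan
                        cov = [designs[0][0], designs[1][0]]
                    else:
                        Ym = Y[traits[0]].copy()
                        Ym[val] = np.nan
                        cov = designs[traits[0]][0]
                    est = plan.estimator
                    est.fit(plan.panel.dosages, Ym, covariates=cov)
                    gebv = np.asarray(est.gebv_)
                    for ti, t in enumerate(traits):
                        g_val = gebv[val, ti] if gebv.ndim == 2 else gebv[val]
                        c_val = corrected[t][val]
                        records.append({
                            "model": model_name, "dataset": dataset, "trait": t,
                            "fold": fold, "accuracy": accuracy(g_val, c_val),
                            "bias": bias(g_val, c_val), "failed": False, "message": "",
                        })
                except Exception as exc:  # noqa: BLE001 - cell failures are data
                    logger.warning("cell (%s, d%s, trait %s, fold %d) failed: %s",
                                   model_name, dataset, tt, fold, exc)
                    for t in traits:
                        records.append({
                            "model": model_name, "dataset": dataset, "trait": t,
                            "fold": fold, "accuracy": np.nan, "bias": np.nan,
                            "failed": True, "message": str(exc),
                        })
    report = CVReport(cells=pd.DataFrame(records), provenance={
        "seed": seed, "k": folds.k, "n_individuals": n,
        "n_chip_snps": int(data.chip.n_snps), "n_wgs_snps": int(data.wgs.n_snps),
        "pruned_count": len(pruned), "loco": loco, "k_pcs": k_pcs,
        "bayes_chain": {k: v for k, v in bayes_chain.items()},
    })
    report.aggregate()
    return report


def compare_models(report: CVReport) -> CVReport:
    """ANOVA + Tukey HSD on fold accuracies; one-sample t-tests of bias vs 1.

    Comparisons run within each trait across (model, dataset) groups with
    complete, equal fold counts; folds are treated as independent
    replicates.
    """
    ok = report.cells[~report.cells["failed"]]
    n_excluded = int(report.cells["failed"].sum())
    if n_excluded:
        logger.warning("compare_models: %d failed cells excluded", n_excluded)
    for trait, sub in ok.groupby("trait"):
        groups = {
            f"{m}:d{d}": g.sort_values("fold")["accuracy"].to_numpy()
            for (m, d), g in sub.groupby(["model", "dataset"])
        }
        names = sorted(groups)
        if len(names) < 2:
            report.tukey[f"trait{trait + 1}"] = {"note": "single model, comparison skipped"}
            continue
        samples = [groups[k] for k in names]
        anova = stats.f_oneway(*samples)
        hsd = stats.tukey_hsd(*samples)
        pair_p = {}
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                pair_p[f"{names[i]} vs {names[j]}"] = float(hsd.pvalue[i, j])
        report.tukey[f"trait{trait + 1}"] = {
            "anova_F": float(anova.statistic), "anova_p": float(anova.pvalue),
            "pairs": pair_p,
        }
    for (m, d, trait), g in ok.groupby(["model", "dataset", "trait"]):
        b = g["bias"].to_numpy()
        if np.allclose(b.var(), 0.0):
            t_stat, p = (0.0, 1.0) if np.allclose(b, 1.0) else (np.inf, 0.0)
        else:
            t_stat, p = stats.ttest_1samp(b, 1.0)
        report.bias_tests[f"{m}:d{d}:trait{trait + 1}"] = {
            "t": float(t_stat), "p": float(p), "mean_bias": float(b.mean()),
        }
    return report


def plot_report(report: CVReport, path) -> None:
    """Accuracy +- SE bar chart per model/dataset cell, one panel per trait."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    agg = report.aggregates if report.aggregates is not None else report.aggregate()
    traits = sorted(agg["trait"].unique())
    fig, axes = plt.subplots(1, len(traits), figsize=(5 * len(traits), 4), squeeze=False)
    for ax, t in zip(axes[0], traits):
        sub = agg[agg["trait"] == t]
        labels = [f"{m}\nd{d}" for m, d in zip(sub["model"], sub["dataset"])]
        ax.bar(range(len(sub)), sub["accuracy_mean"], yerr=sub["accuracy_se"], capsize=3)
        ax.set_xticks(range(len(sub)))
        ax.set_xticklabels(labels, fontsize=7, rotation=45, ha="right")
        ax.set_ylabel("prediction accuracy")
        ax.set_title(f"trait {t + 1}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
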