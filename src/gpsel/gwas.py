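"""Mixed-linear-model association scan with leave-one-chromosome-out kinship.

Each SNP is tested in the model y = Xa + z*b + k + e where k is a random
polygenic effect with covariance K*sA2 and K is a VanRaden kinship built
from every chromosome except the one carrying the tested SNP (LOCO),
avoiding proximal contamination. Variance components are re-estimated by
REML for each LOCO partition; the SNP effect is then estimated by
generalised least squares with V = K*sA2 + I*sE2 fixed, and tested with a
Wald statistic under the normal approximation.

The genome-wide significance threshold is 1/N: for chip panels N is the
SNP count after QC, for sequence panels N is the number of independent
SNPs left by PLINK-style LD pruning (--indep-pairwise 50 10 0.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .core import centered_dosages
from .lmm import LMMError, reml_single
from .panel import GRM, GenotypePanel

logger = logging.getLogger(__name__)


@dataclass
class GWASResult:
    table: pd.DataFrame          # columns id, chrom, pos, beta, se, p
    threshold: float
    n_effective: int             # SNP count behind the 1/N threshold
    untested_ids: list = field(default_factory=list)


@dataclass
class SNPSelection:
    significant_ids: list
    top_snp: str | None
    trait: str = ""
    fold: int | None = None

    def is_empty(self) -> bool:
        return len(self.significant_ids) == 0


def compute_pcs(grm: GRM, k: int = 2) -> np.ndarray:
    """Top-k principal components of the GRM, scaled by sqrt(eigenvalue)."""
    if k >= grm.n:
        raise ValueError(f"k={k} must be below the number of individuals {grm.n}")
    if k == 0:
        return np.zeros((grm.n, 0))
    vals, vecs = linalg.eigh(grm.matrix)
    order = np.argsort(vals)[::-1][:k]
    return vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))


def significance_threshold(n_snps: int, panel_kind: str, pruned_count: int | None = None) -> float:
    """Genome-wide 1/N threshold; sequence panels use the pruned SNP count."""
    if panel_kind == "chip":
        if n_snps <= 0:
            raise ValueError("n_snps must be positive")
        return 1.0 / n_snps
    if panel_kind in ("wgs", "merged"):
        if not pruned_count:
            raise ValueError("sequence panels need the independent-SNP count")
        return 1.0 / pruned_count
    raise ValueError(f"unknown panel kind {panel_kind!r}")


def _chromosome_grm_parts(panel: GenotypePanel):
    """Per-chromosome ZZ' cross-products and 2*sum(p(1-p)) scales."""
    chrom = panel.snp_map["chrom"].to_numpy()
    parts = {}
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        Z, p = centered_dosages(panel, idx)
        poly = (p > 0) & (p < 1)
        Zp = Z[:, poly]
        parts[c] = (Zp @ Zp.T, 2.0 * float(np.sum(p[poly] * (1 - p[poly]))))
    return parts


def fit_mlm_scan(
    panel: GenotypePanel,
    phenotype: np.ndarray,
    fixed_covariates: np.ndarray | None = None,
    loco: bool = True,
    threshold: float | None = None,
    n_effective: int | None = None,
    ridge: float = 1e-6,
    var_override: tuple | None = None,
) -> GWASResult:
    """Association scan of every SNP in the panel against one phenotype.

    ``phenotype`` may contain NaN (e.g. masked validation individuals);
    those rows are excluded from the analysis entirely. ``fixed_covariates``
    should not include an intercept (added internally).
    """
    y = np.asarray(phenotype, float).ravel()
    if panel.n_individuals != len(y):
        raise ValueError("phenotype length does not match panel")
    obs = np.isfinite(y)
    if np.nanstd(y) == 0:
        raise ValueError("phenotype is constant")
    rows = np.flatnonzero(obs)
    yo = y[rows]
    X = np.ones((len(rows), 1))
    if fixed_covariates is not None and np.asarray(fixed_covariates).shape[1] > 0:
        X = np.column_stack([X, np.asarray(fixed_covariates, float)[rows]])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed covariates are rank deficient")

    parts = _chromosome_grm_parts(panel)
    total_cross = sum(m for m, _ in parts.values())
    total_scale = sum(s for _, s in parts.values())
    chrom = panel.snp_map["chrom"].to_numpy()

    records = []
    untested = []
    chroms = list(pd.unique(chrom))
    for c in chroms if loco else [None]:
        if loco:
            cross, scale = parts[c]
            denom = total_scale - scale
            if denom <= 0:
                raise LMMError(f"LOCO kinship undefined for chromosome {c} (single-chromosome panel?)")
            K = (total_cross - cross) / denom
            test_cols = np.flatnonzero(chrom == c)
        else:
            K = total_cross / total_scale
            test_cols = np.arange(panel.n_snps)
        Ko = K[np.ix_(rows, rows)] + ridge * np.eye(len(rows))
        if var_override is not None:
            sA, sE = var_override
        else:
            vc = reml_single(yo, X, Ko)
            if not vc.converged:
                raise LMMError(
                    f"REML failed for LOCO partition {c!r}: loglik={vc.loglik:.4g}, iters={vc.n_iter}"
                )
            sA = vc.genetic[0][0, 0]
            sE = vc.residual[0, 0]
        V = sA * Ko + sE * np.eye(len(rows))
        cf = linalg.cho_factor(V, lower=True)
        Vinv_X = linalg.cho_solve(cf, X)
        XVX_inv = np.linalg.inv(X.T @ Vinv_X)
        Vinv_y = linalg.cho_solve(cf, yo)
        Py = Vinv_y - Vinv_X @ (XVX_inv @ (X.T @ Vinv_y))

        Z, _ = centered_dosages(panel, test_cols)
        Zo = Z[rows]
        PZ = linalg.cho_solve(cf, Zo) - Vinv_X @ (XVX_inv @ (Vinv_X.T @ Zo))
        ztPz = np.einsum("ij,ij->j", Zo, PZ)
        ztPy = Zo.T @ Py
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = ztPy / ztPz
            se = np.sqrt(1.0 / ztPz)
        snp_var = Zo.var(axis=0)
        for k, col in enumerate(test_cols):
            sid = panel.snp_map.at[col, "id"]
            if snp_var[k] <= 0 or not np.isfinite(se[k]) or ztPz[k] <= 0:
                untested.append(sid)
                continue
            z = beta[k] / se[k]
            records.append(
                {
                    "id": sid,
                    "chrom": panel.snp_map.at[col, "chrom"],
                    "pos": panel.snp_map.at[col, "pos"],
                    "beta": beta[k],
                    "se": se[k],
                    "p": max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny),
                }
            )
    table = pd.DataFrame(records)
    if threshold is None:
        threshold = 1.0 / max(len(table), 1)
    return GWASResult(
        table=table,
        threshold=float(threshold),
        n_effective=int(n_effective if n_effective is not None else len(table)),
        untested_ids=untested,
    )


def select_snps(result: GWASResult, trait: str = "", fold: int | None = None) -> SNPSelection:
    """Significant set {p < threshold} and the most significant SNP.

    The top SNP is the argmin-p member of the significant set; exact
    p-value ties break toward the lower (chromosome, position).
    """
    t = result.table
    if len(t) == 0:
        return SNPSelection([], None, trait, fold)
    sig = t[t["p"] < result.threshold]
    if len(sig) == 0:
        return SNPSelection([], None, trait, fold)
    best = sig.sort_values(["p", "chrom", "pos"], kind="mergesort").iloc[0]
    return SNPSelection(list(sig["id"]), str(best["id"]), trait, fold)
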