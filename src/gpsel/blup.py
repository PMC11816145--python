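"""BLUP-alphabet genomic prediction models as sklearn-style estimators.

Eight models from the study design are covered by three estimator
classes plus an alias:

``GBLUP``
    y = Xa + Zg + e with g ~ N(0, G sA2), G the VanRaden relationship
    matrix over all markers of the supplied panel. ``n_traits=2`` gives
    the multi-trait form with 2x2 genetic and residual covariances.
``MABLUP``
    GBLUP plus the most significant GWAS SNP(s) as fixed covariates; the
    breeding value includes the fixed-SNP term M*s_hat.
``MultiBLUP``
    two correlated random genomic terms whose relationship matrices are
    built from disjoint marker groups (GWAS-significant vs the rest).
``OneBLUP``
    GBLUP whose single G is built on the chip markers merged with the
    GWAS-significant sequence markers (the merge happens upstream; the
    class is an alias that names the design).

Estimators follow sklearn conventions: hyperparameters in ``__init__``,
``fit(X, y, covariates=...)`` with X the n x m dosage matrix, fitted
attributes with trailing underscores, and ``predict(X)`` returning
genomic breeding values for new individuals via the cross-relationship
with the training set. ``y`` entries set to NaN are treated as
unphenotyped: they do not enter the likelihood but still receive
breeding values (``gebv_``), which is how validation folds are predicted
without touching their phenotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .core import merge_panels
from .lmm import BLUPSolution, LMMError, VarianceComponents, blup_solve, reml_general, reml_single
from .panel import GenotypePanel

logger = logging.getLogger(__name__)


def _vanraden_parts(X, cols=None, freqs=None):
    """Centered dosage block and VanRaden scale for a column subset."""
    D = X if cols is None else X[:, cols]
    if freqs is None:
        with np.errstate(invalid="ignore"):
            p = np.nanmean(D, axis=0) / 2.0
        p = np.where(np.isnan(p), 0.0, p)
    else:
        p = freqs
    Z = np.where(np.isnan(D), 2.0 * p, D) - 2.0 * p
    poly = (p > 0) & (p < 1)
    scale = 2.0 * float(np.sum(p[poly] * (1 - p[poly])))
    return Z[:, poly], p, poly, scale


def _as_trait_list(arr, n, q):
    """Normalise a covariate argument to one design block per trait."""
    if arr is None:
        return [np.ones((n, 1)) for _ in range(q)]
    if isinstance(arr, (list, tuple)):
        if len(arr) != q:
            raise ValueError(f"need {q} covariate blocks, got {len(arr)}")
        return [np.column_stack([np.ones(n), np.asarray(a, float)]) if a is not None and np.asarray(a).size else np.ones((n, 1)) for a in arr]
    a = np.asarray(arr, float)
    if a.ndim == 1:
        a = a[:, None]
    return [np.column_stack([np.ones(n), a]) for _ in range(q)]


class GBLUP(BaseEstimator, RegressorMixin):
    """Genomic BLUP with a single VanRaden relationship matrix.

    Parameters
    ----------
    n_traits : 1 or 2
        Single- or multi-trait analysis.
    ridge : float
        Diagonal stabiliser added to G before any solve.
    var_components : VarianceComponents | tuple | None
        If given, REML is skipped: a tuple ``(sA2, sE2)`` for one trait,
        or a full :class:`VarianceComponents`.
    max_iter, tol : AI-REML iteration control (multi-trait/general path).
    """

    _model_name = "GBLUP"

    def __init__(self, n_traits: int = 1, ridge: float = 1e-6,
                 var_components=None, max_iter: int = 200, tol: float = 1e-8):
        self.n_traits = n_traits
        self.ridge = ridge
        self.var_components = var_components
        self.max_iter = max_iter
        self.tol = tol

    # -- hooks overridden by subclasses ---------------------------------
    def _kernel_groups(self, X):
        """Column groups, one per random genomic term."""
        return [np.arange(X.shape[1])]

    def _snp_fixed_columns(self, X):
        """Per-trait fixed-SNP column indices (MABLUP); empty for GBLUP."""
        return [[] for _ in range(self.n_traits)]

    # --------------------------------------------------------------------
    def _validate_y(self, y, n):
        Y = np.asarray(y, float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if Y.shape != (n, self.n_traits):
            raise ValueError(f"y must be ({n}, {self.n_traits}); got {Y.shape}")
        if not np.isfinite(Y).any(axis=0).all():
            raise ValueError("each trait needs at least one phenotyped individual")
        return Y

    def fit(self, X, y, covariates=None):
        X = np.asarray(X, float)
        n = X.shape[0]
        Y = self._validate_y(y, n)
        q = self.n_traits
        X_list = _as_trait_list(covariates, n, q)

        # fixed-SNP (MABLUP) columns appended to each trait's design
        snp_cols = self._snp_fixed_columns(X)
        for t in range(q):
            if len(snp_cols[t]):
                M = np.where(np.isnan(X[:, snp_cols[t]]), 0.0, X[:, snp_cols[t]])
                X_list[t] = np.column_stack([X_list[t], M])

        groups = self._kernel_groups(X)
        kernels, self._terms_, self._train_Z_ = [], [], []
        for g in groups:
            Z, p, poly, scale = _vanraden_parts(X, np.asarray(g, dtype=int))
            if scale <= 0:
                raise LMMError("marker group is entirely monomorphic")
            K = (Z @ Z.T) / scale + self.ridge * np.eye(n)
            kernels.append(K)
            self._train_Z_.append(Z)
            self._terms_.append({"cols": np.asarray(g, dtype=int), "freqs": p, "poly": poly, "scale": scale})

        vc = self._resolve_varcomp(Y, X_list, kernels)
        sol = blup_solve(Y, X_list, kernels, vc)

        self.varcomp_ = vc
        self.beta_ = sol.beta_split
        self.components_ = {f"grm{r}": sol.random_effects[r] for r in range(len(kernels))}
        gebv = sum(sol.random_effects)
        # MABLUP: the fixed-SNP contribution is part of the breeding value
        snp_contrib = np.zeros((n, q))
        for t in range(q):
            if len(snp_cols[t]):
                M = np.where(np.isnan(X[:, snp_cols[t]]), 0.0, X[:, snp_cols[t]])
                s_hat = sol.beta_split[t][-len(snp_cols[t]):]
                snp_contrib[:, t] = M @ s_hat
        if any(len(c) for c in snp_cols):
            self.components_["snp_fixed"] = snp_contrib
            gebv = gebv + snp_contrib
        self.gebv_ = gebv[:, 0] if q == 1 else gebv
        self.h2_ = tuple(vc.h2(t) for t in range(q))
        self.converged_ = vc.converged
        self.n_iter_ = vc.n_iter
        self.loglik_ = vc.loglik
        self._solution_ = sol
        self._n_fit_ = n
        return self

    def _resolve_varcomp(self, Y, X_list, kernels) -> VarianceComponents:
        q = self.n_traits
        vcin = self.var_components
        if isinstance(vcin, VarianceComponents):
            return vcin
        if vcin is not None:
            sA, sE = vcin
            return VarianceComponents(
                genetic=[np.atleast_2d(np.asarray(sA, float)) for _ in kernels],
                residual=np.atleast_2d(np.asarray(sE, float)),
                loglik=np.nan, converged=True, n_iter=0, n_traits=q,
            )
        if q == 1 and len(kernels) == 1:
            y = Y[:, 0]
            fin = np.flatnonzero(np.isfinite(y))
            if len(fin) < 50:
                logger.warning("only %d phenotyped individuals in REML fit", len(fin))
            vc = reml_single(y[fin], X_list[0][fin], kernels[0][np.ix_(fin, fin)])
            if not vc.converged:
                raise LMMError("single-trait REML did not converge")
            return vc
        return reml_general(Y, X_list, kernels, max_iter=self.max_iter, tol=self.tol)

    def predict(self, X):
        """Genomic breeding values for new individuals' dosages."""
        if not hasattr(self, "_solution_"):
            raise RuntimeError("estimator is not fitted")
        X = np.asarray(X, float)
        sol: BLUPSolution = self._solution_
        q = self.n_traits
        out = np.zeros((X.shape[0], q))
        for r, term in enumerate(self._terms_):
            Zn, _, _, _ = _vanraden_parts(X, term["cols"], freqs=term["freqs"])
            # _vanraden_parts drops the training-monomorphic columns via poly
            Kx = (Zn @ self._train_Z_[r].T) / term["scale"]
            S = self.varcomp_.genetic[r]
            offset = 0
            parts = []
            for l in range(q):
                rows_l = sol.obs_by_trait[l]
                parts.append(Kx[:, rows_l] @ sol.Py[offset : offset + len(rows_l)])
                offset += len(rows_l)
            for t in range(q):
                for l in range(q):
                    out[:, t] += S[t, l] * parts[l]
        return out[:, 0] if q == 1 else out


class MABLUP(GBLUP):
    """GBLUP with the most significant GWAS SNP(s) as fixed effects.

    ``snp_fixed_idx`` gives the dosage-matrix column(s) of the top SNP
    for a single-trait fit, or one list per trait for a multi-trait fit.
    ``None``/empty degrades gracefully to plain GBLUP (logged), which is
    the behaviour when a training fold yields no significant SNP.
    """

    _model_name = "MABLUP"

    def __init__(self, n_traits: int = 1, snp_fixed_idx=None, ridge: float = 1e-6,
                 var_components=None, max_iter: int = 200, tol: float = 1e-8):
        super().__init__(n_traits=n_traits, ridge=ridge, var_components=var_components,
                         max_iter=max_iter, tol=tol)
        self.snp_fixed_idx = snp_fixed_idx

    def _snp_fixed_columns(self, X):
        idx = self.snp_fixed_idx
        if idx is None:
            logger.warning("MABLUP without significant SNPs degrades to GBLUP")
            return [[] for _ in range(self.n_traits)]
        if self.n_traits == 1:
            return [list(np.atleast_1d(idx))]
        return [list(np.atleast_1d(i)) if i is not None else [] for i in idx]


class MultiBLUP(GBLUP):
    """GBLUP with two random genomic terms over disjoint marker groups.

    ``group1_idx`` lists the dosage columns of the first term (the
    GWAS-significant markers); the second term covers the remaining
    columns. An empty first group degrades to plain GBLUP (logged).
    """

    _model_name = "MultiBLUP"

    def __init__(self, n_traits: int = 1, group1_idx=None, ridge: float = 1e-6,
                 var_components=None, max_iter: int = 200, tol: float = 1e-8):
        super().__init__(n_traits=n_traits, ridge=ridge, var_components=var_components,
                         max_iter=max_iter, tol=tol)
        self.group1_idx = group1_idx

    def _kernel_groups(self, X):
        if self.group1_idx is None or len(self.group1_idx) == 0:
            logger.warning("MultiBLUP without significant SNPs degrades to GBLUP")
            return [np.arange(X.shape[1])]
        g1 = np.asarray(self.group1_idx, dtype=int)
        g2 = np.setdiff1d(np.arange(X.shape[1]), g1)
        if len(g2) == 0:
            raise ValueError("second marker group is empty")
        return [g1, g2]


class OneBLUP(GBLUP):
    """GBLUP on chip markers merged with GWAS-significant sequence markers."""

    _model_name = "OneBLUP"


# ---------------------------------------------------------------------------
# study-design assembly (Table-1 model/dataset grid)
# ---------------------------------------------------------------------------

# legal dataset per model: 1 chip, 2 chip + significant sequence SNPs, 3 sequence
TABLE1: dict = {
    "ST-GBLUP": {1, 3}, "MT-GBLUP": {1, 3},
    "ST-MABLUP": {1, 3}, "MT-MABLUP": {1, 3},
    "ST-OneBLUP": {2}, "MT-OneBLUP": {2},
    "ST-MultiBLUP": {2, 3}, "MT-MultiBLUP": {2, 3},
    "BayesA": {1, 2}, "BayesB": {1, 2}, "BayesBpi": {1, 2},
    "BayesC": {1, 2}, "BayesCpi": {1, 2}, "BayesLasso": {1, 2}, "BayesR": {1, 2},
}

BAYES_FAMILIES = {"BayesA": "A", "BayesB": "B", "BayesBpi": "Bpi", "BayesC": "C",
                  "BayesCpi": "Cpi", "BayesLasso": "Lasso", "BayesR": "R"}


@dataclass
class ModelPlan:
    """A fully assembled model/dataset cell: estimator plus its marker panel."""

    model_name: str
    dataset: int
    estimator: object
    panel: GenotypePanel
    traits: list                      # trait indices the fit covers
    meta: dict = field(default_factory=dict)

    @property
    def is_multitrait(self) -> bool:
        return len(self.traits) == 2


def _union_selection(selections, kind, traits):
    ids = []
    for t in traits:
        sel = selections.get((kind, t))
        if sel is not None:
            ids.extend(sel.significant_ids)
    return list(dict.fromkeys(ids))  # order-preserving union


def build_model(
    model_name: str,
    dataset: int,
    panels: dict,
    selections: dict | None = None,
    target_trait: int = 0,
    **estimator_kwargs,
) -> ModelPlan:
    """Assemble the marker panel and estimator for one Table-1 grid cell.

    ``panels`` maps ``chip``/``wgs`` to QC'd :class:`GenotypePanel`s over
    identical individuals; ``selections`` maps ``(panel_kind, trait)`` to
    the training-fold :class:`SNPSelection` feeding GWAS-integrated models.
    """
    if model_name not in TABLE1:
        raise ValueError(f"unknown model {model_name!r}")
    if dataset not in TABLE1[model_name]:
        raise ValueError(f"model {model_name} is not run on dataset {dataset} in this design")
    selections = selections or {}
    chip, wgs = panels["chip"], panels["wgs"]
    mt = model_name.startswith("MT-")
    traits = [0, 1] if mt else [target_trait]
    q = 2 if mt else 1
    meta: dict = {}

    if model_name in BAYES_FAMILIES:
        from .bayes import BayesAlphabet  # local import avoids a cycle

        if dataset == 1:
            panel = chip
        else:
            sig = _union_selection(selections, "wgs", traits)
            panel = merge_panels(chip, wgs.subset_snps(sig)) if sig else chip.copy()
            meta["n_significant"] = len(sig)
        est = BayesAlphabet(family=BAYES_FAMILIES[model_name], **estimator_kwargs)
        return ModelPlan(model_name, dataset, est, panel, traits, meta)

    base = model_name.split("-", 1)[1]
    if base in ("GBLUP", "MABLUP"):
        kind = "chip" if dataset == 1 else "wgs"
        panel = panels[kind]
        if base == "GBLUP":
            est = GBLUP(n_traits=q, **estimator_kwargs)
        else:
            tops = []
            for t in traits:
                sel = selections.get((kind, t))
                top = sel.top_snp if sel is not None else None
                tops.append(int(panel.snp_indexer([top])[0]) if top else None)
            meta["top_snps"] = tops
            if mt:
                idx = [[i] if i is not None else [] for i in tops]
                idx = None if all(len(i) == 0 for i in idx) else idx
            else:
                idx = [tops[0]] if tops[0] is not None else None
            est = MABLUP(n_traits=q, snp_fixed_idx=idx, **estimator_kwargs)
        return ModelPlan(model_name, dataset, est, panel, traits, meta)

    if base == "OneBLUP":
        sig = _union_selection(selections, "wgs", traits)
        panel = merge_panels(chip, wgs.subset_snps(sig)) if sig else chip.copy()
        meta["n_significant"] = len(sig)
        est = OneBLUP(n_traits=q, **estimator_kwargs)
        return ModelPlan(model_name, dataset, est, panel, traits, meta)

    if base == "MultiBLUP":
        sig = _union_selection(selections, "wgs", traits)
        if dataset == 2:
            panel = merge_panels(chip, wgs.subset_snps(sig)) if sig else chip.copy()
        else:
            panel = wgs
        g1 = panel.snp_indexer(sig) if sig else []
        meta["n_significant"] = len(sig)
        est = MultiBLUP(n_traits=q, group1_idx=list(g1) if len(g1) else None, **estimator_kwargs)
        return ModelPlan(model_name, dataset, est, panel, traits, meta)

    raise ValueError(f"unhandled model {model_name!r}")  # pragma: no cover


# thin functional wrappers over the estimator layer -------------------------

def reml_fit(plan: ModelPlan, Y, covariates=None) -> VarianceComponents:
    """Estimate the plan's variance components (see class docs for the model)."""
    est = plan.estimator
    est.fit(plan.panel.dosages, Y, covariates=covariates)
    return est.varcomp_


@dataclass
class GEBVResult:
    gebv: np.ndarray
    components: dict
    model_name: str
    fold: int | None = None


def solve_mme(plan: ModelPlan, vc: VarianceComponents, Y, covariates=None, fold=None) -> GEBVResult:
    """Solve the mixed-model equations at fixed variance components."""
    est = plan.estimator.set_params(var_components=vc)
    est.fit(plan.panel.dosages, Y, covariates=covariates)
    return GEBVResult(gebv=est.gebv_, components=est.components_,
                      model_name=plan.model_name, fold=fold)
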