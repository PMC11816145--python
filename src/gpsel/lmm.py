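"""Restricted-maximum-likelihood estimation and BLUP solving for
Gaussian mixed models with genomic covariance structures.

Two engines are provided. Single-trait models with one relationship
matrix use an eigendecomposition fast path: the GRM is diagonalised once
and the restricted likelihood, profiled over the residual variance, is
maximised over the variance ratio by bounded scalar search — this cannot
fail to converge and costs O(n) per likelihood evaluation. Everything
else (two random terms and/or two traits, arbitrary missing-record
patterns) goes through dense average-information REML with step-halving
and projection of each (co)variance block onto the positive-semidefinite
cone.

Breeding values for unphenotyped (validation) individuals come from the
standard BLUP cross-covariance identity u = Cov(u, y) V^{-1} (y - Xb),
with the relationship matrix spanning phenotyped and unphenotyped
individuals alike; this is algebraically identical to solving Henderson's
mixed-model equations with those phenotypes masked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize


class LMMError(RuntimeError):
    pass


@dataclass
class VarianceComponents:
    """REML estimates for a (possibly multi-trait, multi-kernel) mixed model.

    ``genetic`` holds one q x q covariance matrix per random term (q =
    number of traits; scalars are 1 x 1 matrices), ``residual`` the q x q
    residual covariance.
    """

    genetic: list
    residual: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    n_traits: int = 1

    def h2(self, trait: int = 0) -> float:
        g = sum(term[trait, trait] for term in self.genetic)
        return float(g / (g + self.residual[trait, trait]))

    def genetic_correlation(self, term: int = 0) -> float:
        S = self.genetic[term]
        if S.shape[0] < 2:
            raise LMMError("genetic correlation needs a two-trait fit")
        denom = np.sqrt(S[0, 0] * S[1, 1])
        return float(S[0, 1] / denom) if denom > 0 else 0.0


# ---------------------------------------------------------------------------
# single-trait, single-kernel fast path
# ---------------------------------------------------------------------------

def reml_single(y, X, K, gamma_bounds=(-8.0, 8.0)) -> VarianceComponents:
    """REML for y = Xb + g + e with g ~ N(0, K sA2), e ~ N(0, I sE2).

    Maximises the profiled restricted likelihood over log10 of the
    variance ratio gamma = sA2/sE2.
    """
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    if len(y) != n:
        raise LMMError("y/X dimension mismatch")
    d, U = linalg.eigh(K)
    d = np.maximum(d, 0.0)
    yt = U.T @ y
    Xt = U.T @ X
    dof = n - p

    def neg_prof(t):
        gamma = 10.0 ** t
        a = gamma * d + 1.0
        w = 1.0 / a
        XtW = Xt * w[:, None]
        XWX = Xt.T @ XtW
        beta = np.linalg.solve(XWX, XtW.T @ yt)
        r = yt - Xt @ beta
        rss = float(r @ (w * r))
        sign, logdet_xwx = np.linalg.slogdet(XWX)
        return 0.5 * (dof * np.log(rss / dof) + np.sum(np.log(a)) + logdet_xwx)

    res = optimize.minimize_scalar(
        neg_prof, bounds=gamma_bounds, method="bounded",
        options={"xatol": 1e-10, "maxiter": 500},
    )
    gamma = 10.0 ** res.x
    a = gamma * d + 1.0
    w = 1.0 / a
    XtW = Xt * w[:, None]
    XWX = Xt.T @ XtW
    beta = np.linalg.solve(XWX, XtW.T @ yt)
    r = yt - Xt @ beta
    s_e = float(r @ (w * r)) / dof
    s_a = gamma * s_e
    return VarianceComponents(
        genetic=[np.array([[s_a]])],
        residual=np.array([[s_e]]),
        loglik=-float(res.fun) - 0.5 * dof,
        converged=bool(res.success),
        n_iter=int(res.nfev),
        n_traits=1,
    )


# ---------------------------------------------------------------------------
# general dense AI-REML
# ---------------------------------------------------------------------------

def _vech_indices(q):
    """(k, l) index pairs of the lower triangle of a q x q symmetric matrix."""
    return [(k, l) for k in range(q) for l in range(k, q)]


def _block_basis(q, k, l):
    E = np.zeros((q, q))
    E[k, l] = 1.0
    E[l, k] = 1.0
    return E


def _project_psd(S, floor):
    vals, vecs = np.linalg.eigh(S)
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


class _GeneralREMLProblem:
    """Dense REML with V(theta) linear in the (co)variance parameters."""

    def __init__(self, Y, X_list, K_list):
        Y = np.asarray(Y, float)
        if Y.ndim == 1:
            Y = Y[:, None]
        self.n, self.q = Y.shape
        self.K_list = [np.asarray(K, float) for K in K_list]
        obs = np.isfinite(Y)
        # observations stacked trait-major: trait-0 block, then trait-1 block
        self.y = np.concatenate([Y[obs[:, t], t] for t in range(self.q)])
        blocks = []
        p_tot = sum(X.shape[1] for X in X_list)
        col = 0
        for t, X in enumerate(X_list):
            Xb = np.zeros((obs[:, t].sum(), p_tot))
            Xb[:, col : col + X.shape[1]] = np.asarray(X, float)[obs[:, t]]
            blocks.append(Xb)
            col += X.shape[1]
        X_full = np.concatenate(blocks, axis=0)
        # fixed effects with no observed records (e.g. a fully masked trait)
        # are dropped from the solve and reported as zero
        self.col_keep = np.any(X_full != 0.0, axis=0)
        self.p_full = p_tot
        self.X = X_full[:, self.col_keep]
        self.obs_by_trait = [np.flatnonzero(obs[:, t]) for t in range(self.q)]
        self.pairs = _vech_indices(self.q)
        self.n_terms = len(K_list)
        self.n_par_per = len(self.pairs)

    def materialize(self, term):
        """Restricted derivative matrices for one covariance block's parameters."""
        K = np.eye(self.n) if term == self.n_terms else self.K_list[term]
        mats = []
        for (k, l) in self.pairs:
            D = np.zeros((len(self.y), len(self.y)))
            rk = self._rows(k)
            rl = self._rows(l)
            Kkl = K[np.ix_(self.obs_by_trait[k], self.obs_by_trait[l])]
            D[np.ix_(rk, rl)] += Kkl
            if k != l:
                D[np.ix_(rl, rk)] += Kkl.T
            mats.append(D)
        return mats

    def _rows(self, t):
        start = sum(len(self.obs_by_trait[s]) for s in range(t))
        return np.arange(start, start + len(self.obs_by_trait[t]))

    def build_V(self, theta_blocks):
        V = np.zeros((len(self.y), len(self.y)))
        for term in range(self.n_terms + 1):
            S = theta_blocks[term]
            K = np.eye(self.n) if term == self.n_terms else self.K_list[term]
            for k in range(self.q):
                for l in range(self.q):
                    if S[k, l] == 0.0:
                        continue
                    V[np.ix_(self._rows(k), self._rows(l))] += S[k, l] * K[
                        np.ix_(self.obs_by_trait[k], self.obs_by_trait[l])
                    ]
        return V

    def loglik(self, theta_blocks):
        V = self.build_V(theta_blocks)
        try:
            cf = linalg.cho_factor(V, lower=True)
        except linalg.LinAlgError:
            return -np.inf, None, None
        logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
        Vinv_y = linalg.cho_solve(cf, self.y)
        Vinv_X = linalg.cho_solve(cf, self.X)
        XVX = self.X.T @ Vinv_X
        sign, logdet_xvx = np.linalg.slogdet(XVX)
        if sign <= 0:
            return -np.inf, None, None
        beta = np.linalg.solve(XVX, self.X.T @ Vinv_y)
        Py = Vinv_y - Vinv_X @ beta
        ll = -0.5 * (logdetV + logdet_xvx + float(self.y @ Py))
        P = linalg.cho_solve(cf, np.eye(len(self.y))) - Vinv_X @ np.linalg.solve(XVX, Vinv_X.T)
        return ll, P, Py


def reml_general(Y, X_list, K_list, max_iter: int = 200, tol: float = 1e-8) -> VarianceComponents:
    """AI-REML for multi-trait and/or multi-kernel models.

    Parameters are the unique elements of one q x q genetic covariance per
    kernel plus the q x q residual covariance; updates are Newton steps on
    the average-information matrix with step-halving, each trial projected
    onto the PSD cone.
    """
    prob = _GeneralREMLProblem(Y, X_list, K_list)
    q = prob.q
    Y2 = np.asarray(Y, float)
    if Y2.ndim == 1:
        Y2 = Y2[:, None]
    vary = np.array([
        np.nanvar(Y2[:, t]) if np.isfinite(Y2[:, t]).any() else np.nan for t in range(q)
    ])
    # traits with no records (or constant records) get a unit placeholder so
    # the starting V is positive definite; their components stay unidentified
    fallback = float(np.nanmax(vary)) if np.any(np.isfinite(vary) & (vary > 0)) else 1.0
    vary = np.where(np.isfinite(vary) & (vary > 0), vary, fallback)
    n_terms = prob.n_terms
    theta = [np.diag(vary) * (0.5 / n_terms) for _ in range(n_terms)] + [np.diag(vary) * 0.5]
    floor = 1e-8 * float(vary.mean())

    D_all = []
    for term in range(n_terms + 1):
        D_all.extend(prob.materialize(term))

    ll, P, Py = prob.loglik(theta)
    if not np.isfinite(ll):
        raise LMMError("non-finite starting likelihood")
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # score and AI matrix
        npar = len(D_all)
        score = np.empty(npar)
        W = np.empty((len(prob.y), npar))
        for i, D in enumerate(D_all):
            score[i] = -0.5 * (np.sum(P * D) - float(Py @ (D @ Py)))
            W[:, i] = D @ Py
        PW = P @ W
        AI = 0.5 * (W.T @ PW)
        try:
            delta = np.linalg.solve(AI + 1e-8 * np.eye(npar) * max(np.trace(AI) / npar, 1.0), score)
        except np.linalg.LinAlgError:
            delta = score / max(np.abs(np.diag(AI)).max(), 1.0)

        accepted = False
        step = 1.0
        for _ in range(12):
            trial = []
            k = 0
            for term in range(n_terms + 1):
                S = theta[term].copy()
                for (a, b) in prob.pairs:
                    S = S + step * delta[k] * _block_basis(q, a, b)
                    k += 1
                f = floor if term < n_terms else max(floor, 1e-6 * float(vary.mean()))
                trial.append(_project_psd(S, f))
            ll_new, P_new, Py_new = prob.loglik(trial)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-10:
                theta, P, Py = trial, P_new, Py_new
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        if abs(ll_new - ll) < tol * (1.0 + abs(ll)):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    return VarianceComponents(
        genetic=[theta[r] for r in range(n_terms)],
        residual=theta[n_terms],
        loglik=float(ll),
        converged=converged,
        n_iter=it,
        n_traits=q,
    )


def reml_fit_auto(Y, X_list, K_list, **kwargs) -> VarianceComponents:
    """Dispatch to the eigen fast path when it applies, else general AI-REML."""
    Y = np.asarray(Y, float)
    if Y.ndim == 1 or Y.shape[1] == 1:
        y = Y.ravel()
        if len(K_list) == 1:
            fin = np.isfinite(y)
            vc = reml_single(y[fin], np.asarray(X_list[0])[fin], np.asarray(K_list[0])[np.ix_(np.flatnonzero(fin), np.flatnonzero(fin))])
            return vc
    return reml_general(Y, X_list, K_list, **kwargs)


# ---------------------------------------------------------------------------
# BLUP solving with masked phenotypes
# ---------------------------------------------------------------------------

@dataclass
class BLUPSolution:
    beta: np.ndarray              # stacked fixed effects (traits concatenated)
    beta_split: list              # per-trait fixed-effect vectors
    random_effects: list          # per term: (n, q) BLUPs for every individual
    gebv: np.ndarray              # (n, q) sum of random terms per individual/trait
    Py: np.ndarray = field(default=None)          # V^{-1}(y - Xb) on observed rows
    obs_by_trait: list = field(default_factory=list)


def blup_solve(Y, X_list, K_list, vc: VarianceComponents) -> BLUPSolution:
    """Solve for fixed effects and random-term BLUPs given variance components.

    Rows of ``Y`` with NaN are treated as unphenotyped; every individual
    still receives a BLUP for each random term through the relationship
    matrix, which is how validation-set breeding values are predicted.
    """
    prob = _GeneralREMLProblem(Y, X_list, K_list)
    q = prob.q
    theta = list(vc.genetic) + [vc.residual]
    V = prob.build_V(theta)
    cf = linalg.cho_factor(V, lower=True)
    Vinv_y = linalg.cho_solve(cf, prob.y)
    Vinv_X = linalg.cho_solve(cf, prob.X)
    XVX = prob.X.T @ Vinv_X
    beta = np.linalg.solve(XVX, prob.X.T @ Vinv_y)
    Py = Vinv_y - Vinv_X @ beta

    n = prob.n
    random_effects = []
    gebv = np.zeros((n, q))
    for term, K in enumerate(prob.K_list):
        S = vc.genetic[term]
        u = np.zeros((n, q))
        # u_t = sum_l S[t, l] * K[:, obs_l] @ Py_l
        offset = 0
        parts = []
        for l in range(q):
            rows_l = prob.obs_by_trait[l]
            parts.append(K[:, rows_l] @ Py[offset : offset + len(rows_l)])
            offset += len(rows_l)
        for t in range(q):
            for l in range(q):
                u[:, t] += S[t, l] * parts[l]
        random_effects.append(u)
        gebv += u

    beta_full = np.zeros(prob.p_full)
    beta_full[prob.col_keep] = beta
    p_sizes = [X.shape[1] for X in X_list]
    beta_split, col = [], 0
    for p in p_sizes:
        beta_split.append(beta_full[col : col + p])
        col += p
    return BLUPSolution(
        beta=beta_full, beta_split=beta_split, random_effects=random_effects, gebv=gebv,
        Py=Py, obs_by_trait=prob.obs_by_trait,
    )
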