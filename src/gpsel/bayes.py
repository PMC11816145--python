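"""Bayesian-alphabet marker-effect models via single-site Gibbs sampling.

The sampling model is y = Xa + sum_i z_i g_i + e with a flat prior on the
fixed effects a and family-specific priors on the marker effects g_i:

====== ===================================================================
A      every marker in; per-marker variance, scaled-inverse-chi-square(v,S)
B      pi = 0.95 of markers null; per-marker variance as BayesA
Bpi    as B with pi ~ U(0,1), updated from its Beta conditional
C      pi = 0.95; one shared variance for all non-null markers
Cpi    as C with pi estimated
Lasso  every marker in; variance exponential(lambda^2/2) (double-exponential
       marginal), latent scales updated by inverse-Gaussian draws
R      four-component normal mixture with variances (0, 1e-4, 1e-3, 1e-2)
       x sigma_g^2 and starting proportions (0.95, 0.02, 0.02, 0.01),
       proportions updated from a flat Dirichlet unless fixed
====== ===================================================================

Marker inclusion is sampled with the effect integrated out, then the
effect from its normal conditional; variances come from their
scaled-inverse-chi-square conditionals and the residual variance from
its own. The GEBV is sum_i z_i ghat_i over posterior-mean effects. The
inner sweep is JIT-compiled (numba); chains are bit-reproducible under a
fixed seed.

Hyperparameters default to v=5 with the scale S solved so the prior mean
per-marker variance matches an assumed heritability spread over the
markers; every realised value is recorded in the returned summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from sklearn.base import BaseEstimator, RegressorMixin

FAMILIES = ("A", "B", "Bpi", "C", "Cpi", "Lasso", "R")
_FAMILY_CODE = {f: i for i, f in enumerate(FAMILIES)}

R_MIX_PROPS = (0.95, 0.02, 0.02, 0.01)
R_MIX_SCALARS = (0.0, 1e-4, 1e-3, 1e-2)


@dataclass
class PriorSpec:
    family: str
    pi: float = 0.0                  # proportion of null-effect markers
    estimate_pi: bool = False
    v: float = 5.0
    S: float = 0.01
    lam: float = 1.0
    s2g_init: float = 1.0            # BayesR total genetic variance start
    mix_props: tuple = R_MIX_PROPS
    mix_scalars: tuple = R_MIX_SCALARS
    fix_pi: bool = False             # BayesR: keep mixture proportions fixed
    ve: float = 5.0
    Se: float = 1.0
    # validation hook: hold all variances at (S, Se, s2g_init) instead of
    # sampling them, so conjugate closed forms apply exactly
    fix_variances: bool = False

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown Bayesian family {self.family!r}")


@dataclass
class ChainConfig:
    n_iter: int = 50_000
    burn_in: int = 25_000
    thin: int = 1
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorSummary:
    effects: pd.Series               # posterior-mean effect per marker
    inclusion_prob: pd.Series
    pi_mean: float
    mix_props_mean: np.ndarray
    s2g_mean: float                  # posterior-mean total marker-explained variance
    s2e_mean: float
    beta_mean: np.ndarray
    gebv: np.ndarray                 # sum_i z_i ghat_i for the training individuals
    hyperparams: dict = field(default_factory=dict)
    traces: dict = field(default_factory=dict)
    ess: dict = field(default_factory=dict)


def make_prior(family: str, h2_guess: float, m_snps: int, var_y: float = 1.0,
               mean_2pq: float = 0.5, fix_pi: bool = False) -> PriorSpec:
    """Construct a family's prior with scales tied to an assumed heritability.

    ``S`` solves the prior mean of the per-marker variance to
    h2_guess*var_y / (m * (1-pi) * mean_2pq); the Laplace rate matches the
    same variance; BayesR's total genetic variance starts at h2_guess*var_y.
    """
    if not (0.0 < h2_guess < 1.0):
        raise ValueError("h2_guess must lie in (0, 1)")
    if family not in FAMILIES:
        raise ValueError(f"unknown Bayesian family {family!r}")
    pi = {"A": 0.0, "B": 0.95, "Bpi": 0.5, "C": 0.95, "Cpi": 0.5, "Lasso": 0.0, "R": 0.0}[family]
    estimate_pi = family in ("Bpi", "Cpi")
    v = 5.0
    vg = h2_guess * var_y
    mean_var = vg / (max(m_snps, 1) * max(1.0 - pi, 0.05) * mean_2pq)
    S = mean_var * (v - 2.0) / v
    lam = float(np.sqrt(2.0 / mean_var))
    return PriorSpec(
        family=family, pi=pi, estimate_pi=estimate_pi, v=v, S=S, lam=lam,
        s2g_init=vg, fix_pi=fix_pi, ve=5.0, Se=(1.0 - h2_guess) * var_y,
    )


@njit(cache=True)
def _sample_inv_gaussian(mu, lam):
    nu = np.random.standard_normal()
    ysq = nu * nu
    x = mu + (mu * mu * ysq) / (2.0 * lam) - (mu / (2.0 * lam)) * np.sqrt(
        4.0 * mu * lam * ysq + mu * mu * ysq * ysq
    )
    if x <= 0.0:
        x = 1e-12
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True)
def _gibbs_chain(Z, ztz, X, y, family, n_iter, burn_in, thin,
                 pi0, estimate_pi, v, S, lam, s2g0, props0, scalars,
                 fix_pi, ve, Se, fix_var, seed):
    np.random.seed(seed)
    n, m = Z.shape
    p = X.shape[1]
    xtx = np.empty(p)
    for c in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, c] * X[i, c]
        xtx[c] = s

    g = np.zeros(m)
    var_j = np.full(m, S if fix_var else v * S / max(v - 2.0, 1.0))
    beta = np.zeros(p)
    s2 = S if fix_var else v * S / max(v - 2.0, 1.0)  # shared variance (C/Cpi)
    s2g = s2g0                        # BayesR total genetic variance
    pi = pi0
    props = props0.copy()
    vary = np.var(y)
    s2e = Se if fix_var else (0.5 * vary if vary > 0 else 1.0)
    e = y.copy()

    g_sum = np.zeros(m)
    incl_sum = np.zeros(m)
    beta_sum = np.zeros(p)
    pi_sum = 0.0
    props_sum = np.zeros(4)
    s2g_sum = 0.0
    s2e_sum = 0.0
    n_keep = 0
    n_samples = (n_iter - burn_in + thin - 1) // thin
    s2e_trace = np.zeros(n_samples)
    s2g_trace = np.zeros(n_samples)

    comp = np.zeros(m, dtype=np.int64)  # BayesR component assignment
    logp = np.empty(4)

    for it in range(n_iter):
        # fixed effects, flat prior, single-site
        for c in range(p):
            old = beta[c]
            rhs = 0.0
            for i in range(n):
                rhs += X[i, c] * (e[i] + X[i, c] * old)
            mean = rhs / xtx[c]
            new = mean + np.random.standard_normal() * np.sqrt(s2e / xtx[c])
            diff = new - old
            for i in range(n):
                e[i] -= X[i, c] * diff
            beta[c] = new

        n_in = 0
        ssq_scaled = 0.0   # BayesR: sum g^2 / c_k ; BayesC: sum g^2
        counts = np.zeros(4)
        counts[0] = 0.0
        for j in range(m):
            zz = ztz[j]
            if zz <= 0.0:
                continue
            old = g[j]
            if old != 0.0:
                for i in range(n):
                    e[i] += Z[i, j] * old
            rhs = 0.0
            for i in range(n):
                rhs += Z[i, j] * e[i]

            new = 0.0
            if family == 0 or family == 5:  # BayesA / BayesLasso: always in
                vj = var_j[j]
                C = zz + s2e / vj
                mean = rhs / C
                new = mean + np.random.standard_normal() * np.sqrt(s2e / C)
                if not fix_var:
                    if family == 0:
                        var_j[j] = (v * S + new * new) / np.random.chisquare(v + 1.0)
                    else:
                        ag = abs(new)
                        if ag < 1e-10:
                            var_j[j] = -2.0 / (lam * lam) * np.log(np.random.random() + 1e-300)
                        else:
                            var_j[j] = 1.0 / _sample_inv_gaussian(lam / ag, lam * lam)
                n_in += 1
            elif family == 6:  # BayesR
                v0 = zz * s2e
                logp[0] = np.log(props[0] + 1e-300) - 0.5 * np.log(v0) - rhs * rhs / (2.0 * v0)
                for k in range(1, 4):
                    vk = zz * zz * scalars[k] * s2g + v0
                    logp[k] = np.log(props[k] + 1e-300) - 0.5 * np.log(vk) - rhs * rhs / (2.0 * vk)
                mx = logp[0]
                for k in range(1, 4):
                    if logp[k] > mx:
                        mx = logp[k]
                tot = 0.0
                for k in range(4):
                    logp[k] = np.exp(logp[k] - mx)
                    tot += logp[k]
                u = np.random.random() * tot
                k_sel = 3
                acc = 0.0
                for k in range(4):
                    acc += logp[k]
                    if u <= acc:
                        k_sel = k
                        break
                comp[j] = k_sel
                counts[k_sel] += 1.0
                if k_sel > 0:
                    vj = scalars[k_sel] * s2g
                    C = zz + s2e / vj
                    mean = rhs / C
                    new = mean + np.random.standard_normal() * np.sqrt(s2e / C)
                    ssq_scaled += new * new / scalars[k_sel]
                    n_in += 1
            else:  # BayesB/Bpi (per-marker var) and BayesC/Cpi (shared var)
                vj = var_j[j] if (family == 1 or family == 2) else s2
                v0 = zz * s2e
                v1 = zz * zz * vj + v0
                log_bf = 0.5 * (np.log(v0) - np.log(v1) + rhs * rhs * (1.0 / v0 - 1.0 / v1))
                log_odds = np.log((1.0 - pi) + 1e-300) - np.log(pi + 1e-300) + log_bf
                p_in = 1.0 / (1.0 + np.exp(-log_odds))
                if np.random.random() < p_in:
                    C = zz + s2e / vj
                    mean = rhs / C
                    new = mean + np.random.standard_normal() * np.sqrt(s2e / C)
                    n_in += 1
                    if family == 1 or family == 2:
                        if not fix_var:
                            var_j[j] = (v * S + new * new) / np.random.chisquare(v + 1.0)
                    else:
                        ssq_scaled += new * new
                else:
                    new = 0.0
                    if (family == 1 or family == 2) and not fix_var:
                        var_j[j] = v * S / np.random.chisquare(v)

            g[j] = new
            if new != 0.0:
                for i in range(n):
                    e[i] -= Z[i, j] * new

        # shared/global variance updates
        if (family == 3 or family == 4) and not fix_var:
            s2 = (v * S + ssq_scaled) / np.random.chisquare(v + n_in)
        if family == 6 and not fix_var:
            s2g = (v * S + ssq_scaled) / np.random.chisquare(v + n_in)
            if not fix_pi:
                tot = 0.0
                for k in range(4):
                    props[k] = np.random.gamma(counts[k] + 1.0, 1.0)
                    tot += props[k]
                for k in range(4):
                    props[k] /= tot
        if estimate_pi:
            pi = np.random.beta(m - n_in + 1.0, n_in + 1.0)

        if not fix_var:
            sse = 0.0
            for i in range(n):
                sse += e[i] * e[i]
            s2e = (sse + ve * Se) / np.random.chisquare(n + ve)

        if it >= burn_in and (it - burn_in) % thin == 0:
            g_sum += g
            for j in range(m):
                if g[j] != 0.0:
                    incl_sum[j] += 1.0
            beta_sum += beta
            pi_sum += pi
            props_sum += props
            if family == 6:
                s2g_trace[n_keep] = s2g
            else:
                tot_g = 0.0
                for j in range(m):
                    if family == 3 or family == 4:
                        if g[j] != 0.0:
                            tot_g += s2
                    else:
                        tot_g += var_j[j] if g[j] != 0.0 or family == 0 or family == 5 else 0.0
                s2g_trace[n_keep] = tot_g / max(m, 1)
            s2g_sum += s2g_trace[n_keep]
            s2e_trace[n_keep] = s2e
            s2e_sum += s2e
            n_keep += 1

    inv = 1.0 / max(n_keep, 1)
    return (g_sum * inv, incl_sum * inv, beta_sum * inv, pi_sum * inv,
            props_sum * inv, s2g_sum * inv, s2e_sum * inv, s2e_trace, s2g_trace)


def _autocorr_ess(x: np.ndarray) -> float:
    """Initial-positive-sequence effective sample size of a scalar trace."""
    x = np.asarray(x, float)
    n = len(x)
    if n < 10 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * xc.var())
    s = 0.0
    for k in range(1, n // 2):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(n / (1.0 + 2.0 * s))


def run_chain(panel, phenotype, fixed_covariates, prior: PriorSpec,
              chain: ChainConfig) -> PosteriorSummary:
    """Run one Gibbs chain on a genotype panel and return posterior means.

    ``panel`` may be a :class:`~gpsel.panel.GenotypePanel` or a raw dosage
    matrix; dosages are centered at twice the allele frequency internally.
    NaN phenotypes drop the individual from the chain.
    """
    from .panel import GenotypePanel

    if isinstance(panel, GenotypePanel):
        dos = panel.dosages
        snp_ids = panel.snp_map["id"].to_numpy()
    else:
        dos = np.asarray(panel, float)
        snp_ids = np.array([f"m{j}" for j in range(dos.shape[1])])
    y = np.asarray(phenotype, float).ravel()
    obs = np.isfinite(y)
    dos = dos[obs]
    with np.errstate(invalid="ignore"):
        p = np.nanmean(dos, axis=0) / 2.0
    p = np.where(np.isnan(p), 0.0, p)
    Z = np.where(np.isnan(dos), 2.0 * p, dos) - 2.0 * p
    X = np.ones((obs.sum(), 1))
    if fixed_covariates is not None and np.asarray(fixed_covariates).size:
        X = np.column_stack([X, np.asarray(fixed_covariates, float)[obs]])
    ztz = np.einsum("ij,ij->j", Z, Z)

    (g_mean, pip, beta_mean, pi_mean, props_mean, s2g_mean, s2e_mean,
     s2e_trace, s2g_trace) = _gibbs_chain(
        np.ascontiguousarray(Z), ztz, np.ascontiguousarray(X),
        np.ascontiguousarray(y[obs]),
        _FAMILY_CODE[prior.family], chain.n_iter, chain.burn_in, chain.thin,
        float(prior.pi), prior.estimate_pi, float(prior.v), float(prior.S),
        float(prior.lam), float(prior.s2g_init),
        np.asarray(prior.mix_props, float), np.asarray(prior.mix_scalars, float),
        prior.fix_pi, float(prior.ve), float(prior.Se), prior.fix_variances,
        int(chain.seed) % (2**31 - 1),
    )
    return PosteriorSummary(
        effects=pd.Series(g_mean, index=snp_ids),
        inclusion_prob=pd.Series(pip, index=snp_ids),
        pi_mean=float(pi_mean),
        mix_props_mean=props_mean,
        s2g_mean=float(s2g_mean),
        s2e_mean=float(s2e_mean),
        beta_mean=beta_mean,
        gebv=Z @ g_mean,
        hyperparams={"v": prior.v, "S": prior.S, "lambda": prior.lam,
                     "pi0": prior.pi, "ve": prior.ve, "Se": prior.Se},
        traces={"s2e": s2e_trace, "s2g": s2g_trace},
        ess={"s2e": _autocorr_ess(s2e_trace), "s2g": _autocorr_ess(s2g_trace)},
    )


def gebv_from_effects(panel, summary: PosteriorSummary, freqs: np.ndarray | None = None) -> np.ndarray:
    """Accumulate GEBV = sum_i z_i ghat_i over the panel's (centered) dosages."""
    from .panel import GenotypePanel

    if isinstance(panel, GenotypePanel):
        ids = list(panel.snp_map["id"])
        dos = panel.dosages
    else:
        dos = np.asarray(panel, float)
        ids = [f"m{j}" for j in range(dos.shape[1])]
    if list(summary.effects.index) != ids:
        missing = set(summary.effects.index) - set(ids)
        if missing:
            raise ValueError(f"panel lacks markers with stored effects: {sorted(missing)[:5]}")
        dosdf_idx = [ids.index(s) for s in summary.effects.index]
        dos = dos[:, dosdf_idx]
    if freqs is None:
        with np.errstate(invalid="ignore"):
            freqs = np.nanmean(dos, axis=0) / 2.0
        freqs = np.where(np.isnan(freqs), 0.0, freqs)
    Z = np.where(np.isnan(dos), 2.0 * freqs, dos) - 2.0 * freqs
    return Z @ summary.effects.to_numpy()


class BayesAlphabet(BaseEstimator, RegressorMixin):
    """sklearn-style wrapper running one Bayesian-alphabet family.

    Single-trait only (the study runs the Bayesian models per trait).
    NaN entries of ``y`` are excluded from the chain but still receive
    breeding values in ``gebv_`` through their marker genotypes.
    """

    def __init__(self, family: str = "C", n_iter: int = 50_000, burn_in: int = 25_000,
                 thin: int = 1, seed: int = 0, h2_guess: float = 0.5,
                 pi: float | None = None, fix_pi: bool = False):
        self.family = family
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.h2_guess = h2_guess
        self.pi = pi
        self.fix_pi = fix_pi

    # run_cv duck-types on this attribute
    n_traits = 1

    def fit(self, X, y, covariates=None):
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        if np.asarray(y).ndim > 1:
            raise ValueError("Bayesian models are single-trait")
        obs = np.isfinite(y)
        dos_train = X[obs]
        with np.errstate(invalid="ignore"):
            p = np.nanmean(dos_train, axis=0) / 2.0
        self.freqs_ = np.where(np.isnan(p), 0.0, p)
        mean_2pq = float(np.mean(2.0 * self.freqs_ * (1.0 - self.freqs_)))
        prior = make_prior(self.family, self.h2_guess, X.shape[1],
                           var_y=float(np.nanvar(y)), mean_2pq=max(mean_2pq, 1e-6),
                           fix_pi=self.fix_pi)
        if self.pi is not None:
            prior.pi = float(self.pi)
            prior.estimate_pi = False
        chain = ChainConfig(n_iter=self.n_iter, burn_in=self.burn_in,
                            thin=self.thin, seed=self.seed)
        cov = np.asarray(covariates, float)[obs] if covariates is not None and np.asarray(covariates).size else None
        summary = run_chain(dos_train, y[obs], cov, prior, chain)
        self.summary_ = summary
        self.effects_ = summary.effects.to_numpy()
        self.pi_ = summary.pi_mean
        self.varcomp_ = {"s2g": summary.s2g_mean, "s2e": summary.s2e_mean}
        self.gebv_ = self.predict(X)
        self.converged_ = True
        return self

    def predict(self, X):
        X = np.asarray(X, float)
        Z = np.where(np.isnan(X), 2.0 * self.freqs_, X) - 2.0 * self.freqs_
        return Z @ self.effects_
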