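"""Synthetic genotype and two-trait phenotype generator.

The generator emulates the statistical structure of a small pig carcass
breeding population genotyped at two densities: a dense sequence-level
("wgs") panel with within-chromosome linkage disequilibrium, a sparse,
evenly spaced "chip" subset of it, and an imputation-error model that
perturbs non-chip dosages and assigns each SNP an imputation-accuracy
score (DR2) negatively associated with its realised error rate.

Two genetically correlated traits are simulated on top of the dense
panel. Trait 1 is oligogenic: a handful of large-effect QTL contribute a
fixed share of its genetic variance over a polygenic background. Trait 2
is purely polygenic. Their default heritabilities are 0.323 and 0.195
with a genetic correlation of 0.636 — the published estimates for rib
number and carcass length in the Suhuai population the study design is
modelled on. Fixed effects mirror the study's structure: trait 1 carries
sex and slaughter-batch effects; trait 2 carries a carcass-weight (CW)
covariate and a CW record-type effect, where record type is determined by
slaughter batch (batches 1-4 vs batch 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import centered_dosages
from .panel import GenotypePanel


class SimConfigError(ValueError):
    """Raised for degenerate simulation configurations."""


@dataclass
class SimConfig:
    """Desk-scale genotype-panel configuration.

    Defaults give 600 individuals on 5 chromosomes x 2,000 SNPs with a 5%
    chip density — a deliberately small stand-in for the study's
    11-million-SNP imputed panel. Individuals are offspring of a closed
    sib-family design (``dams_per_sire`` dams per sire, ``litter_size``
    offspring per dam), the mating structure of a small breeding herd;
    without such relatedness, variance components would be nearly
    unidentifiable at this sample size.
    """

    n_individuals: int = 600
    n_chromosomes: int = 5
    snps_per_chromosome: int = 2000
    chip_fraction: float = 0.05
    ld_decay: float = 0.9          # latent AR(1) correlation between adjacent SNPs
    maf_range: tuple = (0.05, 0.5)
    litter_size: int = 6
    dams_per_sire: int = 4
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 2:
            raise SimConfigError("need at least 2 individuals")
        if self.n_chromosomes < 1 or self.snps_per_chromosome < 1:
            raise SimConfigError("need at least one chromosome and one SNP")
        if not (0.0 < self.chip_fraction <= 1.0):
            raise SimConfigError("chip_fraction must lie in (0, 1]")
        total = self.n_chromosomes * self.snps_per_chromosome
        if self.chip_fraction * total < 50:
            raise SimConfigError("chip subset would have fewer than 50 SNPs")
        if not (0.0 <= self.ld_decay < 1.0):
            raise SimConfigError("ld_decay must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise SimConfigError("maf_range must satisfy 0 < low <= high <= 0.5")


@dataclass
class TraitArchitecture:
    """Genetic architecture of the two simulated traits.

    ``h2`` and ``rg`` default to the published Suhuai estimates. Large-QTL
    effects are uncorrelated between traits, so the achievable ``rg`` is
    bounded by the geometric mean of the polygenic variance shares; the
    closed-form cross-trait effect correlation is solved from that bound.
    """

    h2: tuple = (0.323, 0.195)
    rg: float = 0.636
    n_large_qtl: tuple = (5, 0)
    large_qtl_variance_share: tuple = (0.5, 0.0)
    n_polygenes: int = 1000
    qtl_min_maf: float = 0.15
    residual_correlation: float = 0.2
    fixed_effect_spec: dict = field(
        default_factory=lambda: {
            "sex_effect": 0.5,
            "n_batches": 5,
            "batch_effect_sd": 0.5,
            "cw_mean": 90.0,
            "cw_batch_step": 2.0,
            "cw_sd": 5.0,
            "cw_beta": 0.05,
            "cw_type_effect": 0.8,
        }
    )

    def validate(self) -> None:
        for h in self.h2:
            if not (0.0 <= h < 1.0):
                raise SimConfigError("heritabilities must lie in [0, 1)")
        if not (-1.0 <= self.rg <= 1.0):
            raise SimConfigError("rg must lie in [-1, 1]")
        for s in self.large_qtl_variance_share:
            if not (0.0 <= s <= 1.0):
                raise SimConfigError("QTL variance shares must lie in [0, 1]")
        poly = np.sqrt((1 - self.large_qtl_variance_share[0]) * (1 - self.large_qtl_variance_share[1]))
        if poly == 0.0 and self.rg != 0.0:
            raise SimConfigError("non-zero rg impossible without polygenic variance in both traits")
        if poly > 0 and abs(self.rg) > poly + 1e-12:
            raise SimConfigError(
                f"rg={self.rg} unreachable: uncorrelated large-QTL components cap |rg| at {poly:.3f}"
            )


@dataclass
class TrueEffects:
    """Ground truth of a simulated pair of traits (for parameter-recovery tests)."""

    effects: pd.DataFrame        # index snp id, columns trait1/trait2 additive effects
    tbv: np.ndarray              # (n, 2) true breeding values
    realized_h2: tuple
    realized_rg: float
    qtl_ids: tuple               # (trait-1 QTL ids, trait-2 QTL ids)


def _ar1_haplotypes(rng, n_hap, p, rho):
    """Haplotype alleles from a stationary AR(1) latent Gaussian."""
    m = len(p)
    thresh = stats.norm.ppf(p)
    lat = np.empty((n_hap, m))
    lat[:, 0] = rng.standard_normal(n_hap)
    scale = np.sqrt(1.0 - rho * rho)
    if m > 1:
        innov = rng.standard_normal((n_hap, m - 1))
        for j in range(1, m):
            lat[:, j] = rho * lat[:, j - 1] + scale * innov[:, j - 1]
    return (lat < thresh).astype(np.int8)


def _gametes(rng, hap0, hap1):
    """Recombined gametes, one row per offspring; Poisson(1) crossovers.

    ``hap0``/``hap1`` are the (n_off, m) parental haplotype rows already
    matched to offspring.
    """
    n_off, m = hap0.shape
    out = np.empty((n_off, m), dtype=np.int8)
    for i in range(n_off):
        cur = rng.integers(0, 2)
        k = rng.poisson(1.0)
        cuts = np.sort(rng.integers(1, m, size=k)) if (k > 0 and m > 1) else np.array([], int)
        seg_start = 0
        pair = (hap0[i], hap1[i])
        for cut in list(cuts) + [m]:
            out[i, seg_start:cut] = pair[cur][seg_start:cut]
            cur = 1 - cur
            seg_start = cut
    return out


def simulate_genotypes(config: SimConfig) -> GenotypePanel:
    """Simulate a dense dosage panel with AR(1)-latent LD and sib families.

    Founder haplotypes follow a stationary AR(1) latent Gaussian along
    each chromosome, thresholded at the per-SNP allele-frequency
    quantile. The sampled individuals are offspring of a balanced
    sire/dam mating design; each offspring receives one recombined gamete
    (Poisson(1) crossovers per chromosome) from each parent, giving the
    full-/half-sib relatedness of a closed breeding herd. Chromosomes are
    independent.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, rho = config.n_individuals, config.ld_decay
    n_dams = max(2, int(np.ceil(n / config.litter_size)))
    n_sires = max(2, int(np.ceil(n_dams / config.dams_per_sire)))
    n_par = n_sires + n_dams
    dam_sire = rng.integers(0, n_sires, size=n_dams)
    off_dam = np.arange(n) % n_dams
    off_sire = dam_sire[off_dam]
    blocks, maps = [], []
    for c in range(1, config.n_chromosomes + 1):
        m = config.snps_per_chromosome
        p = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
        par = _ar1_haplotypes(rng, 2 * n_par, p, rho)
        sire_idx = off_sire
        dam_idx = n_sires + off_dam
        pat = _gametes(rng, par[2 * sire_idx], par[2 * sire_idx + 1])
        mat = _gametes(rng, par[2 * dam_idx], par[2 * dam_idx + 1])
        dosage = pat + mat
        blocks.append(dosage.astype(float))
        pos = np.cumsum(rng.integers(100, 5000, size=m))
        maps.append(
            pd.DataFrame(
                {
                    "id": [f"snp{c}_{j}" for j in range(m)],
                    "chrom": str(c),
                    "pos": pos,
                    "a1": "B",
                    "a2": "A",
                    "dr2": 1.0,
                }
            )
        )
    return GenotypePanel(
        ids=np.array([f"ind{i:04d}" for i in range(n)], dtype=object),
        dosages=np.concatenate(blocks, axis=1),
        snp_map=pd.concat(maps, ignore_index=True),
        tag="wgs",
    )


def _scaled_component(Z: np.ndarray, raw_effects: np.ndarray, target_var: float):
    """Scale an effect vector so its TBV component has exactly target_var."""
    comp = Z @ raw_effects
    v = comp.var()
    if target_var <= 0 or v <= 0:
        return np.zeros_like(raw_effects), np.zeros(Z.shape[0])
    s = np.sqrt(target_var / v)
    return raw_effects * s, comp * s


def simulate_traits(
    panel: GenotypePanel, arch: TraitArchitecture, seed: int = 0
) -> tuple[pd.DataFrame, TrueEffects]:
    """Simulate two correlated traits with oligogenic / polygenic architectures.

    Genetic variance is fixed at ``h2`` per trait on a unit phenotypic
    scale; residual variance follows from the realised TBV variance so the
    realised heritability tracks its target. Returns the phenotype table
    (id, trait1, trait2, sex, batch, cw, cw_type) and the ground truth.
    """
    arch.validate()
    rng = np.random.default_rng(seed)
    n, m = panel.n_individuals, panel.n_snps
    Z, _ = centered_dosages(panel)
    maf = panel.maf()
    snp_ids = panel.snp_ids

    shares = arch.large_qtl_variance_share
    poly_share = (1 - shares[0], 1 - shares[1])
    denom = np.sqrt(poly_share[0] * poly_share[1])
    rho = arch.rg / denom if denom > 0 else 0.0

    # candidate pools: QTL drawn among common SNPs so large effects are taggable
    common = np.flatnonzero(maf >= arch.qtl_min_maf)
    pool = common if len(common) >= sum(arch.n_large_qtl) else np.arange(m)
    qtl_idx = []
    taken: set = set()
    for t in range(2):
        k = arch.n_large_qtl[t]
        avail = np.setdiff1d(pool, np.fromiter(taken, dtype=int, count=len(taken)))
        pick = rng.choice(avail, size=k, replace=False) if k > 0 else np.array([], dtype=int)
        taken.update(pick.tolist())
        qtl_idx.append(np.sort(pick))

    # polygenic background sits at loci distinct from the large QTL
    non_qtl = np.setdiff1d(np.arange(m), np.concatenate(qtl_idx) if taken else np.array([], int))
    n_poly = min(arch.n_polygenes, len(non_qtl))
    poly_idx = np.sort(rng.choice(non_qtl, size=n_poly, replace=False))

    # polygenic effect pairs from a bivariate normal with correlation rho
    L = np.array([[1.0, 0.0], [rho, np.sqrt(max(0.0, 1.0 - rho * rho))]])
    poly_raw = rng.standard_normal((n_poly, 2)) @ L.T

    effects = np.zeros((m, 2))
    tbv = np.zeros((n, 2))
    genvar = arch.h2  # phenotypic scale fixed near 1
    for t in range(2):
        e_poly, c_poly = _scaled_component(
            Z[:, poly_idx], poly_raw[:, t], poly_share[t] * genvar[t]
        )
        effects[poly_idx, t] += e_poly
        tbv[:, t] += c_poly
        if len(qtl_idx[t]) > 0:
            raw_q = rng.standard_normal(len(qtl_idx[t]))
            e_q, c_q = _scaled_component(Z[:, qtl_idx[t]], raw_q, shares[t] * genvar[t])
            effects[qtl_idx[t], t] += e_q
            tbv[:, t] += c_q

    # fixed effects and covariates
    fe = arch.fixed_effect_spec
    sex = rng.integers(0, 2, size=n)
    n_batches = fe["n_batches"]
    batch = rng.integers(1, n_batches + 1, size=n)
    batch_effects = rng.normal(0.0, fe["batch_effect_sd"], size=n_batches)
    cw = rng.normal(fe["cw_mean"] + fe["cw_batch_step"] * (batch - 1), fe["cw_sd"])
    cw_type = np.where(batch <= min(4, n_batches - 1), 1, 2)

    # residuals: bivariate normal with correlation residual_correlation
    var_t = [tbv[:, t].var() for t in range(2)]
    sd_e = np.empty(2)
    for t in range(2):
        sd_e[t] = np.sqrt(var_t[t] * (1 - arch.h2[t]) / arch.h2[t]) if arch.h2[t] > 0 else 1.0
    re = arch.residual_correlation
    Le = np.array([[1.0, 0.0], [re, np.sqrt(1.0 - re * re)]])
    resid = rng.standard_normal((n, 2)) @ Le.T * sd_e

    y1 = 10.0 + fe["sex_effect"] * sex + batch_effects[batch - 1] + tbv[:, 0] + resid[:, 0]
    y2 = (
        20.0
        + fe["cw_type_effect"] * (cw_type - 1)
        + fe["cw_beta"] * (cw - cw.mean())
        + tbv[:, 1]
        + resid[:, 1]
    )

    realized_h2 = tuple(
        float(var_t[t] / (var_t[t] + resid[:, t].var())) if var_t[t] > 0 else 0.0
        for t in range(2)
    )
    if var_t[0] > 0 and var_t[1] > 0:
        realized_rg = float(np.corrcoef(tbv[:, 0], tbv[:, 1])[0, 1])
    else:
        realized_rg = 0.0

    pheno = pd.DataFrame(
        {
            "id": panel.ids,
            "trait1": y1,
            "trait2": y2,
            "sex": sex,
            "batch": batch,
            "cw": cw,
            "cw_type": cw_type,
        }
    )
    truth = TrueEffects(
        effects=pd.DataFrame(effects, index=snp_ids, columns=["trait1", "trait2"]),
        tbv=tbv,
        realized_h2=realized_h2,
        realized_rg=realized_rg,
        qtl_ids=(list(snp_ids[qtl_idx[0]]), list(snp_ids[qtl_idx[1]])),
    )
    return pheno, truth


def make_chip_subset(panel: GenotypePanel, chip_fraction: float) -> GenotypePanel:
    """Evenly spaced per-chromosome SNP subset, tagged ``chip``.

    SNP ids are preserved so the chip panel is an identifiable subset of
    the dense panel.
    """
    if not (0.0 < chip_fraction <= 1.0):
        raise SimConfigError("chip_fraction must lie in (0, 1]")
    keep = []
    chrom = panel.snp_map["chrom"].to_numpy()
    for c in pd.unique(chrom):
        cols = np.flatnonzero(chrom == c)
        k = max(1, int(round(chip_fraction * len(cols))))
        sel = np.unique(np.round(np.linspace(0, len(cols) - 1, k)).astype(int))
        keep.extend(cols[sel].tolist())
    sub = panel.subset_snps(panel.snp_ids[np.array(sorted(keep))], tag="chip")
    sub.snp_map["dr2"] = 1.0  # chip genotypes are observed, not imputed
    return sub


def inject_imputation_error(
    panel: GenotypePanel,
    error_rate: float,
    dr2_params: tuple = (5.0, 1.0),
    seed: int = 0,
    chip_ids=None,
) -> GenotypePanel:
    """Perturb non-chip dosages and assign DR2 imputation-accuracy scores.

    Each non-chip SNP j receives an error probability e_j with mean
    ``error_rate``; erroneous dosages flip to a random *other* value in
    {0,1,2}. DR2_j = 1 - e_j * Beta(dr2_params), so DR2 is noisily but
    monotonically decreasing in the SNP's true error rate. Chip SNPs are
    exempt and keep DR2 = 1.
    """
    if not (0.0 <= error_rate <= 1.0):
        raise SimConfigError("error_rate must lie in [0, 1]")
    out = panel.copy()
    if error_rate == 0.0:
        out.snp_map["dr2"] = 1.0
        return out
    rng = np.random.default_rng(seed)
    n, m = panel.n_individuals, panel.n_snps
    chip_mask = (
        out.snp_map["id"].isin(set(chip_ids)).to_numpy() if chip_ids is not None else np.zeros(m, bool)
    )
    e = np.minimum(1.0, error_rate * 2.0 * rng.beta(2.0, 2.0, size=m))
    e[chip_mask] = 0.0
    dr2 = 1.0 - e * rng.beta(dr2_params[0], dr2_params[1], size=m)
    dr2[chip_mask] = 1.0
    flip = rng.random((n, m)) < e[None, :]
    if flip.any():
        dos = out.dosages
        shift = rng.integers(1, 3, size=flip.sum())  # move to one of the two other values
        rows, cols = np.nonzero(flip)
        ok = ~np.isnan(dos[rows, cols])
        dos[rows[ok], cols[ok]] = (dos[rows[ok], cols[ok]] + shift[ok]) % 3
    out.snp_map["dr2"] = dr2
    return out
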