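# gpsel — genomic prediction with GWAS-preselected markers

`gpsel` is a research pipeline for a question that comes up constantly in
livestock breeding with small reference populations: **does integrating
GWAS-significant markers into genomic prediction models raise accuracy
over plain GBLUP**, and for which genetic architectures? It implements
the complete study design around that question for two genetically
correlated carcass traits — one oligogenic (a few large-effect QTL, like
rib number), one polygenic (like carcass length) — including a synthetic
breeding-population generator, so every stage runs and is testable
without any external data.

## What is implemented

**Prediction models** (sklearn-style estimators: `fit(X, y, covariates=...)`,
`predict`, fitted attributes with trailing underscores; `y` entries set to
NaN are unphenotyped individuals that still receive breeding values):

- **GBLUP** — y = Xa + Zg + e, g ~ N(0, G·σ²ᴀ) with the VanRaden
  relationship matrix G = ZZ′ / 2Σpⱼ(1−pⱼ) over centered dosages;
  `n_traits=2` gives the multi-trait form with full 2×2 genetic and
  residual covariance (σ²ᴀ₁, σᴀ₁ᴀ₂, σ²ᴀ₂; σ²ₑ₁, σₑ₁ₑ₂, σ²ₑ₂).
- **MABLUP** — y = Xa + Ms + Zg + e: the most significant GWAS SNP enters
  as a fixed effect; GEBV = Mŝ + Zĝ.
- **OneBLUP** — GBLUP whose single G is built on chip markers merged with
  the GWAS-significant sequence markers (overlaps deduplicated).
- **MultiBLUP** — y = Xa + Z₁g₁ + Z₂g₂ + e with two relationship matrices
  over disjoint marker groups: GWAS-significant vs the rest.
- **Bayesian alphabet** — BayesA/B/Bpi/C/Cpi/Lasso/R single-site Gibbs
  samplers over marker effects (numba-compiled, bit-reproducible under a
  seed); GEBV = Σᵢ zᵢĝᵢ from posterior-mean effects.

**Around the models**: PLINK/VCF panel I/O; MAF ≥ 0.05 and DR² ≥ 0.9
quality control; PLINK-style `--indep-pairwise 50 10 0.5` LD pruning;
mixed-linear-model GWAS with leave-one-chromosome-out kinship and the 1/N
significance threshold (N = independent SNPs for sequence panels);
AI-REML / eigendecomposition REML variance components; 10-fold
cross-validation with training-fold-only marker selection; accuracy
(Pearson r between GEBV and the fixed-effect-corrected phenotype), bias
(slope of corrected phenotype on GEBV), Tukey-HSD model comparison and
t-tests of bias against 1; a YAML study config and a `gs` command line.

**Synthetic data**: a closed sib-family herd (AR(1)-LD founder
haplotypes, balanced sire/dam matings, recombined gametes) genotyped at a
dense "sequence" panel with an evenly spaced chip subset; imputation
error injected per SNP with DR² scores that track the error rate; two
traits with default heritabilities 0.323 and 0.195 and genetic
correlation 0.636, trait 1 carrying large-effect QTL over a polygenic
background, trait 2 purely polygenic.

## Worked example

```python
import numpy as np
from gpsel import *

cfg = SimConfig(n_individuals=400, n_chromosomes=3, snps_per_chromosome=500,
                chip_fraction=0.1, seed=7)
wgs = simulate_genotypes(cfg)
arch = TraitArchitecture()          # h2 = (0.323, 0.195), rg = 0.636
pheno, truth = simulate_traits(wgs, arch, seed=8)
chip = make_chip_subset(wgs, 0.1)
print(f"panel: {wgs.n_individuals} pigs x {wgs.n_snps} sequence SNPs, "
      f"{chip.n_snps} chip SNPs")
print(f"realized h2: {truth.realized_h2[0]:.3f} / {truth.realized_h2[1]:.3f}, "
      f"realized rg: {truth.realized_rg:.3f}")

from gpsel.evaluation import StudyData
data = StudyData(chip=chip, wgs=wgs, pheno=pheno)
folds = make_folds(pheno["id"].to_numpy(), k=10, seed=1)
report = run_cv([("ST-GBLUP", 3), ("ST-MABLUP", 3)], data, folds,
                target_trait=0, seed=1)
compare_models(report)
print(report.aggregates[["model", "accuracy_mean", "accuracy_se",
                         "bias_mean"]].round(3).to_string(index=False))
pair = report.tukey["trait1"]["pairs"]["ST-GBLUP:d3 vs ST-MABLUP:d3"]
print(f"Tukey HSD p (GBLUP vs MABLUP): {pair:.4f}")
```

prints

```
panel: 400 pigs x 1500 sequence SNPs, 150 chip SNPs
realized h2: 0.369 / 0.201, realized rg: 0.632
    model  accuracy_mean  accuracy_se  bias_mean
 ST-GBLUP          0.372        0.027      0.943
ST-MABLUP          0.468        0.032      0.966
Tukey HSD p (GBLUP vs MABLUP): 0.0348
```

Reading this: the generator hit its heritability and genetic-correlation
targets on this draw; across 10 folds, adding the top GWAS SNP of each
training fold as a fixed effect (MABLUP) lifted the oligogenic trait's
prediction accuracy from 0.372 to 0.468 — significant by Tukey's HSD —
while both models' dispersion slopes sit near the unbiased value of 1.

Studies can also be driven from a YAML config:

```bash
gs cv study.yaml --out study_out    # simulate -> QC -> GWAS/fold -> fits -> report
gs gwas wgs.vcf phenotypes.tsv assoc.tsv --trait 1
gs prune wgs.vcf kept.txt --window 50 --step 10 --r2 0.5
```

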