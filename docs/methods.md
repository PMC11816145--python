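# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `gpsel`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The study design

The package reproduces, end to end, a genomic-prediction study layout
common in pig breeding: a few hundred phenotyped and genotyped animals
from a closed herd; a SNP chip plus an imputed sequence-density panel
with per-SNP imputation accuracy (DR²); two genetically correlated
carcass traits, one driven by a handful of large-effect QTL (rib-number
-like, h² ≈ 0.32) and one polygenic (carcass-length-like, h² ≈ 0.20,
genetic correlation ≈ 0.64); and fifteen prediction models — eight
BLUP-alphabet variants and seven Bayesian-alphabet samplers — compared by
10-fold cross-validation on prediction accuracy and dispersion bias.

Three marker datasets feed the models: (1) chip, (2) chip merged with
the GWAS-significant sequence SNPs, (3) the full sequence panel. The
legal (model, dataset) grid is encoded in `gpsel.blup.TABLE1`:
GBLUP/MABLUP on 1 and 3; OneBLUP on 2; MultiBLUP on 2 and 3; the
Bayesian families on 1 and 2.

## Synthetic population

`simulate_genotypes` builds founder haplotypes from a stationary AR(1)
latent Gaussian along each chromosome (parameter `ld_decay`, default
0.9), thresholded at each SNP's allele-frequency quantile (frequencies
uniform on `maf_range`, default (0.05, 0.5)). The sampled individuals
are offspring of a balanced sire/dam design (`litter_size` 6 offspring
per dam, `dams_per_sire` 4), each receiving one recombined gamete
(Poisson(1) crossovers per chromosome) from each parent.

The family structure is essential, not decorative: with a few hundred
*unrelated* individuals, the genomic relationship matrix has almost no
off-diagonal variance and REML cannot separate genetic from residual
(co)variance — in pilots the genetic-correlation estimate collapsed to
the +1 boundary. Full- and half-sib families are what identify variance
components at this scale, exactly as in a real breeding herd slaughtered
in batches.

`simulate_traits` draws trait-1 effects as `n_large_qtl` large QTL
(sampled among SNPs with MAF ≥ 0.15, so "large-effect genes" are
taggable) scaled to `large_qtl_variance_share` of the genetic variance
(default 0.5), plus a polygenic background at 1,000 distinct loci;
trait 2 is purely polygenic. Polygenic effect pairs come from a
bivariate normal whose correlation ρ is solved in closed form so that
the total TBV correlation, including the uncorrelated QTL component,
hits the target r_g: ρ = r_g / √(poly-share₁ · poly-share₂). Because the
QTL components are uncorrelated across traits, |r_g| is capped at that
geometric mean — with the default QTL share of 0.5, r_g = 0.636 is
attainable (cap ≈ 0.71); configurations outside the cap raise a
validation error. Residual variance is set from the realized TBV
variance so the realized heritability tracks its target; residual
cross-trait correlation defaults to 0.2.

Fixed effects mirror the study design: trait 1 carries sex and
slaughter-batch effects; trait 2 carries a carcass-weight (CW) covariate
and a CW record-type effect, with record type determined by slaughter
batch (batches 1–4 vs batch 5). The corrected phenotype for trait 2 is
computed per record-type group (sex + batch + CW within each group),
matching how such traits are pre-adjusted in practice.

`make_chip_subset` takes an evenly spaced subset per chromosome (default
5% of SNPs — the chip density is a free parameter of the design; real
chip-vs-sequence ratios are far more extreme). `inject_imputation_error`
gives each non-chip SNP an error probability e_j = error_rate · min(2B,1)
with B ~ Beta(2,2) (so the mean equals `error_rate`, default 0.03),
flips erroneous dosages to a random other value, and assigns
DR²_j = 1 − e_j·Beta(5,1) — noisily but monotonically decreasing in the
true error rate, with DR² ≡ 1 at zero error and for chip SNPs.

## Mixed models and REML

All relationship matrices are VanRaden method 1, G = ZZ′/2Σp(1−p), with
allele frequencies from the panel itself, monomorphic markers excluded,
missing dosages mean-imputed at 2p before centering, and a 1e-6 ridge
added to the diagonal before any solve. QC boundaries are inclusive:
markers at exactly MAF 0.05 or DR² 0.9 are retained (the filters remove
what is *below* threshold).

Single-trait, single-kernel models use an eigendecomposition fast path:
G is diagonalised once and the restricted likelihood, profiled over the
residual variance, is maximised over log₁₀ of the variance ratio by
bounded scalar search on [−8, 8] (tolerance 1e-10). This cannot fail to
converge. All other structures — two kernels and/or two traits,
arbitrary missing-record patterns — use dense average-information REML:
V(θ) is linear in the unique (co)variance elements, scores and AI terms
are assembled from P = V⁻¹ − V⁻¹X(X′V⁻¹X)⁻¹X′V⁻¹, Newton steps are
step-halved (up to 12 times) with every trial projected onto the PSD
cone (eigenvalue floor 1e-8 of the mean phenotypic variance), and
convergence requires a relative log-likelihood change below 1e-8 (cap
200 iterations). Fixed-effect columns with no observed records (e.g. a
fully masked trait) are dropped from the solve and reported as zero.

Validation individuals are predicted by the masked-phenotype identity
û = Cov(u, y_obs) V_obs⁻¹ (y_obs − Xβ̂), with the relationship matrix
spanning phenotyped and unphenotyped individuals alike. This is
algebraically Henderson's mixed-model equations with those phenotypes
masked; the test suite asserts the MME residual directly and the
GBLUP ≡ ridge-SNP-BLUP identity against an independently coded ridge
solve. MABLUP's GEBV includes the fixed-SNP term Mŝ; empty significant
sets degrade MABLUP/MultiBLUP/OneBLUP to plain GBLUP with a logged
warning.

## GWAS

Each SNP is tested by generalised least squares with V = K·σ²ᴀ + I·σ²ₑ
held at its REML estimate, where K is the leave-one-chromosome-out
(LOCO) VanRaden kinship; variance components are re-estimated per LOCO
partition (the conservative reading of LOCO). The Wald statistic uses
the normal approximation — at a few hundred individuals the difference
from the exact t reference is negligible relative to other
approximations. Principal components (top 2, scaled by √eigenvalue) of
the training-fold GRM are included as covariates. The significance
threshold is 1/N — N the panel size for chip data, the LD-pruned
independent-SNP count for sequence data; "suggestive" and "significant"
coincide (no second threshold is defined in this design). The most
significant SNP is the argmin-p member of the significant set, ties
breaking to the lower (chromosome, position).

A calibration caveat documented by the acceptance suite: at n ≈ 400–600
the scan is mildly conservative under the null (tail fraction
p < 0.05 ≈ 0.044–0.046), because chance REML polygenic variance
over-disperses V along the family structure. The effect shrinks
monotonically with n; null-uniformity is verified at n = 800. Per-SNP
GLS matches the ordinary-least-squares oracle exactly when V is fixed.

## Bayesian alphabet

One single-site Gibbs engine covers the seven families (see the module
docstring for the prior table). Marker inclusion is sampled with the
effect integrated out given the current variance, then the effect from
its normal conditional; per-marker variances from
scaled-inverse-χ²(v+1, (vS+g²)/(v+1)) conditionals; the shared variance
(C/Cpi) and BayesR's σ²_g from their pooled conditionals; π from
Beta(m−k+1, k+1) (Bpi/Cpi); BayesR proportions from a flat Dirichlet
over component counts, starting at (0.95, 0.02, 0.02, 0.01) with
variance scalars (0, 1e-4, 1e-3, 1e-2)·σ²_g — a `fix_pi` flag keeps the
proportions at the literal starting vector for the fixed-proportion
reading. Lasso latent scales use inverse-Gaussian draws
(1/τ² ~ IG(λ/|g|, λ²)); λ is fixed at its initial value. Fixed effects
are sampled under a flat prior rather than pre-corrected.

Hyperparameters: v = 5 and S solved so the prior mean per-marker
variance equals h2_guess·var(y)/(m(1−π)·mean 2p(1−p)); λ = √(2/that
variance); residual prior scaled-inverse-χ² with df 5 and scale
(1−h2_guess)·var(y); BayesR σ²_g starts at h2_guess·var(y). Every
realised value is recorded in the returned summary. Chains default to
50,000 iterations with 25,000 burn-in and thinning 1; study configs
scale these down (desk-scale runs use 600–3,000 iterations, and the test
suite verifies short-vs-long-chain GEBV stability). A `fix_variances`
hook holds all variances constant so conjugate closed forms apply
exactly in validation tests. Chains are bit-identical under a fixed
seed.

## Evaluation

Folds are a random balanced partition (sizes differing by ≤ 1),
identical across models for a given seed. Marker selection runs on
training individuals only — validation phenotypes are masked before the
scan ever sees them (a leakage test corrupts them and asserts nothing
changes). Accuracy is Pearson r between validation GEBVs and the
globally corrected phenotype; bias is the slope of corrected phenotype
on GEBV (computed with matching ddof so a perfect prediction gives
exactly 1). Corrected phenotypes are computed once over all individuals
(the fold-honest variant would re-fit per training fold; the global fit
mirrors standard practice in this design and its optimism is noted, not
"fixed"). Tukey's HSD treats the k fold accuracies as independent
replicates — the usual, slightly optimistic convention, since folds
share training data. Failed cells are recorded with their error and
excluded from comparisons with a logged count. Per-cell wall-clock times
go to a side log, never into the canonical report JSON, so same-seed
reruns are byte-identical.

## Desk-scale configurations

The defaults are a deliberate miniature of the real design (which used
11,063,641 imputed SNPs on 513 pigs): 600 individuals, 5 chromosomes ×
2,000 SNPs, 5% chip density. The heavier checks in the acceptance suite
use: REML recovery at the full default scale over 10 seeds; null-scan
calibration at n = 800 on a 2,000-SNP panel; and the GWAS-integration
study at n = 400 with 3 × 1,000 SNPs, 10-fold CV, 10 replicates.

The integration study deserves its regime note. The benefit of adding
GWAS-selected markers to GBLUP exists in the *marker-dilution* regime —
panel dimension large relative to the population, so that a large QTL's
signal is diluted across the relationship matrix — and for traits whose
QTL are actually detectable at the 1/N threshold. At desk scale that
means a strongly oligogenic trait (the study trait uses 5 QTL carrying
80% of the genetic variance, emulating a major-gene trait) and the
densest panel the time budget allows. Outside that regime — small
panels, family-dominated information, or QTL below the detection
threshold — plain GBLUP absorbs the QTL through relatedness and the
integration benefit genuinely vanishes; that is a property of the
method, and the package reproduces it.

## What passing tests do and do not show

The generator emulates LD, sib-family relatedness, two correlated trait
architectures, chip/sequence density contrast and imputation error. It
does not emulate selection, migration or admixture, across-breed LD
structure, genotyping-batch artefacts, dominance/epistasis, or
real-pedigree depth beyond one generation. Results on synthetic data
demonstrate that the estimators, samplers and the cross-validation
harness are internally correct and that the qualitative
GWAS-integration pattern emerges under the architecture that favours it;
they do not predict the magnitude of accuracy gains on any real
population.

## Known limitations

- LDAK-Thin SNP weighting is not reproduced; all kinships are unweighted
  VanRaden method 1 (a documented substitution, isolated in one
  function).
- Two-kernel REML with a very small significant-SNP group (fewer than
  ~10 markers) is weakly identified: the group's relationship matrix is
  a noisy version of the family kinship and the likelihood can prefer a
  boundary solution with zero polygenic variance. MultiBLUP is most
  useful when the selected set is reasonably large.
- The Bayesian engine is single-trait, as in the study design it
  implements.
- No X-chromosome handling, no genotype phasing/imputation (the error
  model stands in for the imputation step), no pedigree or single-step
  methods, no dominance or epistasis.
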