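# Methods

## The scientific problem

Psychiatric diagnoses are rare binary outcomes, while the traits they relate
to (autistic traits, ADHD symptoms, anxious/depressive symptoms, ...) are
measured continuously in the population. `twinprs` implements the two
standard quantitative-genetic engines for asking how much of the risk for a
diagnosis is shared with continuous variation in the related trait:

1. **Joint categorical/continuous bivariate twin models.**  A diagnosis is
   treated as the indicator that an unobserved standard-normal *liability*
   exceeds a threshold set by prevalence (per sex).  The 4-vector
   (trait₁, liability₁, trait₂, liability₂) of a twin pair is multivariate
   normal with a covariance implied by a variance decomposition into
   additive genetic (A), nonadditive genetic (D), shared-environment (C)
   and nonshared-environment (E) components, plus one correlation per
   component linking the two phenotypes.  Contrasting monozygotic (MZ)
   pairs, whose genetic factors correlate 1, with dizygotic (DZ) pairs
   (A: 0.5, D: 0.25) identifies the decomposition; C correlates 1 in both,
   E in neither.
2. **A polygenic risk score (PRS) pipeline.**  Discovery-GWAS effect sizes
   are harmonized to target genotypes, LD-clumped, summed over effect-allele
   dosages at a grid of p-value selection thresholds, z-standardized, and
   regressed on outcomes with generalized estimating equations whose
   sandwich variance clusters on twin pair; principal components of the
   genotype matrix absorb population stratification and Benjamini–Hochberg
   FDR handles multiplicity.

Because registry-linked twin cohorts cannot be redistributed, a synthetic
cohort generator with known ground truth is a first-class part of the
package: every downstream estimate can be validated against the parameters
that generated the data.

## Model and likelihood

### Implied moments

For component k ∈ {A, C, D, E} with variance shares v_k per phenotype,
cross-phenotype correlation r_k and cross-twin factor correlation κ_k
(MZ: 1/1/1/0 for A/D/C/E; DZ: 0.5/0.25/1/0), the 4×4 latent covariance has

* within-twin cross-phenotype correlation rPh = Σ_k r_k √(v_k,t · v_k,l),
* cross-twin same-phenotype covariance Σ_k κ_k v_k,
* cross-twin cross-phenotype covariance Σ_k κ_k r_k √(v_k,t · v_k,l).

Each component contributes W_k ⊗ [[1, κ_k], [κ_k, 1]] with W_k positive
semidefinite, so the implied matrix is PSD for any admissible parameter
values — the optimizer never needs a PSD repair, though the code still
guards against it.

**Sibling interaction.**  Reciprocal phenotype-on-phenotype paths *s*
between co-twins (which inflate MZ relative to DZ resemblance and can mimic
dominance) are modeled as a path matrix B with s in the cross-twin
same-phenotype cells; the observed covariance is
(I−B)⁻¹ Σ_latent (I−B)⁻ᵀ, re-standardized to a correlation matrix because
the likelihood is evaluated on sex-standardized data.  The source
literature does not give this algebra; the reciprocal-path
parameterization is the standard one.  A single s applies to both
phenotypes by default (`interaction_on="both"`), configurable to either
one, since the original specification of which phenotype carried the
interaction is not recorded.

### Pair likelihood

The exact likelihood of a pair factorizes as (density of the observed
continuous components) × (conditional-normal rectangle probability of the
observed binary components); missing elements are marginalized by
dropping their rows/columns.  Rectangle probabilities use a vectorized
implementation of the Genz/Drezner–Wesolowsky bivariate normal CDF
(`twinprs._bvn`), accurate to ~1e-14 and validated against scipy, because
a fit at 2×10⁵ pairs needs ~10⁵ rectangle probabilities per objective
evaluation and scipy's CDF evaluates points one at a time.  Pairs are
grouped by (zygosity class, missingness pattern, diagnosis pattern, sex
pattern) so each objective evaluation is a handful of vectorized passes.

### Estimation

* Continuous traits are z-standardized within sex (denominator n−1) before
  fitting; sex enters the model only through the thresholds, and DZ
  opposite-sex pairs are pooled with same-sex DZ pairs (no sex-limitation
  model — twin samples of this size are underpowered for sex differences).
* Parameters are transformed to an unconstrained scale (variance shares by
  stick-breaking logits, correlations and s by tanh, thresholds identity)
  and maximized with L-BFGS-B from a moment-based start (cross-twin
  Pearson correlations, prevalence-based thresholds) plus `n_restarts`
  random perturbations (default 2).  Convergence tolerance 1e-9 on the
  log-likelihood.
* BIC = −2·loglik + k·ln(N) with N = number of twin pairs contributing any
  data; the likelihood-ratio chain runs from the full family (ACE or
  ADE-s) to nested reductions, favoring the most parsimonious model whose
  LRT against the full model is non-significant at α = 0.05.  P-values at
  variance-component boundaries use the plain χ² reference (no 50:50
  mixture correction), which is conservative; this caveat is deliberate
  and documented rather than silently corrected.
* Profile-likelihood confidence intervals are available for the
  correlation parameters (χ²(1) inversion with re-optimization); they are
  computed on demand (`profile_ci`) rather than in every fit because each
  bound costs several re-fits.
* Under ADE the reported genetic correlation rG is the correlation of the
  total genetic deviations (A+D composite); rA alone is also exposed,
  since published figures rarely say which convention they use.
* The decomposition of the phenotypic correlation into component shares is
  computed on the latent scale (shares of Σ_k r_k √(v_k,t v_k,l)); with
  s = 0 this coincides with the observed scale.

### Descriptive (saturated) correlations

The saturated summary constrains means/variances across twin order and
zygosity by construction: cross-twin Pearson correlations are computed by
double entry, cross-twin diagnosis correlations are tetrachoric MLEs on
the order-symmetrized 2×2 pair table, and trait-diagnosis correlations are
two-step polyserial MLEs (thresholds from margins, then a 1-D likelihood
maximization).  These are margin-wise ML estimates under the stated
equality constraints rather than one joint 10-parameter fit; the
structural models use the full joint likelihood.  CIs use the Fisher-z
approximation (exact likelihood-based CIs belong to the structural fits).

## Synthetic cohort generator

The generator *is* the study design, not a tuning knob:

* **Twin phenotypes** are drawn from the implied moments per zygosity
  group (MZM/DZM/MZF/DZF/DZOS), liabilities dichotomized at sex-specific
  thresholds, with optional missingness.  Default prevalences in examples
  mirror registry diagnosis rates (0.3%–3.3%).
* **Genotypes** follow a family design: four parental haplotypes per pair
  drawn from a block compound-symmetric Gaussian copula (block size and
  within-block correlation configurable), children inherit one whole
  haplotype per parent.  MZ co-twins receive identical genotypes (the
  analogue of imputing an MZ co-twin's genotype from its sibling); DZ
  co-twins share transmissions with probability ½ per parent, giving the
  Mendelian expected dosage correlation of 0.5.  Whole-haplotype
  transmission means no recombination within a simulated chunk — adequate
  for exercising clumping and pruning, not for modeling LD decay.
* **Discovery GWAS**: β̂ = β_true + ε with SE = √(1/(2·maf·(1−maf)·N)),
  two-sided Wald p-values.  Optional two-subpopulation divergence
  (Balding–Nichols Beta frequencies at a given FST) plus a subpopulation
  mean shift on the outcome create stratification confounding with no
  causal pathway, which the PCA covariates must remove.
* **Outcome**: √h² × standardized true score + independent noise, so the
  variance explained by the true score is exact by construction; the
  binary outcome thresholds it at a target prevalence.

What the generator does **not** emulate: realistic allele-frequency
spectra, LD decay with distance, imputation uncertainty, X chromosome,
assortative mating, age/cohort effects on prevalence, sex-specific
variance components, and measurement scales with floor effects.  Passing
tests therefore demonstrate estimator correctness under the stated model,
not robustness to these real-data features.

Reproducibility: every stochastic stage derives its generator from
(global seed, stage name) via `numpy` SeedSequence, so identical specs
give bit-identical outputs and stages can be re-run independently.

## PRS pipeline choices

* Clumping defaults r² = 0.1, window 250 kb, greedy by ascending p with
  ties broken by (p, position, id); r² is measured in the target sample on
  mean-imputed dosages.  These mirror common practice; the original
  analysis parameters are not published.
* Threshold grid {5e-8, 1e-5, 1e-3, 0.01, 0.05, 0.1, 0.5, 1.0} with 0.5 as
  the primary threshold; scores are z-standardized (denominator n−1);
  missing dosages are imputed as 2× the target-sample allele frequency.
* PCA: MAF ≥ 0.05, greedy LD pruning (r² 0.2 within a 50-variant window),
  frequency-scaled genotypes, components fitted excluding one twin of each
  MZ pair (whose genotypes are identical) and scores produced for all;
  whitened scores, sign fixed by the largest-magnitude loading.  k = 10
  components by default.
* GEE with independence working correlation: point estimates equal the
  ordinary GLM fit; the cluster-robust sandwich sums score contributions
  within twin pairs (with singleton clusters it reduces to HC0, which the
  tests verify against an independent OLS implementation).  Binary
  outcomes report OR = exp(β) with exp(β ± 1.96·SE) limits.
* R² is the incremental variance explained by the score over the
  covariates; for logistic outcomes it is the difference in squared
  correlation between outcome and fitted probability — a proxy, since no
  canonical pseudo-R² is implied by the reporting convention being
  mirrored.
* FDR: Benjamini–Hochberg over all primary-threshold full-sample tests as
  one family; each sensitivity threshold is adjusted as its own family.

## Problem sizes used in validation

The test suite favors one moderately sized run per property over many
replicates: parameter recovery at 4 000 pairs per zygosity group,
selection consistency and LRT calibration at 200/100 replicates of
600–750 pairs, and PRS power at 6 000 individuals.  The operating-point
recovery checks (and `scripts/acceptance.py`) use 100 000 MZ + 100 000 DZ
pairs, the scale at which the recovered genetic correlation is stable to
±0.02.

## Known limitations

* Likelihood-based CIs for derived quantities (rG under ADE) profile the
  underlying correlation parameter, not the composite.
* The threshold parameters are counted as free parameters for both sexes
  even when a sex is absent from the data (harmless for the shipped
  configurations, miscounts BIC by ln N per unused threshold otherwise).
* No sex-limitation, longitudinal or >2-phenotype models; no BGEN/PGEN or
  dosage genotypes; no LD-aware shrinkage weights.
* Multi-wave measures are exposed through `age_cohort`; pooling across
  waves is left to configuration (standardization defaults to within sex,
  optionally crossed with cohort).
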