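# Methods

## The analysis model

The package targets nuclear-family cohorts genotyped at a small panel of
biallelic candidate SNPs, with quantitative lipid and obesity phenotypes.
All genotypes are minor-allele counts; association betas are per copy of
the minor (effect) allele.

**Origin inference.** For an offspring with genotype *o* and parental
genotypes *m*, *f* (possibly missing), the caller enumerates ordered
transmission pairs (a, b) with a from the maternal transmissible set
({0}, {0,1}, {1} for genotypes 0/1/2; {0,1} if ungenotyped), b from the
paternal set, and a + b = o.  Zero compatible pairs is a Mendelian error;
more than one is ambiguous; exactly one is an assigned call with maternal
count a and paternal count b.  Offspring with neither parent genotyped are
untestable by convention, even when homozygous — origin calling is defined
only where at least one parent was observed.  No sibling-aided or
population phasing is attempted: a trio in which both parents and the
child are heterozygous stays ambiguous even when sibling haplotypes could
in principle resolve it.  This sacrifices a little power for calls that
are logically certain rather than probabilistic; it also makes every
assigned call checkable against simulation truth, which the test suite
exploits.  Under HWE and random mating the assignable fraction among
heterozygous offspring of fully genotyped trios is 1 − pq (p = MAF):
0.75 at MAF 0.5, 0.84 at MAF 0.2.

**Association contrasts.** Three linear (identity-link Gaussian) GEE
models per SNP × trait, clustered by nuclear family:

* maternal: origin-assigned heterozygotes with a maternally inherited
  minor allele (exposure 1) vs major-allele homozygotes (exposure 0);
* paternal: symmetric;
* POE: origin-assigned heterozygotes only, paternal origin coded 1 vs
  maternal origin 0.

Minor-allele homozygotes are excluded from the marginal contrasts (the
comparison is defined against major-homozygote carriers); ambiguous,
Mendelian-error and untestable offspring are excluded everywhere.  An
alternative joint-dosage mode regresses the trait on maternal and paternal
minor-allele counts simultaneously over all assigned offspring and reads
the POE as the coefficient difference with its delta-method robust SE; it
is the standard alternative and useful for power work, but the subset
contrasts are the default.

The working correlation defaults to independence with robust sandwich
SEs (exchangeable is selectable); p-values use the normal reference for
the sandwich z (a small-sample t reference is selectable).  Covariates:
BMI, sex, age, age², diabetes status for lipid traits; the same without
BMI for obesity traits; sex is dropped in sex-stratified runs, and the
BMI analysis never adjusts for itself.  WHRadjBMI is realized as the WHR
analysis with BMI appended to the covariates rather than by
pre-residualization (a residual mode would change the outcome variable's
scale; covariate adjustment keeps all obesity traits on the same footing —
the residualization variant is a one-line change for sensitivity
analysis).  Diabetes status enters as indicator coding when multi-level.

Families are split wholly into discovery/replication halves by a seeded
permutation; a discovery POE hit replicates when the replication half has
p < 0.05 with the same sign.  Bonferroni m defaults to the number of
SNP × trait tests actually executed and can be pinned to reproduce a
preconfigured corrected threshold.

**Trait transformations.** Friedewald LDL-C is computed as
TC − HDL-C − TG/5 in mg/dL, missing when TG ≥ 400 mg/dL; in mmol/L mode
the divisor is 2.2 and the threshold 4.52 mmol/L, selected by the declared
unit (units are mandatory when lipids are present).  The Blom transform
uses the 3/8 offset with average ranks for ties — average ranks keep the
map monotone and the output symmetric under negation up to tie effects.
TG, ApoB, LDL-C and all obesity measures are Blom-transformed; the
remaining lipid measures are log-transformed.  The 5-SD filter runs once,
on the transformed scale, with mean and SD computed a single time: for
data this close to normal after transformation one pass leaves everything
within ~3 SD, so iteration would be a no-op (a raw-scale mode exists
behind a flag).

**Familial correlations.** Model 1: Spearman (or partial rank)
correlation of parent/offspring pairs using only the oldest child per
family; father–offspring vs mother–offspring compared with Fisher's
r-to-z treating the two correlations as independent.  They share
offspring, so this is mildly anti-conservative; a Steiger-type dependent
variant is available via `dependent=True`, but the independent comparison
is the field convention and the default.  Models 2–3: random-intercept
(family) mixed regression of offspring trait on parent trait, model 3
adding sex, age, age² and BMI; slopes compared by Wald.  The partial
correlation covariate set is caller-specified; {age, age², sex} is the
natural model-1 choice, with BMI added for the model-3 analogue.

**Variance screen.** With hidden origin effects β_mat, β_pat on the
standardized trait, heterozygotes in an unrelated cohort are an
equal-weight mixture of two components at ±δ around their mean,
δ = |β_pat − β_mat|/2, so their residual variance is inflated by δ²
(ratio 1 + δ² when the homozygote variance is 1).  The default test is a
one-sided Welch comparison of median-centered absolute deviations
(Brown–Forsythe/Levene style), heterozygotes vs pooled homozygotes —
transparent, affine-invariant, and calibrated at ~0.05 under the null in
the package's own simulations.  The alternative is a likelihood-ratio
test of the heterozygote residuals as a symmetric two-component normal
mixture (means μ ± δ, common σ) against δ = 0, referred to ½χ²₁ because
δ = 0 sits on the boundary.  Both methods tag their results; neither
claims bit-compatibility with any external program.  Covariates are
removed once by least-squares residualization before grouping; fractional
dosages map to per-group weights by linear interpolation between
neighbouring hard calls.

**Meta-analysis.** Inverse-variance fixed effects on (beta, SE) pairs is
the default (meta beta Σwβ/Σw, w = 1/se², meta SE (Σw)^(−1/2));
sample-size-weighted z is provided for SE-less summary inputs.  Meta is
computed on the POE contrast.  No heterogeneity modeling (Q, I²) in v1.

## The simulator

`simulate_families` draws, per family, two parents with independent
Bernoulli(MAF) alleles (HWE), an offspring count 1 + Poisson(λ) truncated
at 5 (λ = 0.5 generically; the cohort presets set λ to match their
offspring/family ratio, e.g. 0.574 for the 2257-family preset whose
target is 3552 offspring), and transmits one uniformly chosen allele per
parent with the origin recorded.  Phenotypes are generated directly on
the analysis (transformed) scale,

    z = Σ_snp s(sex)·(β_mat·m + β_pat·p) + c_sex·1[female] + c_age·ã
        + c_age2·(ã² − 1) + c_diab·(D − prev) + c_bmi·z_BMI + u_fam + ε,
    value = mean + sd·z,

with ã the age standardized by fixed constants, u_fam ~ N(0, 0.3²), and
ε auto-scaled so family + residual variance is 1 — so β are in trait-SD
units, directly comparable to association betas.  Parents carry half the
mean parental effect per allele (their own origins are unmodeled) and
share u_fam with their children, which is what drives parent–offspring
resemblance.  Sex-specific POE is multiplicative scaling of (β_mat,
β_pat) by offspring sex.  Covariate coefficients default to small values
(0.1) so covariate adjustment is exercised without dominating the trait;
genetic and covariate terms add (a few percent of) variance on top of the
unit latent scale, so realized SDs slightly exceed their targets under
non-null effects — exact under a null configuration.  Missingness
defaults: 5% per genotype cell (genotyping success > 90%), 10% of parents
wholly ungenotyped (families need only one genotyped parent to be
informative), 5% per phenotype cell, all applied after generation so the
recorded truth stays complete.  Cohort presets carry the published-style
trait means/SDs (e.g. BMI 26.69 ± 4.61, WHR 0.90 ± 0.10 for the
Finnish/Swedish-style preset; BMI 27.89 ± 5.45, obesity traits only, for
the Hungarian-style preset) and diabetes prevalences by generation.
The default SNP panel uses the studied loci's rsIDs, chromosomes and
genes; their MAFs are not published, so plausible values (0.06–0.45) were
fixed once.  `simulate_unrelateds` draws each individual as the child of
two unobserved HWE parents, keeps the origin effects in the phenotype,
and hides the origins — exactly the situation the variance screen targets.

What the simulator does *not* emulate: linkage disequilibrium between
panel SNPs, assortative mating, multi-generation pedigrees, genotyping
error (so Mendelian-error handling is exercised only by constructed
cases), non-normal residuals, and real covariate–trait architecture.
Passing tests therefore demonstrate internal correctness and statistical
calibration under the generative model, not robustness to those real-data
features.

## Numerical and design notes

* The HWE test enumerates the full conditional distribution of the
  heterozygote count given the allele counts in log space and sums
  probabilities ≤ the observed outcome's (two-sided exact test, with a
  1 + 1e−12 relative guard against float ties); monomorphic SNPs return
  p = 1 with a warning.  Founders-only is the default because offspring
  genotypes are correlated with their parents'; an all-members mode
  exists since either choice is defensible.
* Cohort-scale origin calling goes through a 48-entry lookup table built
  from the single-trio caller, so the vectorized path is exactly the
  per-trio rule.
* GEE fits use statsmodels; with singleton clusters and independence
  working correlation the estimator degenerates to OLS (checked to
  1e−8).  Rank-deficient designs raise with the aliased column names;
  sweeps record per-cell failures in a `note` column instead of aborting.
* The mixed model (familial slopes) is REML via statsmodels MixedLM with
  an OLS fallback, flagged `converged=False`, for degenerate inputs.
* The mixture LRT optimizes (μ, log σ, δ) by Nelder–Mead from three δ
  starts (0, σ/2, σ) to avoid the δ = 0 saddle.
* Determinism: every stochastic component takes a seed; the pipeline
  derives the simulation and family-split streams from one top-level
  seed, writes floats with fixed formats, and hashes only the scientific
  part of the configuration, so identical (config, seed) reruns are
  byte-identical.
* Validation problem sizes — 10,000 trios for the assignable-fraction
  check, 1000 × 300-family null cohorts for POE calibration, 200
  replicates for effect recovery and for the variance mechanism at
  n = 3000 — were chosen to put Monte-Carlo error well below the effect
  being checked while keeping the whole suite at a couple of minutes on
  one CPU.

## Known limitations

* Duos are resolved only when the present parent is homozygous; no
  probabilistic origin assignment, so power is conservative at low MAF.
* The marginal maternal/paternal contrasts and the POE contrast use
  overlapping but different samples, so B_POE = B_PAT − B_MAT holds only
  approximately (exactly in the joint-dosage mode).
* The independent-samples Fisher comparison of parental correlations is
  anti-conservative when many families contribute both pairs.
* Binary-outcome (logistic) GEE and random-effects meta-analysis are out
  of scope in v1.
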