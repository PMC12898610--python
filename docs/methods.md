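# Methods

## Scope and data model

The package analyses a case–control cohort with four aligned tables:
subjects (group, age, sex, BMI), a plasma protein panel (nine complement
analytes plus the derived Bb/C3 ratio), an additive genotype matrix with
per-SNP annotation, and survey scores (CDC-SI total, five MFI-20
subscales, eight SF-36 T-score subscales). All protein analyses are on
log2-transformed concentrations; values below a configurable per-analyte
detection floor (default 0.01 in each analyte's native unit) are clamped
to the floor before the log, so the transform is always finite. The
floor is a package choice — no limit-of-detection rule was available —
and only affects exact zeros or near-zeros.

Minor alleles are determined in-sample: for every site the less frequent
allele among non-missing calls becomes the counted allele, with ties at
exactly 0.5 broken to the lexicographically smaller nucleotide
(deterministic and documented in the annotation output). Multi-allelic
VCF records are skipped with a warning; missing genotypes stay missing
and each model drops incomplete rows pairwise.

## Covariate screening and case–control models

Screening fits one simple OLS per (analyte, covariate) with sex coded
male = 1 (female is the reference/majority class); covariates with
p < α (default 0.05) form the analyte's adjustment set, and a
configuration override can force covariates in regardless of p (for
adjustments supported by prior literature). No multiplicity correction
is applied across analytes in the screening or case–control stages; the
output metadata says so.

The linear case–control model codes the group indicator as control = 1,
so the reported coefficient is the adjusted control-minus-case mean
difference (a negative value means higher levels in cases). The logistic
model takes case = 1 (Newton iterations, tolerance 1e-8, max 100; perfect
separation is flagged as non-converged with NaN coefficients rather than
silently reported). Multinomial subgroup models use NFhet as the
reference, whose coefficient block is identically zero. Likelihood-ratio
tests require the reduced model to be nested and fitted on exactly the
same rows; the statistic is clamped at zero against floating-point
jitter. Pairwise group contrasts evaluate adjusted means at covariate
sample means, which reduces each contrast to a difference of group-dummy
coefficients with t-based unadjusted p-values.

## pQTL scan

For each testable SNP–protein pair, the full model (dosage + covariates)
and reduced model (covariates) are fitted by least squares on identical
rows and compared by F = ((RSS_red − RSS_full)/1)/(RSS_full/(n − p_full)),
referred to F(1, n − p_full). With a single added degree of freedom this
equals the squared t of the dosage coefficient, an identity the test
suite asserts to 1e-9. A pair is testable when ≥ 2 dosage values are
present and the minority dosage class has ≥ 3 rows (avoids degenerate
leverage); monomorphic pairs are skipped and logged, and Bonferroni m is
the number of models actually fitted. Dosage is numeric 0/1/2 — the
2-df genotypic coding is out of scope. If the full model fits exactly
(RSS = 0), F is reported as +inf with p = 0 when the genotype removes the
last residual, and 0 with p = 1 when the outcome was already perfectly
fit (e.g. constant) without it.

## Enrichment, overlap and directionality

Top hits are the scan records with p strictly below the tier threshold
(0.01 by default; 0.05 for the disease-overlap join). Enrichment for
analyte a and functional group g is the observed proportion of a's hits
in g divided by g's expected proportion in the pool of all analytes' hit
lists, computed at SNP level and at gene level (genes deduplicated within
a list). By default the pool counts a SNP once per list it appears in;
`deduplicate_pooled=True` counts each SNP/gene once overall — the choice
is exposed because the pooling convention is genuinely ambiguous. The
identity Σ_g expected_g·score_g = 1 holds per analyte and level by
construction and is asserted exactly.

Cis/trans classification uses a user-supplied analyte → (gene, chrom,
TSS) table; cis means same chromosome and |pos − TSS| ≤ 1 Mb inclusive.
The directionality summary regresses per-minor-allele protein β on the
disease odds ratio by unweighted OLS and reports R²; rows whose risk
allele is the major allele are re-expressed minor-respect by inverting
the OR (the β is already per minor-allele copy). The risk nucleotide is
compared against the annotation's minor allele when available, so the
result is robust to recoding.

## Stratified ROC and subgrouping

Within a genotype stratum, case status is fitted by logistic regression
on the log2 analyte plus covariates; covariates constant within the
stratum (e.g., sex in an all-female stratum) are dropped automatically.
The AUC of the predicted probabilities is the Mann–Whitney concordance
(ties ½), identical to brute-force pairwise counting; with no covariates
left the monotone logit makes it exactly the AUC of the raw analyte.
The SE is Hanley–McNeil and the test against AUC = 0.5 is a normal
approximation on (AUC − ½)/SE — the original filter rule named no method,
so this conventional choice is isolated in two small functions and
swappable. CI95 = AUC ± 1.96·SE truncated to [0, 1]. Filters default to
AUC > 0.75 (strict; the ≥ variant is configurable), p < 0.05, n ≥ 15.
AUCs are apparent (in-sample predicted probabilities), which is
optimistic; this matches the screening use, not out-of-sample
performance.

Two-marker subgrouping: a subject is "het" iff dosage is exactly 1 at
either index marker; homozygous at both — including homozygous-risk
(dosage 2) carriers — is "rem"; labels prepend CFS/NF by case status.
Missing genotypes exclude the subject by default (an observed het call at
the other marker is decisive); a "rem" fallback is configurable. The
subgroup re-analysis reruns the LRT/multinomial/contrast battery on the
four labels and repeats ROC and survey associations restricted to
CFShet ∪ NFhet.

## Synthetic cohort generator

The generator is the package's stand-in for the restricted study data.
Defaults (in `default_study_config`) encode the study conditions:

* 50 cases, 121 controls; age ~ N(50, 10²) truncated > 18 years; BMI ~
  N(27, 5²) kg/m² truncated > 15 with a +2 case offset; 75% female (the
  exact fraction was not published; it is a configurable placeholder).
* Demographic effects in log2 units: BMI slopes 0.169 (CRP), 0.033 (C3),
  0.036 (C3a), 0.025 (C5a), 0.026 (Factor B), 0.020 (Factor D), 0.023
  (Factor H); male offsets −0.645 (CRP) and −0.159 (Factor B); age slope
  0.011/yr (Factor D).
* Marginal case − control shifts per analyte (e.g. +0.215 for C3, −0.022
  for Bb, +1.087 for CRP) and control-group means/SDs matching the
  published group summaries; one shared latent factor (loadings 0.5 of
  total SD for the correlated analytes, small for Bb/C5a/SC5b-9) drives
  inter-protein correlation, and residual SDs are derived so total
  variances approximate the published SDs.
* Thirteen named variants with realistic MAFs, annotations and disease
  odds ratios, plus background SNPs (default total 150, a deliberate
  desk-scale stand-in for the chip's 9146) with MAF ~ U(0.05, 0.5) and
  functional groups drawn with the published gene-count weights.
  Additive pQTL effects are planted per minor-allele copy at the
  published magnitudes (−0.36 and −0.23 at the C2 missense marker,
  −0.19 at the CFH V62I marker, etc.). The Bb/C3 ratio is never
  generated directly; it is derived, so ratio effects follow from the
  Bb and C3 effects.
* Genotypes are Hardy–Weinberg draws via thresholded latent normals;
  LD pairs use a Gaussian copula whose latent correlation is calibrated
  numerically so the realized dosage-scale r matches the configured
  value (infeasible targets are capped with a warning). Disease ORs are
  planted by tilting the minor-allele frequency in cases so the allelic
  odds ratio matches; controls use the configured MAF.
* Genotype–phenotype interaction: an extra case–control shift
  (`het_extra_shifts`, default +0.50 log2 for C3) applies only within
  heterozygote carriers of the two index markers, with the base shift
  rebalanced against the realized carrier fraction so the configured
  marginal shift is preserved. The size is derived from the published
  discrimination levels (unstratified C3 AUC ≈ 0.69 vs het-restricted
  ≈ 0.84, i.e. standardized separations of ≈ 0.7 and ≈ 1.4 SD). This is
  what gives genotype-stratified ROC something real to find.
* Surveys are linear in centred log2 protein levels plus group baseline
  offsets and noise; MFI subscales are clipped to [4, 20].
* If a site's realized minor allele differs from the configured one, the
  site is recoded and the ground-truth β signs flip with it, keeping the
  stored MAF ≤ 0.5 invariant and the scan's minor-allele convention.

All randomness flows from one `numpy` Generator seeded by a single
integer; identical config + seed reproduces every output bit-identically.

What the generator does **not** emulate: genome-wide LD structure beyond
explicit pairs, population stratification, relatedness, assay batch
effects, non-Gaussian protein tails, and missingness mechanisms. Passing
tests therefore demonstrate correctness and calibration of the methods
under the assumed generative model, not robustness of the original
study's findings to real-data complications.

## Numerical choices and problem sizes

Logistic/multinomial fits use Newton iterations (tol 1e-8, max 100);
non-finite likelihoods or separation mark fits non-converged. The scan
uses a plain least-squares path (`numpy.linalg.lstsq` + explicit RSS
algebra) for speed, cross-checked against statsmodels in the tests.
Simulation-based checks use deliberately modest sizes chosen to estimate
rates with adequate precision: 2000 null pairs and 1000 LRT replicates
for calibration (binomial SE ≈ 0.5–0.7 points at a 5% rate), 500
replicates for effect recovery, 200 for the stratified-ROC comparison,
and 150-SNP cohorts for end-to-end runs.

## Known limitations

* Apparent (in-sample) AUC only; no cross-validation.
* Two-marker subgrouping only; no combinatorial marker search.
* No kinship/mixed-model adjustment, conditional analysis, imputation,
  phasing, or liftover; genotype QC is limited to monomorphism and
  missingness handling.
* The survey stage treats CDC-SI as a total score (per-item analysis is
  not implemented).
* External GWAS integration is a join on a user-provided summary table;
  the package never queries remote services.
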