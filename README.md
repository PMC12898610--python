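# complement-pqtl

Genotype-stratified analysis of circulating complement proteins in a
case–control cohort: protein quantitative trait locus (pQTL) scanning,
covariate-adjusted case–control association, functional-group enrichment,
and genotype-defined subgroup discovery via stratified ROC. The package is
aimed at researchers studying immune dysregulation in heterogeneous
illnesses such as ME/CFS, where plasma complement markers (CRP, C3, C3a,
C5a, Bb, Factor B, Factor D, Factor H, SC5b-9 and the Bb/C3 activity
ratio) are tested jointly against immune-chip genotypes.

Because the original subject-level data are access-restricted, the package
ships a first-class synthetic cohort generator that reproduces the study's
statistical structure (50 cases / 121 controls, Hardy–Weinberg genotypes
with LD, additive pQTL effects, demographic covariate effects, group-level
protein shifts, inter-protein correlation) with known ground truth, so
every method can be validated by parameter recovery and calibration.

## The models

All protein levels are analysed on the log2 scale. For each SNP–protein
pair the scan compares nested linear models on identical subjects:

    full:     log2(protein) = β₀ + β₁·dosage + β₂·covariates + ε
    reduced:  log2(protein) = β₀ + β₂·covariates + ε

    F = ((RSS_reduced − RSS_full) / 1) / (RSS_full / (n − p_full))

with dosage the additive count (0/1/2) of the in-sample minor allele; the
FvR p-value comes from F(1, n − p_full), and Bonferroni correction uses
the number of models actually fitted. Case–control association uses
OLS (group effect reported as adjusted control − case difference) and
logistic regression logit P(case) = β₀ + β₁·log2(protein) + β₂·covariates.
Per-analyte covariate sets come from a bivariate screen of age, sex and
BMI (selected at p < 0.05, with configurable overrides).

Top pQTL hits (p < 0.01) are scored against seven curated functional
groups: enrichment = observed group proportion in an analyte's hit list /
expected proportion from the pooled lists (computed at SNP and gene
level). Disease-associated SNPs are intersected with the scan, classified
cis/trans (±1 Mb of the encoding gene's TSS, inclusive), and the OR–β
relationship is summarised by OLS R², with all effects expressed with
respect to the minor allele.

Subgroups are defined by heterozygosity at two index markers (dosage
exactly 1 at either ⇒ "het", otherwise — including homozygous-risk
carriers — "rem", crossed with case status: CFShet/CFSrem/NFhet/NFrem).
Within genotype strata, case status is modelled by logistic regression on
a protein plus covariates; the AUC of predicted probabilities is the
Mann–Whitney concordance (ties = ½) with Hanley–McNeil standard errors,
filtered at AUC > 0.75, p < 0.05, n ≥ 15.

## Worked example

```python
from complement_pqtl.simulate import default_study_config, simulate_cohort
from complement_pqtl import association, pqtl, roc

sim = simulate_cohort(default_study_config(seed=0))
panel = sim.panel  # log2-transformed, with the Bb/C3 ratio derived

lin  = association.case_control_linear(panel, sim.cohort, "C3", ("bmi",))
logi = association.case_control_logistic(panel, sim.cohort, "C3", ("bmi",))
rec  = pqtl.fit_pqtl(sim.genotypes, panel, sim.cohort, "rs9332739", "Bb")
labels = roc.assign_subgroups(sim.genotypes, sim.cohort, "rs9332739", "rs800292")
```

prints (via the fitted objects):

```
C3 case-control (linear):   beta = -0.176  p = 1.89e-03
C3 case-control (logistic): beta = +1.626  p = 2.71e-03
rs9332739 -> Bb pQTL: beta = -0.339 +/- 0.112  F = 9.3  p = 0.0027
subgroups: {'NFrem': 77, 'NFhet': 44, 'CFShet': 29, 'CFSrem': 21}
C3 AUC unstratified: 0.65 +/- 0.05
C3 AUC het-restricted (n=73): 0.86 +/- 0.05  p = 6.3e-14
```

Reading: the negative linear β means adjusted C3 is higher in cases, and
the positive logistic β means higher C3 raises the odds of being a case.
The scan recovers the planted −0.36 log2/allele Bb effect at the C2
missense marker within one standard error. Restricting the C3 ROC to the
heterozygote-defined subgroups (CFShet ∪ NFhet) lifts the AUC from 0.65
to 0.86 — the genotype stratum isolates the subjects in whom the
complement shift is concentrated.

The same analysis runs end to end from the command line:

```sh
complement-pqtl simulate --seed 0 --out inputs/     # write input files
complement-pqtl run --config pipeline.yaml          # all six stages
```

emitting tidy TSVs (`covariate_screen.tsv`, `case_control.tsv`,
`pqtl_scan.tsv`, `enrichment.tsv`, `overlap.tsv`, `directionality.tsv`,
`roc_screen.tsv`, `subgroups.tsv`, …) plus a `manifest.json` of input and
output hashes; reruns with the same seed are bit-identical.

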