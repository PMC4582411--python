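# Methods

## Design

The package implements the two-sample-style allele-score MR design for
vitamin D status and blood pressure as a chain of testable stages:

1. **Cohorts** — simulated (default) or loaded from tab-separated tables.
2. **Phenotype preparation** — hypertension classification, antihypertensive
   treatment correction, log transform of 25(OH)D.
3. **Allele scores** — unweighted synthesis/metabolism scores; harmonisation
   of external per-SNP summary statistics.
4. **Per-study associations** — adjusted OLS / logistic regressions.
5. **Meta-analysis** — fixed or DerSimonian–Laird random effects, chosen by
   a heterogeneity test; univariate meta-regression; consortium combination.
6. **MR core** — Wald ratio, delta-method variance, F / relative bias.
7. **Pipeline/CLI** — orchestration, report bundle, decision log.

## Phenotype definitions

Hypertension is SBP ≥ 140 mm Hg, DBP ≥ 90 mm Hg (inclusive thresholds), or
current antihypertensive use, classified on *observed* (uncorrected)
pressures. The continuous-BP analyses instead use treatment-corrected
pressures: +15 mm Hg systolic and +10 mm Hg diastolic added back for
treated individuals, applied exactly once (the function is deliberately not
idempotent). 25(OH)D is analysed as ln(nmol/L); per-allele effects are
reported as percent differences via `100·(exp(β)−1)`. The alternative
convention `100·β` differs by < 2% at the effect sizes involved; the
conversion is isolated in one function (`percent_per_allele`) so the choice
is a one-line change, and the downstream ratio arithmetic is insensitive to
it.

## Simulator

`SimConfig`/`generate_cohort` draw, per individual: genotypes
Binomial(2, EAF) independently per SNP (Hardy–Weinberg, no LD — the panel
genes are unlinked, and the score arithmetic assumes independent loci);
age, sex, BMI, month of blood draw, laboratory batch;

```
ln 25(OH)D = μ + Σ_j β_j g_j + A·cos(2π(month − peak)/12) + confounders + N(0, σ_X)
latent BP  = mean + θ·(ln25OHD − μ) + confounders + N(0, σ_BP)
```

Treatment is assigned by a logistic model on latent SBP, and observed BP of
treated individuals is lowered by a fixed 15/10 mm Hg — so the analysis
stage's +15/+10 correction is exact in expectation, making the correction
rule itself testable. Per-study streams fold a CRC-32 hash of the study
label into the seed sequence: identical parameter sets across studies still
give independent draws, and everything is byte-reproducible given the seed.

Key defaults (all overridable): μ = ln 50 nmol/L, seasonal amplitude 0.15
log-units peaking in August, σ_X = 0.35, mean BP 130/80 with σ = 15/10 mm Hg,
confounding through BMI (−0.012 per kg/m² on ln 25(OH)D; +0.8/+0.6 mm Hg
per kg/m² on SBP/DBP), age and sex; causal effects θ default to zero. The
panel's per-allele effects (0.0279 for the two synthesis SNPs, 0.0524 for
the two metabolism SNPs) were chosen so the default synthesis score shows a
≈2.8%/allele association with 25(OH)D and R² ≈ 0.5% — the regime the
published score analyses operate in; they are defaults, not estimates. The
magnitude of confounding is illustrative: no external value exists for it.

What the simulator does **not** emulate: linkage disequilibrium, imputation
uncertainty, population stratification, assay differences between studies,
non-European allele frequencies, and genuinely non-log-normal 25(OH)D.
Passing tests therefore demonstrate the correctness and calibration of the
statistical machinery under the stated generative model, not robustness to
those real-data complications.

## Harmonisation

External summary rows are matched to the panel's 25(OH)D-increasing
orientation: identical alleles pass through, swapped alleles flip the beta
sign and complement the EAF, strand-complement readings are resolved the
same way, and anything else is an error. Palindromic SNPs (A/T, C/G) of
unknown strand are excluded with a warning rather than silently flipped —
a conservative QC choice. One panel SNP (*CYP24A1* rs6013897, T/A) is
itself palindromic, so tables known to share the panel's strand convention
(e.g. the pipeline's own simulated consortium files) are read with
`trust_strand=True`; externally sourced tables should not be.

## Statistical engine

- OLS and Newton/IRLS logistic fits come from statsmodels; the logistic
  convergence tolerance is 1e−8 with 50 iterations, and perfect separation
  raises an error instead of returning a huge finite log-odds. Rank-deficient
  designs are rejected naming the collinear columns. All models are
  complete-case.
- Fixed-effect pooling uses inverse-variance weights; heterogeneity is
  Cochran's Q, I² = max(0, (Q−df)/Q)·100. Random effects use the
  DerSimonian–Laird moment estimator (the era-standard default in Stata,
  which the original analyses used; REML is not implemented). The
  fixed/random rule is: random iff p(Q) < α_Q, strict inequality, α_Q
  default 0.05 — the qualitative rule made explicit.
- Univariate meta-regression uses a method-of-moments residual τ² and a
  re-weighted WLS fit (metareg-style).
- The allele-score effect from per-SNP summary statistics is the
  dosage-variance-weighted average `Σv_jβ_j/Σv_j`, `v_j = 2·EAF_j(1−EAF_j)`,
  with `se = √(Σv_j²se_j²)/Σv_j` under independence. This reconstruction is
  kept behind a single operation and is unit-tested against individual-level
  score regression on simulated data (they agree asymptotically; the exact
  consortium approximation used historically is not publicly specified).

## MR core

The per-10% convention divides the per-allele outcome effect by the
percent-per-allele exposure effect and multiplies by 10 — linear in
percent, which reproduces the standard triangulation arithmetic exactly
(e.g. −0.08/2.83·10 = −0.283). The phenotypic per-10% conversion in
simulate mode instead uses the model-exact Δln = ln(1.1); the two
conventions differ by ≈3% relative, which is treated as an estimator
convention, not corrected for. Wald intervals use the normal reference
(consistent with meta-analytic inputs), the delta-method variance sets the
numerator–denominator covariance to zero (no covariance is available for
overlapping samples; the estimate object carries this as metadata), and
binary outcomes exponentiate the log-odds interval. `f_statistic` takes R²
and n explicitly rather than guessing any particular study's n.

## Numerical and degenerate-input choices

- Dosages outside [0, 2], non-positive 25(OH)D, missing treatment flags,
  zero-length meta inputs, constant meta-regression covariates, k < 2 for
  random effects, r² ≥ 1 and n ≤ 2 for F are all hard errors.
- An infinite consortium SE is a valid zero-weight limit: combination
  returns the cohort stratum unchanged.
- A heterogeneity p exactly equal to α_Q selects fixed effects.
- Scores refuse to compute when a component SNP is absent (no single-SNP
  fallback); individuals missing a component dosage are dropped with a
  logged count.

## Problem sizes

Defaults are scaled to make repeated end-to-end simulation practical while
staying in the published analyses' statistical regime (instrument R² ≈
0.5%, F well above the weak-instrument rule of thumb): pipeline default 8
studies × 1 500 individuals plus a 20 000-individual consortium stratum;
the recovery experiments use 20 studies × 1 500 per replicate (200
replicates in the test suite, 60 in the acceptance script); the
summary-vs-individual-level agreement check uses one cohort of 50 000.

## Known limitations

- Single shared covariate set across linear and logistic models; geographic
  region / principal components enter only as user-supplied columns.
- No pleiotropy-robust estimators (median/Egger/mode post-date the design
  this package reproduces); the per-SNP comparison of score components is
  the only pleiotropy check beyond lipid adjustment.
- DerSimonian–Laird τ² is known to be noisy at small k; no Knapp–Hartung
  correction is applied.
- The simulator's treatment model is a single logistic on latent SBP;
  real prescribing depends on history and comorbidity.
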