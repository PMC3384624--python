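# Methods

This note documents the models, procedures, defaults and numerical
choices behind `ffmnet`, and what the synthetic-data experiments do and
do not demonstrate.

## Panels

A panel is an ordered list of metabolites with chemical-class labels.
The packaged presets follow Biocrates AbsoluteIDQ naming and the class
composition of the kits the emulated study used: `p180` holds 186
metabolites (21 amino acids, 19 biogenic amines, 40 acylcarnitines
including free carnitine C0, 14 lysoPC, 38 PC aa, 38 PC ae,
15 sphingomyelins, hexose) and `p150` holds 163 (14 amino acids,
41 acylcarnitines, 15 lysoPC, 77 PC, 15 SM, hexose). The exact species
membership of the original kits is not machine-readable from public
sources, so the presets are curated species lists with the right class
counts; the aa/ae split of the p180's 76 PCs (38/38 here) and any user
panel are configurable through the panel TSV format.

## Quality control

Order is fixed: CV filter → missingness filter → outlier detection →
subject policy → imputation.

* **CV filter.** Per plate, CV = sample SD/mean of the reference-blood
  replicates (ddof = 1); the mean CV is the unweighted mean over plates
  with a defined CV (≥ 2 replicates, nonzero mean). Metabolites with
  mean CV *strictly* above 0.25 are removed. All thresholds in QC are
  strict, following the "bigger than / exceeded / more than" convention,
  so boundary values are kept.
* **Outliers.** mean ± 5 SD per metabolite, computed once over all
  subjects including the candidate (no re-estimation; an iterative
  scheme was not specified in the recipe this implements). Two flagged
  metabolites of one subject are *dependent* when the Pearson
  correlation of their full concentration columns is ≥ 0.70 in absolute
  value; a subject's independent-outlier count is the number of
  connected components of that dependency graph. The phrase this
  operationalises ("correlation with all other outliers") is ambiguous;
  column correlation is the only version computable from the data, and
  components give a conservative count. More than three independent
  outliers drops the subject; otherwise the cells are blanked.
* **Imputation.** Chained-equations regression, single completed
  dataset: metabolites in decreasing-missingness order, each regressed
  on its 10 most-correlated currently-complete predictors, missing
  cells filled with prediction + N(0, residual SD) noise, 5 sweeps,
  seeded. Imputed values are floored at half the smallest observed
  positive value of the metabolite — negative concentrations are
  unphysical and exact zeros would break downstream log-ratios.
  Ill-conditioned fits fall back to the metabolite mean (logged).
  The `QcReport` records every exclusion, flag and filled value, and is
  sufficient to replay the full matrix transformation (tested).

## Transform and association

Default transform: z = (ln x − mean(ln x))/SD(ln x) with ddof = 1;
zeros are replaced by ε·(smallest positive value), ε = 0.5. A
rank-based inverse-normal option (Blom offsets) is available for
panels with heavy non-log-normal tails. Tied/constant vectors are
rejected (the SD of a tied log vector is ~1e-16 from rounding, so the
zero-variance check is relative).

Associations are OLS with the transformed metabolite as response and
FFMI as exposure, adjusted for age and sex, plus batch indicator
contrasts when the cohort was measured in more than one batch. The scan
uses one shared design matrix and a vectorised multi-response OLS
(β, SE, two-sided t-test p, adjusted R² per column); the single-model
path is cross-checked against statsmodels in the test suite. p-values
are floored at the smallest positive double so that downstream ratios
of p-values stay finite.

**Multiple testing.** The default threshold is α/M_eff with M_eff the
eigenvalue-based effective number of tests on the metabolite
correlation matrix (each eigenvalue contributes 1 if ≥ 1 plus its
fractional part; eigenvalues are rounded at 1e-10 before flooring so
that a rank-deficient panel's eigenvalue of 8−1e-15 does not contribute
a spurious ~1). M_eff equals M for an uncorrelated panel and 1 for a
perfectly correlated one. The published thresholds (3.12e-4 / 3.5e-4)
depend on the original cohort's correlation structure and cannot be
rederived without it; they are offered as fixed replay values.

**Strata.** Built-in stratifications: sex, age (> 65 vs ≤ 65), sports
activity, BMI (≥ 30 vs < 30). Thresholds are recomputed within each
stratum; strata below 50 subjects are skipped; covariates constant
within a stratum (sex inside sex strata) are dropped.

## Ratios and p-gain

Intra-class pairs only, unordered, stored with lexicographic
orientation (under the log-z transform, swapping numerator and
denominator flips β and leaves p and p-gain unchanged — asserted to
1e-10 in the tests, so orientation is a convention, not a choice). The
class partition is configurable: default is one group per chemical
class; a lipid-merge option pools PC aa/PC ae/lysoPC, which reproduces
the 5202 pairs of the 163-metabolite panel under that grouping. The
original study's exact partition is not recoverable from its printed
class counts, hence the option.

p-gain = min(p_M1, p_M2)/p_ratio, computed on the log scale so p-values
below ~1e-300 do not underflow. A ratio is significant iff its p-value
passes the panel threshold *and* p-gain strictly exceeds the cut-off.
The default cut-off is the number of metabolites after QC (the
Bonferroni-flavoured rule of thumb for the extra tests ratios
introduce); the published 170/150 values are available for replay.

## Gaussian graphical model

Covariates (age, sex, FFMI, optionally batch) are removed first by
residualisation — they are nuisance terms, not network nodes — and the
full-order partial correlations among metabolites come from the inverse
of the residual covariance: ρ_ij = −ω_ij/√(ω_ii ω_jj). The
per-pair regress-out-everything-else residual correlation is the
independent oracle; the two routes agree to 1e-10 on random SPD
instances (tested at 100 instances).

Edge inference: Fisher z with √(n − k − 3), where k counts every
conditioned variable — the covariates (batch as its indicator count)
plus the other M−2 metabolites; Bonferroni over all C(M,2) pairs at
α = 0.01. The magnitude cut-off |ρ| ≥ 0.3 is inclusive and applied to
the absolute value (sign is kept as an edge attribute). Near-singular
residual covariances (M approaching n) raise with advice to set the
optional ridge λ, which marks results as regularised; the default
cohort (n = 965 ≫ M = 166) never needs it. Networks export to
GraphML/GML (round-trip tested) and a TSV edge list.

## Synthetic cohorts

The generator is a pure function of (config, seed) and emits ground
truth alongside the data.

* **Phenotypes.** Sex Bernoulli(0.5); FFMI normal with sex-specific
  mean/SD 19.71 ± 1.66 (men) / 16.99 ± 1.85 (women) kg/m²; BFMI
  8.34 ± 2.29 / 11.24 ± 3.08; heights 172.3 ± 6.4 / 159.3 ± 6.0 cm; age
  N(63.2, 5.5²) truncated to [51, 80]; FFM/FM back-computed from the
  indices so weight = FFM + FM exactly. These are the published cohort
  descriptives of the study population the generator emulates.
* **Dependence.** A class-structured sparse precision matrix on the log
  scale: within-class edges at density 0.05 with partial correlations
  U(0.3, 0.6), random sign; no cross-class edges. Edges are placed
  under a per-row diagonal-dominance budget (Σ|ω| ≤ 0.9), which
  guarantees positive definiteness while *preserving the drawn
  magnitudes*; a diagonal ridge exists as a fallback but would shrink
  every planted value toward the detection boundary, so the budget is
  the primary mechanism. Dropping metabolites (e.g. after QC) changes
  the remaining full-order partial correlations; `marginal_partial_corr`
  provides the exact Schur-complement ground truth for any subset.
* **Effects.** Planted standardized betas live on the transformed
  scale: the latent log-signal is β·FFMI_c + 0.05·age_z + 0.05·sex_z +
  batch shift + scaled correlated noise, with the noise scaled so the
  latent variance is ~1; exponentiation and the ln-z transform then
  return exactly the latent coordinate, so the planted β is the OLS
  estimand up to O(1/√(2n)) sample-SD noise. Default effect table: the
  published non-obese stratum estimates (|β| 0.07–0.16, BCAAs and
  acylcarnitines positive, PC ae/lysoPC negative). Nuisance γ = 0.05
  makes covariate adjustment consequential; 3 batches with log-SD 0.05
  emulate multi-batch measurement.
* **Marginals.** Per-metabolite log-normal location/scale chosen to hit
  published mean/SD in µmol/l where available (e.g. Val 227.26 ± 53.13,
  hexose 5180 ± 760) and class-typical scales otherwise.
* **Contamination.** Outliers replace raw values with mean ± U(6,9)·SD
  (rate 1e-3) — far enough out that the ±5 SD detector must catch them
  even after they inflate their own column's SD at sparse rates;
  missingness is MCAR at 2e-3. Reference replicates are log-normal with
  dispersion set to the target CV: 0.07 for ordinary metabolites and
  0.5 for 20 designated low-abundance species, so the CV filter removes
  exactly 20 of 186, matching the emulated study's QC outcome (166
  kept). The 0.5 value reflects that truly failing assays sit well
  above the 25% threshold; a planted CV near the threshold would make
  "exact removal" ill-defined, since a 5-replicate CV estimate has
  sampling SD ≈ cv/√8.

**What passing does not show.** The generator draws log-normal
concentrations with an exactly sparse within-class GGM, MCAR
missingness and gross symmetric outliers. Real cohorts have cross-class
biochemical coupling, limit-of-detection (not-at-random) missingness,
batch-by-metabolite interactions, and non-log-normal tails; calibration
and recovery results here certify the implementation under its stated
model, not performance on such data.

## Experiment sizes

The acceptance experiments use the default cohort (n = 965, 186 → 166
metabolites): 100 replicate cohorts for β coverage/type-I calibration,
3 replicates for network recovery, 100 random SPD instances (M ≤ 20)
for the dual-route oracle, and a 300-subject/59-metabolite fixture with
near-normal marginals (CV 0.02) for the exact-QC check — chosen so the
planted structure is unambiguous at the 5 SD boundary. Coverage is
pooled over planted-metabolite × replicate draws: at 100 replicates a
per-metabolite coverage estimate has binomial noise of the same order
as the 95% target itself.

## Known limitations

* The imputer is a fixed-order chained-equations scheme with a single
  completed dataset; it does not propagate imputation uncertainty
  (no multiple imputation), which is adequate at the ≤1% missingness it
  is used for here.
* M_eff thresholds are estimated from the same data they gate; for
  small panels (< ~20 metabolites) plain Bonferroni is advisable.
* The GGM treats covariates asymmetrically (residualised, not nodes);
  with strong covariate-metabolite nonlinearity the partial
  correlations absorb the misfit.
* SNP association assumes additive dosage effects and skips monomorphic
  variants; no relatedness/population-structure adjustment is provided.
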