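# Methods

This note documents the statistical procedures implemented in `sphingonet`,
the assumptions behind them, the choices made where the design was
genuinely open, and what the synthetic-data studies do and do not
demonstrate.

## Clinical classification

MetS follows the updated ATPIII rule: a subject is positive when at least 3
of 5 components are abnormal — waist circumference (>102 cm men, >88 cm
women), triglycerides (≥150 mg/dL), HDL-c (<40 mg/dL men, <50 mg/dL women),
blood pressure (systolic ≥130 or diastolic ≥85 mmHg), fasting glucose
(≥100 mg/dL) — and a medication flag (lipid-lowering, HDL-raising, treated
hypertension with history, glucose-lowering) forces the matching component
abnormal regardless of the measured value. The classifier is monotone: a
worse component value can never remove a diagnosis (property-tested).
Missing component data raise an explicit error naming the field; we do not
impute clinical values.

Impaired glucoregulation is defined as glucose >100 mg/dL **and** insulin
≥25 μIU/mL. CRP strata split at the sample median; ties go to "low" (the
definition speaks of below/above the median, so a deterministic convention
is needed and the ≤-median side is the conservative one). Subjects missing
CRP are excluded from CRP-stratified analyses.

## Lipid preprocessing

- **Missingness filter.** A species is retained only when its missing
  fraction is *strictly* below 20%; a species missing exactly 20% of values
  is dropped. Missing values model abundances below the detection limit.
- **Transformation.** Natural log, then per-species z-scoring with the
  sample SD (ddof = 1), computed over non-missing entries; missing stays
  missing. The log base is immaterial after z-scoring, and the rank-based
  network stage is invariant to any monotone per-species transform, so
  neither choice propagates downstream.
- **Ratios.** CER/LCER and (DCER+CER)/(HCER+LCER) are computed on raw
  (untransformed) class totals. Totals sum the non-missing species of a
  class — no imputation; the <20% filter bounds the resulting bias. Both
  ratios are invariant to a global rescaling of the matrix.

## Volcano screen

Species are compared between MetS+ and MetS− on raw abundances with the
two-sided Wilcoxon rank-sum test: exact null distribution when both groups
have ≤8 observations and no ties, otherwise the normal approximation with
tie-corrected variance and continuity correction. A species is flagged when
p < 0.05 and the fold change exceeds 1.15 in either direction. Fold change
is the ratio of group **means** of raw abundances (the usual volcano
convention; the ratio of medians is available via `fc_stat="median"`, and
the choice is recorded in the output metadata). No multiplicity correction
is applied at this exploratory stage. A caveat worth knowing: for balanced
groups of 3 or 4 the normal approximation can deviate from the exact
two-sided p by up to ~0.037 in the middle of the null distribution; from
n = 5 per group the deviation stays below 0.02.

## Association models

Linear (OLS) and binary logistic (GLM/IRLS, tolerance 1e-8, max 100
iterations) models estimate the per-1-SD coefficient of a z-scored lipid
exposure, adjusted for sex, age, race, and education (linear models
optionally also MetS). Categorical covariates are dummy-coded against fixed
references (sex "female", race "White", education "high school or less");
age enters linearly in years by default with a 3-bin categorical option
(<50, 50–65, >65). Inference is Wald: logistic effects are reported as
odds ratios with exp(β ± 1.96·se) CIs. Complete-case analysis throughout.
Rank-deficient designs raise an error naming the collinear columns;
non-convergence (e.g. perfect separation) raises an explicit error rather
than returning an untrustworthy estimate. Display matrices mask cells with
p ≥ 0.05 to 0.

## Distance networks

Within a stratum, Spearman ρ is computed for every species pair with
midranks and pairwise-complete observations; p-values use the
t-approximation t = ρ√((n−2)/(1−ρ²)) on n−2 df with the pairwise n (checked
against a label-permutation oracle at n = 10). The Benjamini–Hochberg
family is the strictly-upper-triangle of one stratum's matrix — networks
are built and interpreted per subgroup, so adjustment is not pooled across
strata. Then

- d_ij = 1 − |ρ_ij| when p_adj,ij < α (default 0.05),
- otherwise the coefficient is zeroed: d_ij = 1 and the pair contributes
  **no edge** to the graph.

Edge weights are w_ij = |ρ_ij| = 1 − d_ij, the only monotone choice
consistent with "shorter distance = stronger association".

**Clustering** is agglomerative Clauset–Newman–Moore: start from singleton
clusters, repeatedly merge the connected pair with the largest modularity
gain ΔQ = 2(e_cd − a_c a_d), and return the partition with maximal weighted
Newman modularity along the merge path. Ties in ΔQ are broken by the
lexicographically smallest cluster-index pair, making the algorithm fully
deterministic; nodes without significant edges remain singletons, and
clusters are never merged across disconnected components (such a merge can
only lower Q). Greedy Q is verified against exhaustive partition search on
all instances with ≤8 nodes.

**Interclass distance** between classes A and B is the arithmetic mean of
d over all |A|·|B| cross-class pairs (within-class pairs excluded). With
every cross pair non-significant the value is exactly 1.

**Permutation test.** The difference Δ = D_A − D_B between two strata is
tested by pooling the strata's subjects, reassigning them at random to
pseudo-strata of the original sizes, and recomputing Δ through the *full*
pipeline (Spearman → BH → distance) each repetition; two-sided
p = (1 + #{|Δ_perm| ≥ |Δ_obs|})/(1 + n_perm), so p is never exactly 0.
Default n_perm = 1,000. Subjects with any missing species value are
excluded up front so each repetition operates on complete data (the
vectorized rank path); this keeps the permutations exchangeable at the cost
of some subjects when missingness is non-trivial.

**Whole-network comparison.** Two strata's correlation matrices are
compared with a Steiger-type statistic: Fisher-z each off-diagonal pair and
sum (z1 − z2)²/(1/(n1−3) + 1/(n2−3)) into a χ² with k(k−1)/2 df. This is
the Fisher-z χ² form; for a single pair it reduces exactly to the
two-sample correlation z-test. It assumes independent strata and |ρ| < 1
everywhere off-diagonal (violations raise errors).

## Synthetic cohort generator

The generator emulates the structure the analyses assume, so the whole
pipeline can be exercised and calibrated without restricted cohort data.

- **Clinical components.** The five MetS components derive from latent
  standard normals sharing a common factor (pairwise latent correlation
  0.4). The latent threshold τ is solved numerically (Gauss–Hermite
  quadrature + root finding) so that P(≥3 components abnormal) equals the
  target prevalence — default 0.374, the descriptive prevalence of the
  motivating cohort — and each latent maps to a clinical value that crosses
  its ATPIII cut-off exactly when the latent crosses τ (diastolic pressure
  is tied to systolic so the diastolic criterion never fires alone). The
  *classifier*, not the generator, assigns the diagnosis; calibration is
  verified against a 99% binomial interval at n = 10,000. Medication flags
  default to rate 0 so this calibration is exact.
- **Biomarkers.** CRP, IL-6, fibrinogen, sICAM, sE-selectin are lognormal
  with additive log-scale shifts for MetS subjects (CRP +0.6, IL-6 +0.4,
  fibrinogen +0.15, sICAM +0.10, sE-selectin +0.15).
- **Lipids.** Log-abundances are multivariate normal with a class-block
  correlation: within-class Spearman 0.5, interclass 0.2 by default, with
  stratum overrides that mirror the qualitative network findings the
  pipeline is meant to detect — all interclass pairs tightened to 0.35 in
  MetS+/CRP-high, and CER–HCER 0.35 / HCER–LCER 0.10 in MetS−/CRP-high.
  Targets are specified on the Spearman scale and converted to the latent
  Pearson scale via ρ_P = 2·sin(πρ_S/6), so exponentiation preserves the
  planted rank correlations exactly. MetS subjects' class means shift by
  +0.20 (DCER, CER), −0.15 (HCER), −0.25 (LCER), 0 (SM) on the log scale
  (fold changes ≈ 1.22/0.86/0.78, straddling the 1.15 volcano threshold).
  Every stratum's correlation matrix is validated as positive semidefinite
  at construction, naming the offending class pair when a 2-class submatrix
  fails.
- **Missingness** is injected missing-completely-at-random at 5% by
  default. Real below-detection-limit missingness is left-censored, not
  MCAR; MCAR is sufficient for testing the <20% filter and keeps every
  downstream estimator unbiased, but it means the tests here say nothing
  about censoring-induced bias in real data. Left-censoring is out of
  scope.

What passing the synthetic studies shows: the estimators recover planted
rank correlations, mean shifts, and prevalence; the permutation test is
correctly sized and powered under the planted alternatives; clustering
recovers planted block structure. What it does not show: robustness to
left-censored missingness, assay batch effects, covariate-confounded
missingness, or sampling-design effects — none of which the generator
emulates.

## Simulation study sizes

The calibration and power suites use a two-class panel of 8 species (4 CER,
4 LCER), chosen to keep per-repetition correlation matrices small: type-I
error over 500 null datasets (n = 200/stratum, 200 permutations each);
power over 100 runs (interclass Spearman 0.6 vs 0.3, n = 500/stratum).
Clustering recovery uses the full 26-species ceramide/glycosphingolipid
panel (within 0.6, interclass 0.1, n = 1,000, 50 runs) scored by adjusted
Rand index against the class labels. Greedy-vs-exhaustive comparisons use
200 random weighted graphs with ≤8 nodes (Bell(8) = 4,140 partitions each).

## Numerical conventions and degenerate inputs

- Spearman uses midranks; constant species raise an error naming the
  species, as do pairs with <4 complete observations.
- BH adjustment is capped at 1 and verified against the brute-force step-up
  definition.
- Permutation p-values use add-one smoothing; Δ comparisons use a 1e-15
  absolute guard against floating-point ties.
- Greedy merges treat ΔQ differences below 1e-12 as ties.
- z-scoring refuses zero-variance and non-positive columns rather than
  emitting NaN/inf.
- All randomness flows through `numpy.random.default_rng` seeds carried in
  configs and result objects; identical config + seed reproduces outputs
  bit-for-bit.

## Pipeline conventions

The orchestrated run uses the four ceramide/glycosphingolipid classes
(DCER, CER, HCER, LCER) for ratios, association exposures, and networks;
sphingomyelins take part in the volcano screen but show no group shift
under the default generator, matching their exclusion from the focused
analyses. Strata with fewer than 20 subjects are skipped with a logged
warning. Interclass permutation tests and Steiger comparisons run for all
stratum pairs and all 6 class pairs. A JSON manifest records versions,
seed, thresholds, covariate references, stratum sizes, dropped species, and
input checksums. Note the observed interclass distances reported alongside
the permutation tests are computed on complete cases (matching the
permutation null), while the per-stratum network tables use
pairwise-complete correlations; with low missingness the two agree closely.
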