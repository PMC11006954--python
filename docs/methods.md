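# Methods

This note records the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that matter.

## Peak annotation and derived traits

A CE peak table (RMU position, AUC area per peak) is annotated against a
reference of RMU centers with a symmetric window of half-width
`tolerance` (default 1.5 RMU, closed at both ends; the assay literature
states no tolerance, so it is configurable). Reference windows may not
overlap at the configured tolerance, which makes assignment unambiguous by
construction. Every input peak ends in exactly one of three bins:
*assigned*, *excluded* (inside an exclusion zone, recorded with the zone's
reason — the default reference excludes (215, 225) around the known
carryover at RMU ≈ 220), or *residual* (returned to the caller, never
silently dropped). The peak near RMU ≈ 334 is assigned but deliberately
unidentified, because published libraries disagree on its identity; it
enters the normalisation denominator but no derived group.

Relative abundances are percent of total assigned area (identified +
unidentified). Residual peaks are outside the denominator. Group
definitions are composition predicates on the parsed Oxford name:
sialylated (S ≥ 1), terminal galactosylated (G ≥ 1 and S = 0 — sialic acid
caps the galactose terminus, so a sialylated structure is not "terminal"
galactosylated), agalactosylated (G = 0), fucosylated (F = 1), bisected
(B = 1). The first three partition the identified abundance, giving the
invariant `agal + term-gal + sialylated + unidentified = 100`.

The Gal-ratio is `G0 / (G1 + 2·G2)` with sialylated structures counted by
their galactose number. The weight 2 on di-galactosylated structures
follows the established formula in the prognostic-biomarker literature;
the source study cites that formula without restating it, so the form used
here is adopted explicitly and flagged. A zero denominator returns NaN (an
undefined sentinel), not an exception.

The shipped reference table (`data/rmu_reference_synthetic_v1.csv`) lists
the 20-structure biantennary IgG panel. Its RMU centers are **synthetic
placeholders** — only the 220 (carryover) and 334 (unidentified) positions
are anchored to the assay — and real analyses must substitute the
instrument's calibrated table via `RmuReference.from_csv`.

## Cohort statistics

- *Two-group tests* default to Welch's unequal-variance t test
  (`equal_var=True` restores the pooled form); the source analyses say
  only "unpaired t tests", and Welch is the safer default under group
  variance differences.
- *BH FDR* is the step-up procedure with monotonicity enforcement,
  order-preserving with the input. The FDR family is whatever panel the
  caller passes in one call — matching the practice of correcting across
  the markers tested within one analysis.
- *Interaction models* are OLS `y ~ A + B + A:B + covariates` via
  statsmodels, treatment coding for categoricals (reference level = first
  sorted; configurable by recoding the column), listwise deletion, and a
  rank check that names the collinear columns on failure. Glycan values
  enter on the raw percent scale.
- *Spearman matrices* use average-rank ties, two-sided p, and BH across
  the whole matrix as one family; pairs with < 4 complete observations or
  a constant column yield NaN. Partial correlations (e.g. adjusting for a
  cardiovascular risk score and aspirin use) use rank residualisation:
  rank-transform both variables and the covariates, regress out the
  covariate ranks, and correlate residuals — a standard partial-Spearman
  construction, chosen because the source does not name its
  partialization method.
- *Stratified runs* apply any analysis within strata (sex, menopause,
  visit), skipping undersized strata with a warning. Repeated-visit data
  are analysed by pooling visits into the slope machinery or collapsing to
  per-subject means; subject-level random effects are out of scope and a
  documented limitation.

## The glycan clock

One CV round standardises features, builds a penalty grid of 100
log-spaced values from `λ_max = max|Xᵀ(y−ȳ)|/n` (the smallest penalty with
an all-zero fit) down four decades, assigns 5 folds stratified by response
quintile (plain random folds by flag), and computes the CV error curve
with scikit-learn's coordinate-descent path solver. The one-SE rule picks
the largest penalty whose mean CV error is within one standard error of
the minimum; the selected set is the nonzero support of a full-data fit at
that penalty. Stability selection repeats this over seeds
`base_seed … base_seed + rounds − 1` — fold reshuffling is the *only*
randomness, so results are bit-reproducible given `base_seed` — and keeps
features chosen in ≥ 80 of 100 rounds.

The final clock is an **unpenalized OLS refit** on the selected features in
controls. The source does not state its refit choice; refitting makes the
zero-mean calibration ("average of zero difference between predicted and
chronological age" in controls) hold exactly, by the OLS-with-intercept
residual identity, rather than approximately. Acceleration is
predicted-minus-chronological age; the group test is a two-sided Welch t
test of case deltas against control deltas. Both the case-only SD and the
pooled case+control SD are reported, since summary SDs of this kind are
ambiguous between the two conventions. Nested models use the Gaussian LRT
`n·log(RSS_s/RSS_l)` against χ² with df = feature-count difference; its
null calibration is verified by simulation in the test suite.

Inflammatory markers join a combined clock only after passing an
age-correlation screen (Spearman, BH q < 0.05 within the marker panel, per
group), mirroring the practice of admitting only markers that track age.

## The synthetic world

The generator emulates, with one seeded RNG (same seed ⇒ bit-identical
bundle):

- four sex × HIV groups with sizes 235/254/253/243 and six age bands
  (≤45 … >65) in the reference design's proportions; ages uniform within
  bands;
- compositional profiles: baseline percent per structure (summing to 100
  with a 2% unidentified component) + per-structure age slopes ×
  (age − 50) + HIV and sex level shifts + optional subject random
  intercept + Gaussian noise (default SD 0.4%), clipped at zero and
  renormalised to 100. Slopes and shifts each sum to zero across
  structures so renormalisation is neutral;
- a planted acceleration δ (default 3.5 y): every structure with a
  generating age slope is shifted by δ × slope in HIV-positive samples —
  exactly the displacement δ extra years of aging would produce, so any
  linear clock trained on controls should read back δ. HIV *level* shifts
  are deliberately confined to zero-slope structures so that δ is the only
  clock-relevant displacement in the default world; this is what makes
  "planted acceleration" a parameter with an exact unit interpretation
  rather than a loose analogy;
- CE peak tables back-generated from the percentages at the reference RMU
  positions with a lognormal per-sample area scale (total AUC is
  arbitrary, exercising scale invariance) and a planted carryover peak at
  RMU 220;
- 22 inflammation markers as linear loadings on the derived groups plus
  noise (baselines at plausible pg/mL magnitudes);
- case/control outcome labels from a logistic model on derived traits
  (default: positive coefficients on agalactosylated and bisected,
  baseline case rate ≈ 31% so cases are the minority, as in a plaque
  case-control design).

What it does **not** emulate: logistic-normal compositional noise (additive
Gaussian + renormalisation is simpler and adequate for testing; real
profiles are heavier-tailed), batch/plate effects, assay drift,
missingness, subject dropout, or nonlinear age trends. A green recovery
test therefore establishes that the estimators read back the planted
parameters of a well-specified linear world — not that they are robust to
real-world artefacts.

## Numerical choices

- Peak windows closed at both ends; a peak exactly at center+tolerance is
  assigned.
- Mahalanobis matching covariance is shrunk toward the identity
  (`0.95·Σ + 0.05·I` on standardized covariates) so near-collinear
  covariates at small n cannot dominate the metric through a near-null
  eigenvalue; matching is greedy without replacement in a seeded random
  case order, the common "nearest neighbor" practice. Wald (not
  profile-likelihood) CIs for odds ratios.
- Logistic separation is surfaced as an error recommending a penalized
  fit rather than returning divergent estimates.
- The clock's λ grid (100 points, 4 decades) and age-quintile fold
  stratification are package choices where the source is silent; both are
  exposed as parameters.
- Full-precision (`repr`) serialization throughout the pipeline writer, so
  re-reading outputs and recomputing summaries is lossless.

## Scaling of long-running checks

The null-pipeline false-positive-rate property is run at 60 replicate
cohorts × 4 derived-group tests (binomial envelope on the pooled count)
rather than 500 replicates, and the clock's null behaviour is covered by
the δ = 0 arm of the 20-seed recovery suite; this keeps the default test
run within a practical time budget. The LRT null calibration runs at its
full 1,000 simulations.

## Known limitations

- No mixed-effects modelling for repeated measures (visits are pooled or
  collapsed to subject means).
- Branch-tagged isomers (e.g. `FA2[3]G1` vs `FA2[6]G1`) are distinct
  profile columns with identical compositions; group sums count both, and
  compositional round-trips drop the tag by design.
- The default RMU reference is a synthetic stand-in (see above).
- The matching stage assumes the exact-agreement strata leave enough pool;
  exhausted cases are reported in diagnostics rather than imputed.
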