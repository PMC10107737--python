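# Methods

`cpmreserve` implements connectome-based predictive modelling (CPM) of a
residual measure of cognitive reserve, together with a synthetic cohort
generator that provides ground truth for every stage. This note records
the model, the tunable parameters and their defaults, the numerical
choices, and what the synthetic tests do and do not establish.

## The reserve residual

Cognitive reserve is operationalised as the residual from an ordinary
least-squares regression of a global-cognition composite on age, sex,
grey-matter volume, hippocampal volume and mean cortical thickness.
Subjects whose cognition exceeds the structural prediction get positive
residuals (higher reserve). The composite is the mean of the five
within-sample z-scored subtest scores (verbal fluency, processing speed,
executive function, immediate and delayed memory); z-scoring uses the
sample SD (`ddof=1`). A sum-of-z-scores composite is available and
differs from the mean only by a factor of five, so the residual measure
is identical up to scale. Standardisation and the residual fit are
always within-dataset: a training and an external cohort each get their
own composite scaling and residual regression, mirroring how multi-site
studies construct the measure separately per site. Rows with missing
values in any fitted variable are dropped complete-case and counted in
`ResidualModel.n_dropped`.

Sex enters as a 0/1 code; because the regression contains an intercept,
any two-level coding yields identical residuals (tested).

## Connectivity and motion

Connectivity between two nodes is the Fisher z-transform
`z = arctanh(r)` of the Pearson correlation of their mean time series;
matrices are symmetric with an exactly zero diagonal. `|r|` is clipped
at `1 - 1e-7` before `arctanh`, so duplicated nodes produce a large
finite z (~8.4) rather than infinity — this keeps network-strength sums
finite. Framewise displacement (FWD) follows the Power convention: the
sum of absolute frame-to-frame differences of the six rigid-body
parameters, rotations converted to arc length on a 50 mm sphere
(configurable radius; the first frame is 0 by definition). Subjects are
excluded when mean FWD exceeds 0.4 mm or when their largest
frame-to-frame movement exceeds the 97.5th percentile of movements
pooled over the whole sample; both thresholds are configurable. Note
that the percentile rule is sample-relative: in any heterogeneous
sample some subject owns the extreme frames, so a nonzero exclusion
fraction is expected even in calm cohorts.

## The CPM core

Per cross-validation fold, on training subjects only:

1. **Edge selection.** Every unique edge (upper-triangle, row-major,
   i < j — the order recorded in every serialised model) is correlated
   with the target. With covariates, both edge and target are
   residualised on the covariates plus intercept and the residuals
   correlated (partial correlation). Two-sided p-values use the exact
   transformation `t = r sqrt(df / (1 - r^2))` with `df = n - 2 - c`
   for `c` covariates. Edges with `p < threshold` split by sign into
   positive and negative masks.
2. **Network strength.** Per subject, the masked full-matrix sum halved
   (each unique edge counted once). Combined strength is positive minus
   negative strength, and the combined tail is fitted as its own
   single-predictor model on that difference, not as a two-predictor
   model.
3. **Line fit and application.** `target = intercept + slope * strength`
   per tail, applied to the held-out subjects.

Accuracy is summarised per tail by Pearson r, R² and MAE. R² is taken
from the regression of observed on predicted; with a single predictor
and an intercept this equals the squared Pearson correlation, so the
two conventions coincide and R² cannot be negative here.

**Degenerate folds.** When a fold selects no edges (strengths constant)
the line is undefined; that fold's predictions fall back to the fold's
training-target mean and a warning is logged. This choice has a visible
consequence: under a null target, leave-one-out fold means
anti-correlate perfectly with the held-out value, so at ultra-strict
thresholds (where most folds are empty) the null distribution of the
out-of-fold r is biased negative and widely dispersed (measured at
threshold 1e-4, n = 200, 205 nodes: mean ≈ −0.15, SD ≈ 0.32). At
conventional thresholds (0.0009–0.01) the null is well behaved
(mean ≈ 0, SD ≈ 0.13). Permutation controls are therefore run at the
canonical threshold 0.0009 and averaged over several seeded
permutations; a single null draw is not a reliable check at any
threshold.

**Cross-validation schemes.** Leave-one-out, and repeated k-fold with
seeded shuffling into folds whose sizes differ by at most one; repeats
use sequential sub-streams spawned from the root seed. With k = n the
k-fold scheme reproduces leave-one-out bitwise (tested). Per-fold edge
statistics do not depend on the threshold, so threshold optimisation
computes them once and re-thresholds per grid point; the default grid is
{1e-4, 5e-4, 9e-4, 1e-3, 5e-3, 0.01, 0.05} (9e-4 included as a
conventional reported optimum for this family of analyses), the
selection criterion is the combined-tail out-of-fold r, and ties go to
the smaller threshold. A winning threshold whose combined correlation is
not significantly positive (p ≥ 0.05) is flagged non-significant rather
than suppressed.

**Aggregation and external application.** Fold masks combine under a
recorded rule — `intersection` (default; the consensus network of edges
selected in every fold), `union`, or `frequency` with a configurable
minimum — and line parameters are averaged arithmetically over the folds
where they were defined. External cohorts must share the node roster;
their strengths come from the aggregated masks and predictions from the
averaged lines. A negative out-of-sample correlation is reported but
flagged *not meaningful as prediction*: a model that anti-predicts has
no predictive interpretation regardless of its p-value.

## Validity testing

Face validity is a positive Pearson correlation (p < 0.05, configurable)
with a reserve proxy such as a verbal-intelligence score. The protective
effect uses three nested OLS models: cognition on age + sex + cortical
thickness (step 1), adding the candidate measure (step 2, independence
effect ΔR²), adding the thickness × measure interaction (step 3,
moderation effect ΔR²), with a nested-model F-test per increment. The
interaction is built from mean-centred components by default so the
step-3 increment is invariant to the location/scale of the main effects;
the raw product is available for sensitivity analysis. Age and sex do
not enter the product term. No multiple-testing correction is applied
across validity tests; the per-test α is configurable.

Group comparisons from printed summaries use the pooled-variance
two-sample t-test (pooled, not Welch: pooled reproduces the printed
statistics of the cohort tables this module is validated against) and
the Pearson chi-square without Yates continuity correction, for the
same reason. Proxy instruments with different maxima are put on a
common scale by min–max normalisation before comparison.

## The synthetic cohort generator

The generator emulates the data structure of a two-cohort ageing study:
one phenotype row and one symmetric 205×205 Fisher-z matrix per subject
(205 is the roster left after removing 63 cerebellum/brainstem nodes
from a 268-node parcellation), plus ground truth. The generative model:

- latent reserve `R ~ N(0, sigma_reserve²)`;
- age uniform on 20–80 y, sex Bernoulli(0.5); grey-matter volume,
  hippocampal volume and cortical thickness linear in age plus Gaussian
  noise, with intercepts/slopes chosen to land the means and SDs in the
  range typical of published ageing-cohort tables (e.g. thickness
  ≈ 2.6 ± 0.1 mm);
- a cognition signal = linear function of the five
  demographic/structural variables (`structural_coefficients`,
  default (−0.02, 0.1, 8.0, 100.0, 0.8)) + `R` + N(0,
  `sigma_cog_noise`²); the five subtests each add independent
  N(0, `sigma_subtest_noise`²);
- a proxy score loaded positively on reserve (33 + 6·R/σ_R + N(0, 4²)),
  NART-like in location and spread;
- every unique edge i.i.d. `N(edge_mean, sigma_edge²)` per subject on
  the Fisher-z scale; planted edges add (positive sign) or subtract
  (negative sign) `beta·R` with `beta` chosen in closed form so the
  population edge–reserve Pearson correlation equals `gamma`;
- per-subject FWD series: a lognormal per-subject mean (location
  0.15 mm, log-scale 0.4), rejection-sampled into the low- or
  high-motion regime (threshold 0.4 mm) according to
  `high_motion_fraction`, with gamma-distributed frames rescaled to hit
  the drawn mean exactly.

Defaults — 200 subjects, 205 nodes, 10 planted edges per sign,
`gamma = 0.4`, `sigma_reserve = 1`, `sigma_cog_noise = 0.3`,
`sigma_subtest_noise = 0.5` — define the standard test conditions used
throughout the suite and the acceptance script. Under them the reserve
residual correlates ~0.9 with the latent reserve and the combined-tail
LOOCV r lands around 0.6–0.8.

A single root seed drives one `numpy` Generator for all draws, so a
cohort is bit-reproducible from its config. An external cohort can
reuse a training cohort's planted edge indices (`planted_edges=`) to
share ground truth, and `flip_coupling=True` reverses the coupling sign
on those edges — the in-silico analogue of a population where the same
edges relate to reserve in the opposite direction, used to exercise the
negative-transfer failure mode.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: spatially autocorrelated parcels, the
empirical (non-Gaussian, positively shifted, dependent) distribution of
Fisher-z edges, scanner/site effects, distance-dependent motion
artefacts, non-linear age effects, and measurement models for the
subtests. Recovery results here demonstrate the pipeline's correctness,
not expected field performance; published real-data CPM correlations
for reserve-like phenotypes are far lower (r ≈ 0.3) than the planted
signal recovered here.

## Problem sizes and other choices

The test suite exercises most logic on 30–150-subject cohorts with
16–40-node rosters, and the acceptance checks on the full default
conditions (200 × 205); these sizes make every property measurable with
comfortable Monte-Carlo margins while the whole suite stays fast. The
canonical-network assignment (10 labels: MF, FP, DMN, Mot, VisI, VisII,
VAs, SAL, SC, CBL) is supplied as a data file, since atlas-to-network
mappings are external resources; `random_assignment` generates a
synthetic stand-in for testing and examples. The pipeline's stage
re-use is a light checksum gate: a stage records a hash of its
effective inputs and skips rewriting serialized outputs when the hash
and files are intact; it is not a workflow engine.

## Known limitations

- Edge selection assumes approximately Gaussian edge distributions for
  the t-based p-values; rank-based selection is not implemented.
- Empty-mask fallback (training mean) is one of several defensible
  conventions; dropping such folds instead would change null behaviour.
- The aggregation rule for external application is recorded but the
  field's own convention is ambiguous between union, intersection and
  frequency weighting; results can differ materially between rules on
  weak signals.
- Bootstrap-aggregated, multivariate and dynamic-connectivity CPM
  variants are out of scope.
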