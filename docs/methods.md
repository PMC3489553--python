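# Methods

## The measurement model

A trafficking study injects `Inj` cpm of radioiodinated lymphocytes i.v.
per mouse and, at a terminal time point, measures the RBC pellet of
arterial blood (volume `V_p` µl, counts `C_p` cpm) and each dissected
tissue (weight `w` g, counts `C_t` cpm). Labeled cells sediment with the
red cells, so all blood-side quantities are defined on the RBC pellet:

* `%Inj/ml = 100 · (C_p/V_p · 1000) / Inj` — percent of dose per ml of
  pellet. Note this is per ml of *pellet*, not of whole blood; the two
  differ by the hematocrit factor.
* `%Inj/g = 100 · C_t / Inj / w` — percent of dose per gram of tissue.
* tissue/RBC ratio `= (C_t/w) / (C_p/V_p)` µl/g — the volume of pellet
  whose activity equals one gram of tissue. It cancels `Inj` and the blood
  level, so it is insensitive to clearance and is the preferred response
  for between-group comparisons; `%Inj/g = ratio · %Inj/ml / 1000` exactly.

All cpm concentrations are carried per-µl internally and converted to
per-ml only where a formula demands it; a single canonical unit avoids
silent 1000× errors. No background subtraction is applied by default (an
optional correction clamps at zero with a warning, since counting data near
background can go negative). No radioactive-decay correction is applied:
studies span ≤150 min, short against the ~8-day half-life of the label.
Tissue/RBC ratios are within-animal quantities; pairing blood and tissue
samples across mice requires an explicit override flag.

Capillary depletion homogenizes cortex and separates vasculature (pellet)
from parenchyma (supernatant) on a dextran gradient. Each fraction's
`Fr/pellet = (cpm_Fr / cortex weight) / (pellet cpm/µl)` has the same µl/g
units as the uptake ratio, and the parenchymal percentage
`100·P/(P+C)` measures complete transit of the capillary wall. The two
percentages are complementary by construction.

Cell numbers are back-calculated as
`cells/g = (blood lymphocytes per µl whole blood / hematocrit) ×
tissue/RBC ratio`: dividing by hematocrit converts a whole-blood cell
concentration to a per-µl-of-pellet concentration, the denominator scale of
the ratio. Multiplying by organ weight gives cells per organ; `100/(%Inj/g)`
gives the number of injected cells per cell retained per gram.

Labeling QC reports specific activity (total cpm / cell count) and iodine
incorporation (QC-spin pellet / (pellet + supernatant)), with a pass flag
at a configurable threshold (default 0.90).

## Clearance

`log10(%Inj/ml)` is regressed on time by ordinary least squares (replicates
at a time point enter as individual observations). Half-time is
`log10(2)/(−slope)`; the constant is quoted as 0.301 in the user-facing
formula but computed as `log10(2)` to avoid rounding drift. Vd is
`100/10^intercept`. What counts as the "linear portion" of a clearance
curve is a judgment call, so the fit takes an explicit, recorded time
window (default: all points) and an optional drop of the earliest time
point. A series is classified as `no_measurable_clearance` when the slope
is ≥ 0 **or** the two-sided regression p-value is ≥ alpha (default 0.05,
configurable); the signed Pearson r is reported along with |r|, since a
clearing series has r < 0. The circulating/extravascular split at t = 0 is
`100·(vascular volume)/Vd` vs the remainder; Vd below the vascular volume
is capped with a warning rather than an error.

## Variance partitioning

The 2×2 design crosses the source of the cells (Cells) with the recipient
(Mouse). Sums of squares are computed as error-SS differences between
nested least-squares fits on sum-to-zero (effect-coded) design matrices;
F = MS_effect/MS_residual with p from the F distribution. For unbalanced
data the default is Type III under the sigma-restricted coding — chosen to
match the behavior of the commercial statistics packages this analysis is
usually run in — with Types I and II available and recorded in the output;
for balanced designs the three coincide (tested). Each effect's importance
is its eta-squared, `100·SS_effect/SS_total` (not partial eta-squared:
with total-SS normalization the effect and residual shares sum to 100% in
balanced designs, leaving an explicit residual share). A zero total SS
yields a degenerate table: all shares 0, F reported as missing. Missing
responses are dropped listwise with a logged count. An empty design cell
makes the interaction inestimable and raises an error naming the cell.

Newman–Keuls orders the group means and steps down: a pair spanning `r`
ordered means is tested with
`q = |m_i − m_j| / sqrt(MS_res/2 · (1/n_i + 1/n_j))` against the
studentized-range quantile at `(r, df_res)`, computed numerically from the
distribution function (no lookup tables). When a span's extreme pair is
non-significant, everything nested inside is declared non-significant
untested, which guarantees logical coherence. The unequal-`n` standard
error above is the common averaged-reciprocal generalization. With two
groups the procedure reduces exactly to the pooled two-sample t test
(`q = t·√2`).

Bonferroni-by-time compares two groups at each time of a time course using
the pooled residual of the group×time two-way table:
`t = |m_1 − m_2| / sqrt(MS_res·(1/n_1 + 1/n_2))`, adjusted
`p = min(1, T·p)` over the `T` testable time points. Times at which a
group is absent are skipped with a warning; with a single time point the
residual comes from the two-group one-way layout and the test is an
unadjusted pooled t test. Alpha defaults to 0.05 two-sided everywhere.

## The synthetic generator

`TraffickingScenario` encodes the study conditions: 150,000 cpm injected
per mouse at a specific activity of 53.3 cpm/cell; sampling times 5, 15,
30, 90, 150 min with n = 7 per group; a clearing host with half-time
171 min and a steady-state host (infinite half-time), both with intercept
log10(%Inj/ml) = 0.5; steady-state tissue/RBC base ratios of 10 µl/g for
brain and — anchored so that a ~2 %Inj/ml blood level puts spleen uptake in
the 15–20 %Inj/g range — 7,500 µl/g for spleen and 1,500 µl/g for lymph
nodes; organ weights 0.45 g (brain), 0.123 g (spleen), 5.2 mg (nodes).
Group effects are multiplicative fold-factors per tissue on the second
factor level (fold changes are the natural scale for positive biological
rates; observed strain effects are of the "2–3 times higher" kind).
Between-mouse variability is lognormal with mean 1; the default CV of 0.25
is a calibration choice made to produce group SEMs of realistic magnitude,
not a measured value, and is adjustable. Counting noise is Poisson on
every recorded cpm. RBC pellet volumes are drawn uniform 15–25 µl; only
concentrations matter downstream, so the draw is recorded but
inconsequential. All draws flow through one `numpy.random.Generator`, so a
scenario plus seed reproduces records byte-identically.

The generator emulates the statistical structure of the assay, not its
biology: tissue ratios are at steady state (no uptake kinetics within a
mouse), there is no cell death, label elution, recirculation between
compartments, or agent-level adhesion/diapedesis dynamics. Passing
recovery tests therefore demonstrates that the estimators are correct for
the stated model, not that real data satisfy the model.

## Pipeline behavior and numerical choices

`run_study_analysis` computes derived measures, fits clearance per host
level when at least two distinct sampling times are available (a
single-time factorial study records the host entry with reason
`insufficient_time_points`), and analyzes each tissue: host×time ANOVA
with Bonferroni post-tests when multiple times are present, otherwise the
Cells×Mouse factorial with eta-squared shares and a Newman–Keuls pass over
the four groups. Mice missing an injection check or blood sample are
excluded with a logged warning. Every output file embeds a hash of the
analysis configuration; floats are written at full precision in
`report.json` and at 10 significant digits in CSVs, and reruns on
identical input and configuration are byte-identical (no timestamps enter
the outputs, by design).

Numerical details: sums of squares are clamped at zero against float
cancellation; a table is flagged degenerate when the total SS is below
`1e-12·max(|y|,1)²·n`; studentized-range quantiles are cached per
`(alpha, r, df)`; F is reported as infinite (p = 0) when an effect SS is
positive against a zero residual, and missing when both are zero.

## Validation problem sizes

The simulation-based checks run at the scale of the study they emulate:
clearance recovery uses 500 replicate 19-point studies (lognormal CV 20%,
true half-time 171 min) and requires the median estimate within 15% of
truth with exact recovery at zero noise; ANOVA oracle equivalence compares
100 random balanced/unbalanced 2×2 datasets against a sum-coded regression
fit (statsmodels) at 1e-8; attribution recovery runs 200 replicates at
group sizes 7/6/5/7 with a 2.5-fold effect and CV 0.25 and requires the
generated side (Cells or Mouse) to carry the largest variance share in
≥95% of replicates; type-I control uses 2,000 null replicates against the
95% binomial band around alpha = 0.05; Newman–Keuls coherence is checked
on 1,000 random 4-group datasets.

## Known limitations and open points

* The fraction of cells in tissue beds computed from Vd ≈ 32 ml and a 2 ml
  vascular space is 93.75%; figures of ~97% sometimes quoted for such
  preparations do not follow from this arithmetic, and the package reports
  only the computed value.
* Serum radioactivity is accepted in input but enters no derived quantity.
* Published eta-squared shares for one and the same brain analysis appear
  variously as 31% and 34% depending on where they are quoted; nothing in
  the machinery here depends on resolving that, and the factor crossed
  with Cells is canonically named "Mouse" (it appears as "Tissue" in some
  renderings).
* No mixed-effects, repeated-measures, or multi-exponential clearance
  models: each mouse contributes one terminal observation per tissue and
  the clearance model is a single log-linear phase.
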