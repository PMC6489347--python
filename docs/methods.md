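# Methods

## The analysis model

The package treats relative validity as an agreement problem between ordinal
category assignments. Three instruments observe the same 28-day window of a
participant's diet:

- a daily app diary of standard servings for 10 food groups (fruit,
  vegetables, legumes, chicken/turkey, fish, red meat, soft drinks, sweets,
  prepared foods, beer), kept for 28 consecutive days with 21–28 days
  actually completed;
- 4 estimated dietary records on scheduled nonconsecutive days, 3 weekday +
  1 weekend;
- a food frequency questionnaire collecting, per group, one of the 6
  habitual-consumption categories directly.

Each instrument is mapped to standard servings per week and binned on a
shared category scheme. Agreement between the app and each reference is then
summarised per food group, per method pair, in the whole sample and in 12
binary covariate strata, by Spearman correlation, cross-classification
percentages, and linearly weighted kappa, each compared with conventional
pass thresholds (ρ ≥ 0.5; exact ≥ 35.0 %; exact+adjacent ≥ 75.0 %;
extreme ≤ 8.0 %; κ_w ≥ 0.41).

## Conversions

**App.** Mean servings/day is taken over *completed days only* — participants
with partial months contribute their completed-day average, with no
imputation — and multiplied by 7.

**Dietary records.** Weekly frequency = (mean over weekday records) × 5 +
(mean over weekend records) × 2. The 5/2 weights are fixed regardless of how
many records of each day type exist; the conversion is linear in the serving
values.

**FFQ.** Pass-through: the instrument already collects categories.

## Category schemes and cutpoints

The 6-level scheme's labels fix integer anchor ranges (1–2/week, 3–4/week,
5–6/week, 7–14/week for "once or twice a day", ≥21/week for "3 or more times
a day") but leave non-integer weekly frequencies ambiguous. We place the
cutpoints at the midpoints between adjacent label ranges —
[0,1), [1,2.5), [2.5,4.5), [4.5,6.5), [6.5,17.5), [17.5,∞) — which
reproduces every published worked assignment (5.32 → level 4, 3.5 → level 3,
3.2 → level 3, 5.4 → level 4). The collapsed 3-level scheme used for the
sensitivity illustration is [0,3), [3,6.5), [6.5,∞): "less than 3 times a
week" pins the first edge at 3, and the daily boundary reuses the 6.5
midpoint. Bins are half-open [low, high), so every nonnegative frequency
maps to exactly one level and the assignment is monotone.

Weekly frequencies are rounded to 10 decimals before binning so that binary
artefacts (0.76 × 7 = 5.319999…) land on the intended side of a cutpoint.

Custom schemes can be supplied as JSON `{k, labels, cutpoints}`.

## Statistics

**Spearman.** ρ is the Pearson correlation of mid-ranks, which handles the
heavy ties of 6-level data. The 95 % CI uses the Fisher z transform with
SE = 1/√(n−3); the two-sided p-value comes from z = atanh(ρ)·√(n−3). A
stratum where either instrument assigns everyone the same category has no
defined correlation; the cell is flagged (with a reason code) and excluded
from group averages rather than reported as 0.

**Cross-classification.** Exact = |i−j| = 0, exact+adjacent = |i−j| ≤ 1,
extreme = the two opposite-corner cells (level 1 vs level k, both orders).
Percentages are of the stratum's n.

**Weighted kappa.** Linear weights w_ij = 1 − |i−j|/(k−1) by default
(quadratic weights are available via `quadratic_weights`); linear partial
credit matches the adjacency emphasis of the cross-classification
criterion. The SE is the Fleiss–Cohen–Everitt asymptotic form under
H₀: κ = 0, and the p-value is the one-sided normal test of κ/SE₀ (agreement
worse than chance is not the alternative of interest). Degenerate marginals
(p_e = 1, all mass in one cell) make κ undefined; the cell is flagged.

**Averages.** The "average" row per stratum is the unweighted mean of each
statistic over the 10 food groups, excluding flagged cells; no CI, SE or p
is attached to an average.

**Interpretation bands.** Correlations: |ρ| ≥ 0.5 strong, ≥ 0.30 moderate,
≥ 0.10 weak, else negligible. Kappa bands are applied to the 2-decimal
rounded value (the reporting precision): > 0.80 very good, 0.61–0.80 good,
0.41–0.60 moderate, 0.21–0.40 fair, below poor — closed intervals, so there
are no gaps at the printed boundaries.

**Strata.** Six binary axes (age, gender, occupation, smoking, activity,
BMI). Boundary values — age 25, activity 150 min/week, BMI 25 kg/m² — are
assigned to the "≥" stratum, matching the stratum labels; no rule for
boundary cases is stated in the published tables, so the label convention is
a design choice here. Strata with fewer than 4 participants are flagged and
reported without statistics, never silently dropped.

**Rounding.** Rendered tables round half-away-from-zero: percentages to 1
decimal, correlations and kappas to 2 — matching how such tables are
conventionally printed (68.47 % → 68.5 %).

## The synthetic cohort generator

No raw data from the motivating study exist publicly, so the generator
emulates the *data-generating process the analysis presupposes*, with the
study's printed cohort structure as defaults:

- **Covariates** (n = 203 default): independent draws from the study
  marginals — 56.7 % female, 57.1 % employees, 16.3 % smokers, 66.5 % with
  ≥ 150 min/week activity, 34.0 % with BMI ≥ 25; age normal (32.0, 11.4)
  truncated above 18. Continuous activity and BMI values are drawn
  consistently with the drawn binary stratum.
- **Latent intake**: per participant × group, a weekly event rate λ from a
  log-normal with group-specific median (7/week for fruit and vegetables
  down to 1.5/week for beer and prepared foods, spanning all six categories)
  and dispersion σ ≈ 0.6–1.1. The log-normal/Poisson combination is a
  standard habitual-intake model producing realistic between- and
  within-person variation; the study specifies no generative model, so this
  is the package's choice.
- **Truth diary**: daily event counts Poisson(λ/7), multiplied by a weekend
  factor on calendar positions day mod 7 ∈ {6, 0} (beer 2.0×, soft drinks
  1.3×, others 1×); each event contributes a serving size from a discrete
  grid (default 0.5/1/1.5 with probabilities 0.25/0.6/0.15). The calendar
  anchoring gives exactly the 5:2 weekday:weekend ratio the record
  conversion assumes.
- **App observation**: the diary equals truth on completed days; the number
  of completed days follows the study's empirical distribution (58.1 % at
  28 days … 2.0 % at 21), and the completed subset is uniform — the
  published counts say nothing about runs of missed days, so no serial
  structure is imposed.
- **Record observation**: 3 weekday + 1 weekend day, pairwise nonadjacent,
  uniform over valid schedules (rejection sampling); values copy the truth,
  each entry independently perturbed by ±1 grid step with probability
  `dr_noise` (floored at 0, so an error at 0 goes up).
- **FFQ observation**: the true category of the *realized* 28-day weekly
  mean, shifted ±1 level with probability `ffq_noise` (optionally ±2 with
  `ffq_noise2`), clamped to the scale. Error acts on the category scale
  because that is what the instrument collects.

All noise parameters are knobs, not estimates — the study reports no error
model. Defaults (`ffq_noise=0.2`, `dr_noise=0.1`) produce plausible
imperfect agreement; setting them to 0 with full completion makes app and
FFQ categories *identical by construction*, the parameter-recovery anchor
used in testing. A single `numpy` Generator seeded from the config drives
everything, so outputs are byte-identical across runs with the same seed.

### What passing tests do and do not show

The generator draws covariates independently of intake and applies
homogeneous, nondifferential observation error. Real cohorts have
correlated covariates, diet–covariate associations, social-desirability and
differential misreporting, serial completion patterns, and seasonal drift —
none of which is modelled (per-stratum noise overrides exist as hooks but
have no defaults). Tests on synthetic cohorts therefore verify that the
*pipeline computes the intended quantities correctly*, not that any
instrument is valid in a real population.

## Problem sizes and numerical choices

The test suite uses cohorts of 15–200 participants and 50 Monte-Carlo
replicates for the noise-monotonicity check — sizes at which the binomial/
Poisson tolerances used (3 SDs) are informative while the whole suite runs
in under a minute of simulation time. Statistical oracle equivalence is
checked against independent double-sum implementations, scipy's rank
machinery, and scikit-learn's `cohen_kappa_score` to 1e-12.

## Known limitations

- Kappa p-values use the H₀ standard error and a one-sided normal test;
  published tables in this field often print only significance thresholds,
  and other software may report slightly different p's (not CIs for κ).
- The Fisher-z CI for ρ is approximate under heavy ties at small n.
- Confidence intervals for cross-classification percentages are not
  computed (the tables this layout mirrors print none).
- Strata are analysed marginally; no between-stratum inference is offered.
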