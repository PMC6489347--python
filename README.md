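# dietagree

Relative-validity analysis for short dietary-recall instruments.

A recurring problem in nutritional epidemiology: a new, low-burden dietary
instrument (here, a smartphone app on which participants record the standard
servings of 10 food groups consumed each day for 28 consecutive days) must be
validated before use — but true intake is unmeasurable, so validation is
*relative*: agreement with imperfect reference instruments. This package
implements that analysis for two references — a semiquantitative food
frequency questionnaire (FFQ) and 4 estimated dietary records (DRs, 3 weekday
+ 1 weekend day) — as a tested, reusable pipeline for statisticians and
nutrition researchers running or re-analysing such validation studies.

## The method

All three instruments are expressed as habitual weekly consumption per food
group and binned on a common ordinal scale (default 6 levels, "less than once
a week" … "3 or more times a day"):

- **app diary**: weekly frequency = mean servings/day over completed days × 7
  (e.g. 0.76/day → 5.32/week → "5–6 times a week");
- **dietary records**: weekly frequency = (weekday mean × 5) + (weekend mean
  × 2);
- **FFQ**: reported categories used as-is.

For each food group *g*, method pair, and stratum, agreement between the
category vectors *x, y* is measured by:

- **Spearman rank correlation** ρ, computed as the Pearson correlation of
  mid-ranks (tie-corrected), with a Fisher-z 95 % CI (SE = 1/√(n−3)) and a
  two-sided p-value;
- **cross-classification**: % exact (x=y), % exact+adjacent (|x−y| ≤ 1), and
  % extreme disagreement (the two opposite-corner cells);
- **weighted Cohen kappa** κ_w = (p_o − p_e)/(1 − p_e) with linear weights
  w_ij = 1 − |i−j|/(k−1), p_o = Σ w_ij p_ij, p_e = Σ w_ij p_i·p_·j, and the
  Fleiss–Cohen–Everitt asymptotic SE under H₀: κ = 0.

A cell **passes** when ρ ≥ 0.5, exact ≥ 35.0 %, exact+adjacent ≥ 75.0 %,
extreme ≤ 8.0 %, and κ_w ≥ 0.41. The battery runs on the whole sample and in
12 binary strata (age </≥ 25 y, gender, occupation, smoking, physical
activity </≥ 150 min/week, BMI </≥ 25 kg/m²).

Because no participant-level data from the motivating study are public, the
package includes a first-class **synthetic cohort generator**: log-normal
latent weekly intake rates per participant × group, Poisson day-to-day
variation over 28 days, empirical app-completion patterns (21–28 days), the
4-record scheduling rule, and controllable FFQ/DR observation error — so the
whole pipeline is testable end to end, including exact parameter recovery
when observation noise is switched off.

## Worked example

```python
from dietagree import CohortConfig, run_validation_study

cfg = CohortConfig(n_participants=120, seed=7)
data, report = run_validation_study(cfg)
row = report.select(stratum_axis="all", method_pair="app_vs_dr",
                    food_group="average")[0].summary
print(f"mean SCC {row.scc:.2f}, exact {row.exact_pct:.1f}%, "
      f"exact+adjacent {row.exact_adjacent_pct:.1f}%, "
      f"extreme {row.extreme_pct:.1f}%, weighted kappa {row.kappa_w:.2f}")
```

prints

```
mean SCC 0.62, exact 40.1%, exact+adjacent 85.2%, extreme 0.0%, weighted kappa 0.46
```

— averaged over the 10 food groups, app-assigned and record-assigned
categories correlate strongly (ρ ≥ 0.5), 40 % of participants land in the
same category and 85 % within one, nobody is classified at opposite extremes,
and chance-corrected agreement is moderate: all five criteria pass. The
app-vs-FFQ pair agrees more closely (mean κ_w 0.85 under default noise)
because the records subsample only 4 of 28 highly variable days. The
`examples/` scripts walk through conversion, the statistics, the generator,
and the full pipeline; a thin CLI (`dietagree simulate|convert|agree|report|
pipeline`) wraps the same functions for shell use.

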