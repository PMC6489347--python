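"""Generate a synthetic validation cohort and inspect its structure.

Each participant gets a latent habitual intake per food group, 28 days of
Poisson-varying true consumption, and three noisy observations of it: the
app diary (with realistic incomplete days), the 4 scheduled dietary records,
and the FFQ.  With all observation noise off, the app and FFQ categories
coincide exactly — the generator's parameter-recovery anchor.
"""

from dietagree import CohortConfig, simulate_study_data

# defaults mirror the study cohort: n=203, 56.7% women, 58.1% completing all
# 28 days, ten groups from near-daily fruit to infrequent beer
data = simulate_study_data(CohortConfig(n_participants=50, seed=42))

print(f"participants: {len(data.participants)}")
print(f"female share: "
      f"{sum(p.gender == 'female' for p in data.participants) / 50:.2f}")
days = [s.completed.sum() for s in data.simulations.values()]
print(f"completed days: min {min(days)}, max {max(days)}, "
      f"full-month completers {sum(d == 28 for d in days)}/50")

truth = data.truth_frame()
fruit = truth[truth.food_group == "fruit"]
print(f"fruit: median latent rate {fruit.lambda_weekly.median():.1f}/week, "
      f"median realized mean {fruit.realized_weekly_mean.median():.1f}/week")

agree = (data.app_categories == data.ffq_categories).to_numpy().mean()
print(f"app-vs-FFQ category agreement with default FFQ noise: {agree:.2f}")

noise_free = simulate_study_data(
    CohortConfig(n_participants=50, ffq_noise=0.0, dr_noise=0.0,
                 completion={28: 1.0}, seed=42)
)
identical = noise_free.app_categories.equals(noise_free.ffq_categories)
print(f"with error-free observation the app and FFQ categories are "
      f"identical: {identical}")
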