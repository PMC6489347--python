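"""Convert each instrument's raw records to habitual-consumption categories.

Builds the two classic conversion examples — an app diary averaging 0.76
servings/day and a 4-day dietary-record set — and shows how both end up on
the shared 6-level weekly-frequency scale that makes the instruments
comparable.
"""

import numpy as np

from dietagree import (
    DEFAULT_FOOD_GROUPS,
    SCHEME6,
    AppDiary,
    DietaryRecordEntry,
    DietaryRecordSet,
    FFQResponse,
    categorize,
    categorize_instrument,
    mean_daily_servings,
    weekly_from_daily,
    weekly_from_dr,
)

# --- app diary: 28 completed days of vegetables averaging 0.76 servings/day
rng = np.random.default_rng(0)
daily = rng.uniform(0, 1.5, 28)
daily *= 0.76 * 28 / daily.sum()  # rescale so the 28-day mean is exactly 0.76
servings = np.zeros((28, len(DEFAULT_FOOD_GROUPS)))
servings[:, DEFAULT_FOOD_GROUPS.index("vegetables")] = daily
diary = AppDiary("P0001", servings, np.ones(28, dtype=bool))

mean_day = mean_daily_servings(diary, "vegetables")
weekly = weekly_from_daily(mean_day)
cat = categorize(weekly, SCHEME6)
print(f"app diary:  {mean_day:.2f} servings/day  ->  {weekly:.2f}/week  "
      f"->  level {cat.level} ({cat.label})")
# 0.76/day is 5.32 servings/week, which lands in "5-6 times a week".

# --- dietary records: red meat 0, 0.5, 1 on weekdays and 0.5 at the weekend
records = DietaryRecordSet(
    "P0001",
    [
        DietaryRecordEntry(2, "weekday", {"red meat": 0.0}),
        DietaryRecordEntry(9, "weekday", {"red meat": 0.5}),
        DietaryRecordEntry(16, "weekday", {"red meat": 1.0}),
        DietaryRecordEntry(27, "weekend", {"red meat": 0.5}),
    ],
)
weekly_dr = weekly_from_dr(records, "red meat")
cat_dr = categorize(weekly_dr, SCHEME6)
print(f"records:    weekday mean 0.50 x5 + weekend mean 0.50 x2  "
      f"->  {weekly_dr:.1f}/week  ->  level {cat_dr.level} ({cat_dr.label})")

# --- FFQ: already categorical, passes through unmodified
ffq = FFQResponse("P0001", {"vegetables": 4, "red meat": 3}, SCHEME6)
cats = categorize_instrument(ffq, SCHEME6)
print(f"ffq:        reported levels pass through -> "
      f"{ {g: c.level for g, c in cats.items()} }")
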