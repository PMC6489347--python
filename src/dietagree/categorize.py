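"""Instrument-to-category conversion.

All three instruments are expressed as habitual weekly consumption and then
binned on a common category scheme:

* app diary — mean daily servings over completed days, times 7;
* dietary records — weekday mean × 5 plus weekend mean × 2 (the printed
  conversion formula, fixed regardless of how many days of each type were
  recorded);
* FFQ — used as reported (the instrument already collects categories).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .core import (
    AppDiary,
    CategoryScheme,
    DietaryRecordSet,
    FFQResponse,
    FrequencyCategory,
)

__all__ = [
    "mean_daily_servings",
    "weekly_from_daily",
    "mean_weekday_servings",
    "weekly_from_dr",
    "categorize",
    "categorize_instrument",
]

# Weekly frequencies are compared to cutpoints after rounding at this many
# decimals so that products like 0.76*7 land deterministically on a bin edge.
_BOUNDARY_DECIMALS = 10


def mean_daily_servings(diary: AppDiary, group: str) -> float:
    """Arithmetic mean of daily servings for a group, completed days only."""
    vals = diary.group_values(group)
    if vals.size == 0:
        raise ValueError("diary has no completed days")
    return float(np.mean(vals))


def weekly_from_daily(mean_daily: float) -> float:
    """Scale a mean daily consumption to standard servings per week."""
    if mean_daily < 0:
        raise ValueError(f"mean daily servings must be nonnegative, got {mean_daily}")
    return mean_daily * 7.0


def mean_weekday_servings(records: DietaryRecordSet, group: str) -> float:
    """Mean servings per weekday over the weekday record entries."""
    vals = [e.servings.get(group, 0.0) for e in records.weekday_entries]
    if not vals:
        raise ValueError("record set has no weekday entries")
    return float(np.mean(vals))


def weekly_from_dr(records: DietaryRecordSet, group: str) -> float:
    """Weekly frequency from dietary records: weekday mean ×5 + weekend mean ×2."""
    wd = [e.servings.get(group, 0.0) for e in records.weekday_entries]
    we = [e.servings.get(group, 0.0) for e in records.weekend_entries]
    if not wd or not we:
        raise ValueError("record set must contain both weekday and weekend days")
    return float(np.mean(wd)) * 5.0 + float(np.mean(we)) * 2.0


def categorize(weekly: float, scheme: CategoryScheme) -> FrequencyCategory:
    """Assign a weekly frequency to its habitual-consumption category.

    Bins are half-open [low, high); the assignment is monotone nondecreasing
    in the weekly frequency and every nonnegative frequency maps to exactly
    one level.
    """
    if weekly < 0:
        raise ValueError(f"weekly frequency must be nonnegative, got {weekly}")
    w = round(weekly, _BOUNDARY_DECIMALS)
    level = int(np.searchsorted(scheme.cutpoints, w, side="right")) + 1
    return FrequencyCategory(level=level, scheme=scheme)


def categorize_instrument(
    data: AppDiary | DietaryRecordSet | FFQResponse,
    scheme: CategoryScheme,
    groups: tuple[str, ...] | None = None,
) -> Mapping[str, FrequencyCategory]:
    """Per-food-group categories for any instrument record.

    App diaries and dietary records are converted to weekly frequencies
    first; FFQ responses pass through unchanged.
    """
    if isinstance(data, AppDiary):
        gs = groups or data.groups
        return {
            g: categorize(weekly_from_daily(mean_daily_servings(data, g)), scheme)
            for g in gs
        }
    if isinstance(data, DietaryRecordSet):
        if groups is None:
            seen: list[str] = []
            for e in data.entries:
                for g in e.servings:
                    if g not in seen:
                        seen.append(g)
            gs = tuple(seen)
        else:
            gs = groups
        return {g: categorize(weekly_from_dr(data, g), scheme) for g in gs}
    if isinstance(data, FFQResponse):
        if data.scheme != scheme:
            raise ValueError("FFQ response was collected on a different scheme")
        gs = groups or tuple(data.levels)
        return {
            g: FrequencyCategory(level=int(data.levels[g]), scheme=scheme)
            for g in gs
        }
    raise TypeError(f"unsupported instrument record {type(data).__name__}")
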