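"""Domain types shared by every stage of the validity analysis.

The package compares a daily short dietary recall (an app diary kept for 28
consecutive days) against two reference instruments — a food frequency
questionnaire (FFQ) and a set of 4 estimated dietary records (DRs) — by
expressing all three on a common ordinal scale of habitual weekly consumption
and measuring agreement.  This module holds the instrument records, the
category schemes, the participant covariates with their binary analysis
strata, and the interpretation bands for correlation and kappa statistics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "DEFAULT_FOOD_GROUPS",
    "FoodGroup",
    "FoodGroupRegistry",
    "Participant",
    "AppDiary",
    "DietaryRecordEntry",
    "DietaryRecordSet",
    "FFQResponse",
    "CategoryScheme",
    "FrequencyCategory",
    "AgreementSummary",
    "CriteriaVerdict",
    "UndefinedStatisticError",
    "interpret_scc",
    "interpret_kappa",
    "stratum_of",
    "STRATUM_AXES",
    "round_half_away",
]

#: The ten food groups monitored by the study instruments, spanning
#: near-daily items (fruit, vegetables) to infrequent ones (beer, legumes).
DEFAULT_FOOD_GROUPS: tuple[str, ...] = (
    "fruit",
    "vegetables",
    "legumes",
    "chicken/turkey",
    "fish",
    "red meat",
    "soft drinks",
    "sweets",
    "prepared foods",
    "beer",
)


class UndefinedStatisticError(ValueError):
    """A statistic is mathematically undefined for the given input.

    Raised e.g. for Spearman correlation on a constant vector or weighted
    kappa on degenerate marginals.  Callers that aggregate over food groups
    catch this and flag the cell instead of reporting a number.
    """


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (68.47 -> 68.5 at 1 decimal).

    Matches the rounding used by the printed tables; Python's built-in
    banker's rounding would send 0.675 to 0.67.
    """
    if not math.isfinite(x):
        return x
    factor = 10.0**ndigits
    scaled = x * factor
    # nudge by an epsilon scaled to the value to defeat binary representation
    # artefacts like 68.465 stored as 68.46499999...
    eps = math.copysign(1e-9 * max(1.0, abs(scaled)), scaled)
    return math.floor(abs(scaled + eps) + 0.5) * math.copysign(1.0, x) / factor


@dataclass(frozen=True)
class FoodGroup:
    """A monitored food group, identified by its name."""

    name: str

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise ValueError("food group name must be non-empty")


class FoodGroupRegistry:
    """Ordered registry of food groups; extensible, names unique."""

    def __init__(self, names: Iterable[str] = DEFAULT_FOOD_GROUPS) -> None:
        names = tuple(names)
        if len(set(names)) != len(names):
            raise ValueError("food group names must be unique")
        self._groups = tuple(FoodGroup(n) for n in names)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self._groups)

    def __len__(self) -> int:
        return len(self._groups)

    def __iter__(self):
        return iter(self._groups)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass(frozen=True)
class Participant:
    """Study participant covariates used to define the analysis strata."""

    id: str
    age: float
    gender: str  # "female" | "male"
    occupation: str  # "student" | "employee"
    smoker: str  # "no" | "yes"
    activity_min_per_week: float
    bmi: float

    def __post_init__(self) -> None:
        if self.age <= 18:
            raise ValueError(f"age must exceed 18, got {self.age}")
        if self.bmi <= 0:
            raise ValueError(f"bmi must be positive, got {self.bmi}")
        if self.gender not in ("female", "male"):
            raise ValueError(f"unknown gender {self.gender!r}")
        if self.occupation not in ("student", "employee"):
            raise ValueError(f"unknown occupation {self.occupation!r}")
        if self.smoker not in ("no", "yes"):
            raise ValueError(f"smoker must be 'no'/'yes', got {self.smoker!r}")
        if self.activity_min_per_week < 0:
            raise ValueError("activity_min_per_week must be nonnegative")


#: Binary stratification axes with the labels the report tables print.
STRATUM_AXES: dict[str, tuple[str, str]] = {
    "age": ("<25", "≥25"),
    "gender": ("females", "males"),
    "occupation": ("students", "employees"),
    "smoking": ("no", "yes"),
    "activity": ("≥150", "<150"),
    "bmi": ("<25", "≥25"),
}


def stratum_of(p: Participant, axis: str) -> str:
    """Assign a participant to a binary stratum on the given axis.

    Boundary values (age 25, activity 150 min/week, BMI 25 kg/m²) go to the
    "≥" stratum, matching the printed stratum labels.
    """
    if axis == "age":
        return "<25" if p.age < 25 else "≥25"
    if axis == "gender":
        return "females" if p.gender == "female" else "males"
    if axis == "occupation":
        return "students" if p.occupation == "student" else "employees"
    if axis == "smoking":
        return p.smoker
    if axis == "activity":
        return "≥150" if p.activity_min_per_week >= 150 else "<150"
    if axis == "bmi":
        return "<25" if p.bmi < 25 else "≥25"
    raise ValueError(f"unknown stratification axis {axis!r}")


@dataclass
class AppDiary:
    """A participant's 28-day app diary of daily standard servings.

    ``servings`` is a (28, n_groups) array; rows for days the participant did
    not complete are NaN and excluded from every computation.  ``completed``
    is the per-day completion mask.
    """

    participant_id: str
    servings: np.ndarray
    completed: np.ndarray
    groups: tuple[str, ...] = DEFAULT_FOOD_GROUPS

    N_DAYS = 28

    def __post_init__(self) -> None:
        self.servings = np.asarray(self.servings, dtype=float)
        self.completed = np.asarray(self.completed, dtype=bool)
        if self.servings.shape != (self.N_DAYS, len(self.groups)):
            raise ValueError(
                f"servings must be ({self.N_DAYS}, {len(self.groups)}), "
                f"got {self.servings.shape}"
            )
        if self.completed.shape != (self.N_DAYS,):
            raise ValueError("completed mask must have one entry per day")
        n_done = int(self.completed.sum())
        if not 1 <= n_done <= self.N_DAYS:
            raise ValueError("diary must have between 1 and 28 completed days")
        done = self.servings[self.completed]
        if np.isnan(done).any():
            raise ValueError("completed days must have serving values")
        if (done < 0).any():
            raise ValueError("servings must be nonnegative")
        # uncompleted days carry no data
        self.servings[~self.completed] = np.nan

    @property
    def n_completed(self) -> int:
        return int(self.completed.sum())

    def group_values(self, group: str) -> np.ndarray:
        """Serving values for one group over completed days, in day order."""
        j = self.groups.index(group)
        return self.servings[self.completed, j]


@dataclass(frozen=True)
class DietaryRecordEntry:
    """One scheduled dietary-record day: servings per food group."""

    day_index: int
    day_type: str  # "weekday" | "weekend"
    servings: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.day_type not in ("weekday", "weekend"):
            raise ValueError(f"day_type must be weekday/weekend, got {self.day_type!r}")
        if any(v < 0 for v in self.servings.values()):
            raise ValueError("servings must be nonnegative")


@dataclass
class DietaryRecordSet:
    """The 4 scheduled dietary records: 3 weekday + 1 weekend day by default.

    Day indices must be distinct and pairwise nonadjacent (the records are
    scheduled on nonconsecutive days).  Other weekday/weekend counts are
    accepted as long as both day types are present.
    """

    participant_id: str
    entries: Sequence[DietaryRecordEntry]

    def __post_init__(self) -> None:
        self.entries = tuple(self.entries)
        days = [e.day_index for e in self.entries]
        if len(set(days)) != len(days):
            raise ValueError("record day indices must be distinct")
        days_sorted = sorted(days)
        for a, b in zip(days_sorted, days_sorted[1:]):
            if b - a < 2:
                raise ValueError(
                    f"record days must be nonconsecutive, got {a} and {b}"
                )
        if not self.weekday_entries or not self.weekend_entries:
            raise ValueError("need at least one weekday and one weekend record")

    @property
    def weekday_entries(self) -> tuple[DietaryRecordEntry, ...]:
        return tuple(e for e in self.entries if e.day_type == "weekday")

    @property
    def weekend_entries(self) -> tuple[DietaryRecordEntry, ...]:
        return tuple(e for e in self.entries if e.day_type == "weekend")


@dataclass
class FFQResponse:
    """FFQ selections: one habitual-consumption category per food group.

    FFQ data are used as reported — the instrument already collects the
    common categories, so no conversion is applied.
    """

    participant_id: str
    levels: Mapping[str, int]
    scheme: "CategoryScheme"

    def __post_init__(self) -> None:
        for g, lv in self.levels.items():
            if not 1 <= int(lv) <= self.scheme.k:
                raise ValueError(
                    f"level {lv} for {g!r} outside 1..{self.scheme.k}"
                )


@dataclass(frozen=True)
class CategoryScheme:
    """Ordinal habitual-consumption scale defined by weekly-frequency bins.

    ``cutpoints`` are the k−1 strictly increasing weekly-frequency thresholds;
    level i covers the half-open bin [cutpoints[i-2], cutpoints[i-1]) with
    level 1 starting at 0 and level k unbounded above.
    """

    name: str
    labels: tuple[str, ...]
    cutpoints: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.cutpoints) != len(self.labels) - 1:
            raise ValueError("need exactly k-1 cutpoints for k labels")
        if len(self.labels) < 2:
            raise ValueError("a scheme needs at least 2 levels")
        if any(b <= a for a, b in zip(self.cutpoints, self.cutpoints[1:])):
            raise ValueError("cutpoints must be strictly increasing")
        if self.cutpoints[0] <= 0:
            raise ValueError("first cutpoint must be positive")

    @property
    def k(self) -> int:
        return len(self.labels)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"name": self.name, "k": self.k, "labels": list(self.labels),
                 "cutpoints": list(self.cutpoints)},
                indent=2, ensure_ascii=False,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CategoryScheme":
        d = json.loads(Path(path).read_text())
        if d.get("k") is not None and d["k"] != len(d["labels"]):
            raise ValueError("k does not match number of labels")
        return cls(
            name=d.get("name", "custom"),
            labels=tuple(d["labels"]),
            cutpoints=tuple(float(c) for c in d["cutpoints"]),
        )


# Six-level scheme: the study's sextile scale.  The label ranges fix integer
# anchors (once or twice a week = 1-2, 3-4 times, 5-6 times, 1-2/day = 7-14,
# 3+/day = 21+); cutpoints sit at the midpoints between adjacent ranges so
# that frequencies like 5.32 or 3.5 land on the category the labels imply.
SCHEME6 = CategoryScheme(
    name="scheme6",
    labels=(
        "less than once a week",
        "once or twice a week",
        "3-4 times a week",
        "5-6 times a week",
        "once or twice a day",
        "3 or more times a day",
    ),
    cutpoints=(1.0, 2.5, 4.5, 6.5, 17.5),
)

# Collapsed three-level scheme used for the sensitivity illustration:
# less than 3 times a week / 3-6 times a week / once or more per day.
SCHEME3 = CategoryScheme(
    name="scheme3",
    labels=(
        "less than 3 times a week",
        "3-6 times a week",
        "once or more times a day",
    ),
    cutpoints=(3.0, 6.5),
)

SCHEMES: dict[str, CategoryScheme] = {"scheme6": SCHEME6, "scheme3": SCHEME3}


@dataclass(frozen=True)
class FrequencyCategory:
    """An assigned ordinal consumption category on a scheme."""

    level: int
    scheme: CategoryScheme

    def __post_init__(self) -> None:
        if not 1 <= self.level <= self.scheme.k:
            raise ValueError(f"level {self.level} outside 1..{self.scheme.k}")

    @property
    def label(self) -> str:
        return self.scheme.labels[self.level - 1]


@dataclass
class AgreementSummary:
    """Agreement statistics for one food group × method pair × stratum."""

    food_group: str
    method_pair: str  # "app_vs_ffq" | "app_vs_dr"
    stratum: str
    n: int
    scc: float | None = None
    scc_ci_low: float | None = None
    scc_ci_high: float | None = None
    scc_p: float | None = None
    exact_pct: float | None = None
    exact_adjacent_pct: float | None = None
    extreme_pct: float | None = None
    kappa_w: float | None = None
    kappa_se: float | None = None
    kappa_p: float | None = None

    def __post_init__(self) -> None:
        if self.scc is not None and not -1 - 1e-12 <= self.scc <= 1 + 1e-12:
            raise ValueError("scc outside [-1, 1]")
        if self.exact_pct is not None and self.exact_adjacent_pct is not None:
            if not (0 <= self.exact_pct <= self.exact_adjacent_pct <= 100 + 1e-9):
                raise ValueError("need 0 <= exact <= exact+adjacent <= 100")
        if self.extreme_pct is not None and not 0 <= self.extreme_pct <= 100:
            raise ValueError("extreme_pct outside [0, 100]")
        if self.kappa_w is not None and self.kappa_w > 1 + 1e-12:
            raise ValueError("weighted kappa cannot exceed 1")


@dataclass(frozen=True)
class CriteriaVerdict:
    """The five acceptance criteria for one summary row.

    A method pair passes for a cell when SCC ≥ 0.5, exact agreement ≥ 35.0%,
    exact+adjacent ≥ 75.0%, extreme disagreement ≤ 8.0%, and weighted
    kappa ≥ 0.41.
    """

    scc_ok: bool
    exact_ok: bool
    adjacent_ok: bool
    extreme_ok: bool
    kappa_ok: bool

    @property
    def overall(self) -> bool:
        return (
            self.scc_ok and self.exact_ok and self.adjacent_ok
            and self.extreme_ok and self.kappa_ok
        )


def interpret_scc(rho: float) -> str:
    """Correlation strength band: strong / moderate / weak / negligible.

    Cohen's cutoffs on |rho|: ≥0.50 strong, ≥0.30 moderate, ≥0.10 weak.
    """
    if not -1 <= rho <= 1:
        raise ValueError(f"correlation must lie in [-1, 1], got {rho}")
    a = abs(rho)
    if a >= 0.5:
        return "strong"
    if a >= 0.30:
        return "moderate"
    if a >= 0.10:
        return "weak"
    return "negligible"


def interpret_kappa(kw: float) -> str:
    """Weighted-kappa agreement band on the conventional closed intervals.

    Values are compared after rounding to 2 decimals (the reporting
    precision): >0.80 very good, 0.61–0.80 good, 0.41–0.60 moderate,
    0.21–0.40 fair, below that poor.
    """
    if kw > 1:
        raise ValueError(f"kappa cannot exceed 1, got {kw}")
    r = round_half_away(kw, 2)
    if r > 0.80:
        return "very good"
    if r >= 0.61:
        return "good"
    if r >= 0.41:
        return "moderate"
    if r >= 0.21:
        return "fair"
    return "poor"
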