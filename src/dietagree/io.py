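"""CSV readers/writers for the instrument files.

Formats (all long, one observation per row):

* diary:        participant_id, day_index, food_group, servings —
                an absent (participant, day) pair means the day was not
                completed; a completed day with no row for a group means 0
                servings for that group (the app walks through every group
                daily, so explicit zeros are optional);
* records:      participant_id, day_index, day_type, food_group, servings;
* ffq:          participant_id, food_group, category_level;
* participants: id, age, gender, occupation, smoker,
                activity_min_per_week, bmi.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_FOOD_GROUPS,
    AppDiary,
    CategoryScheme,
    DietaryRecordEntry,
    DietaryRecordSet,
    FFQResponse,
    Participant,
)

__all__ = [
    "read_participants",
    "write_participants",
    "read_diaries",
    "write_diaries",
    "read_record_sets",
    "write_record_sets",
    "read_ffq",
    "write_ffq",
    "write_categories",
    "read_categories",
]


def read_participants(path: str | Path) -> list[Participant]:
    df = pd.read_csv(path, dtype={"id": str})
    required = {
        "id", "age", "gender", "occupation", "smoker",
        "activity_min_per_week", "bmi",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"participants file missing columns {sorted(missing)}")
    return [
        Participant(
            id=row.id, age=float(row.age), gender=row.gender,
            occupation=row.occupation, smoker=row.smoker,
            activity_min_per_week=float(row.activity_min_per_week),
            bmi=float(row.bmi),
        )
        for row in df.itertuples()
    ]


def write_participants(participants: Iterable[Participant], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "id": p.id, "age": p.age, "gender": p.gender,
                "occupation": p.occupation, "smoker": p.smoker,
                "activity_min_per_week": p.activity_min_per_week, "bmi": p.bmi,
            }
            for p in participants
        ]
    ).to_csv(path, index=False)


def read_diaries(
    path: str | Path, groups: tuple[str, ...] = DEFAULT_FOOD_GROUPS
) -> dict[str, AppDiary]:
    df = pd.read_csv(path, dtype={"participant_id": str})
    required = {"participant_id", "day_index", "food_group", "servings"}
    if not required.issubset(df.columns):
        raise ValueError(f"diary file must have columns {sorted(required)}")
    out: dict[str, AppDiary] = {}
    for pid, sub in df.groupby("participant_id", sort=True):
        servings = np.full((AppDiary.N_DAYS, len(groups)), np.nan)
        completed = np.zeros(AppDiary.N_DAYS, dtype=bool)
        days = sorted(sub["day_index"].unique())
        for d in days:
            if not 1 <= d <= AppDiary.N_DAYS:
                raise ValueError(f"day_index {d} outside 1..{AppDiary.N_DAYS}")
            completed[d - 1] = True
            servings[d - 1, :] = 0.0  # completed day: unlisted groups are 0
        for row in sub.itertuples():
            if row.food_group not in groups:
                raise ValueError(f"unknown food group {row.food_group!r}")
            j = groups.index(row.food_group)
            servings[row.day_index - 1, j] = float(row.servings)
        out[pid] = AppDiary(
            participant_id=pid, servings=servings,
            completed=completed, groups=groups,
        )
    return out


def write_diaries(diaries: Mapping[str, AppDiary], path: str | Path) -> None:
    rows = []
    for pid, d in diaries.items():
        for day in range(1, AppDiary.N_DAYS + 1):
            if not d.completed[day - 1]:
                continue
            for j, g in enumerate(d.groups):
                rows.append(
                    {"participant_id": pid, "day_index": day,
                     "food_group": g, "servings": d.servings[day - 1, j]}
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_record_sets(path: str | Path) -> dict[str, DietaryRecordSet]:
    df = pd.read_csv(path, dtype={"participant_id": str})
    required = {"participant_id", "day_index", "day_type", "food_group", "servings"}
    if not required.issubset(df.columns):
        raise ValueError(f"record file must have columns {sorted(required)}")
    out: dict[str, DietaryRecordSet] = {}
    for pid, sub in df.groupby("participant_id", sort=True):
        entries = []
        for (day, day_type), day_rows in sub.groupby(["day_index", "day_type"], sort=True):
            servings = dict(zip(day_rows["food_group"], day_rows["servings"].astype(float)))
            entries.append(
                DietaryRecordEntry(day_index=int(day), day_type=day_type, servings=servings)
            )
        out[pid] = DietaryRecordSet(participant_id=pid, entries=entries)
    return out


def write_record_sets(sets: Mapping[str, DietaryRecordSet], path: str | Path) -> None:
    rows = []
    for pid, rs in sets.items():
        for e in rs.entries:
            for g, v in e.servings.items():
                rows.append(
                    {"participant_id": pid, "day_index": e.day_index,
                     "day_type": e.day_type, "food_group": g, "servings": v}
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ffq(path: str | Path, scheme: CategoryScheme) -> dict[str, FFQResponse]:
    df = pd.read_csv(path, dtype={"participant_id": str})
    required = {"participant_id", "food_group", "category_level"}
    if not required.issubset(df.columns):
        raise ValueError(f"FFQ file must have columns {sorted(required)}")
    out: dict[str, FFQResponse] = {}
    for pid, sub in df.groupby("participant_id", sort=True):
        levels = dict(zip(sub["food_group"], sub["category_level"].astype(int)))
        out[pid] = FFQResponse(participant_id=pid, levels=levels, scheme=scheme)
    return out


def write_ffq(responses: Mapping[str, FFQResponse], path: str | Path) -> None:
    rows = []
    for pid, r in responses.items():
        for g, lv in r.levels.items():
            rows.append(
                {"participant_id": pid, "food_group": g, "category_level": int(lv)}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_categories(
    frame: pd.DataFrame, path: str | Path,
    weekly: pd.DataFrame | None = None,
) -> None:
    """Write a participant × group category frame in long format.

    Columns: participant_id, food_group, weekly_frequency (blank when not
    applicable, e.g. FFQ), category_level.
    """
    rows = []
    for pid in frame.index:
        for g in frame.columns:
            w = "" if weekly is None else weekly.loc[pid, g]
            rows.append(
                {"participant_id": pid, "food_group": g,
                 "weekly_frequency": w, "category_level": int(frame.loc[pid, g])}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_categories(path: str | Path) -> pd.DataFrame:
    """Read a long category CSV back into a participant × group frame."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    return df.pivot(
        index="participant_id", columns="food_group", values="category_level"
    ).astype(int)
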