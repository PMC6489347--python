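import numpy as np
import pytest
from hypothesis import settings

from dietagree import (
    DEFAULT_FOOD_GROUPS,
    SCHEME3,
    SCHEME6,
    AppDiary,
    DietaryRecordEntry,
    DietaryRecordSet,
    Participant,
)

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


@pytest.fixture
def scheme6():
    return SCHEME6


@pytest.fixture
def scheme3():
    return SCHEME3


@pytest.fixture
def make_diary():
    """Factory: diary with a constant daily value for every group."""

    def _make(value=1.0, n_completed=28, participant_id="P0001"):
        servings = np.full((28, len(DEFAULT_FOOD_GROUPS)), float(value))
        completed = np.zeros(28, dtype=bool)
        completed[:n_completed] = True
        servings[~completed] = np.nan
        return AppDiary(
            participant_id=participant_id,
            servings=servings,
            completed=completed,
        )

    return _make


@pytest.fixture
def worked_example_records():
    """The printed record-conversion example: red meat 0, 0.5, 1 on the
    weekday records and 0.5 on the weekend record."""
    return DietaryRecordSet(
        participant_id="P0001",
        entries=[
            DietaryRecordEntry(2, "weekday", {"red meat": 0.0}),
            DietaryRecordEntry(9, "weekday", {"red meat": 0.5}),
            DietaryRecordEntry(16, "weekday", {"red meat": 1.0}),
            DietaryRecordEntry(27, "weekend", {"red meat": 0.5}),
        ],
    )


@pytest.fixture
def participant():
    return Participant(
        id="P0001", age=24.0, gender="female", occupation="student",
        smoker="no", activity_min_per_week=150.0, bmi=24.9,
    )
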