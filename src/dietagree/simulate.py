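"""Synthetic validation cohorts.

No participant-level data from the motivating study are available, so this
module generates cohorts with the statistical structure the validity
analysis presupposes:

* a latent habitual intake per participant × food group — a weekly event
  rate λ drawn from a log-normal across participants, with an optional
  weekend multiplier;
* a 28-day "true" diary — daily event counts Poisson(λ/7), each event's
  serving size drawn from a discrete grid, giving realistic day-to-day
  intrapersonal variation around the habitual level;
* instrument observation models — the app sees the true diary on the days
  the participant completed (completion counts follow the study's empirical
  distribution over 21–28 days); the dietary records copy the truth on 4
  scheduled days (3 weekday + 1 weekend, nonconsecutive) with an optional
  per-entry recording error; the FFQ reports the category of the realized
  28-day mean with an optional ±1-level misclassification;
* participant covariates drawn from the study cohort's marginals.

Everything is deterministic given the configured seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .categorize import categorize, categorize_instrument
from .core import (
    DEFAULT_FOOD_GROUPS,
    AppDiary,
    CategoryScheme,
    DietaryRecordEntry,
    DietaryRecordSet,
    FFQResponse,
    Participant,
    SCHEME6,
)

__all__ = [
    "IntakeParams",
    "CohortConfig",
    "LatentIntake",
    "DiarySimulation",
    "sample_cohort",
    "simulate_diary",
    "select_dr_days",
    "observe_dr",
    "observe_ffq",
    "sample_usability",
    "run_validation_study",
    "StudyData",
    "weekend_days",
    "USABILITY_QUESTIONS",
]

N_DAYS = 28

#: 28-day calendar weekend positions: day_index mod 7 in {6, 0},
#: i.e. days 6,7,13,14,20,21,27,28 — the 5:2 weekday:weekend split the
#: record conversion formula assumes.
WEEKEND_DAYS = frozenset(d for d in range(1, N_DAYS + 1) if d % 7 in (6, 0))


def weekend_days() -> frozenset[int]:
    return WEEKEND_DAYS


@dataclass(frozen=True)
class IntakeParams:
    """Latent-intake law for one food group.

    ``median_weekly`` is the across-participant median of the weekly event
    rate λ (events/week); ``dispersion`` the log-normal sigma of λ;
    ``weekend_multiplier`` scales the daily rate on weekend days.
    """

    median_weekly: float
    dispersion: float = 0.8
    weekend_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.median_weekly < 0:
            raise ValueError("median_weekly must be nonnegative")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        if self.weekend_multiplier <= 0:
            raise ValueError("weekend_multiplier must be positive")


# Default per-group habitual rates (events/week): frequent staples near
# daily, occasional items a couple of times a week, and genuinely infrequent
# groups around once a week — spanning all six categories of the scale.
DEFAULT_INTAKE: dict[str, IntakeParams] = {
    "fruit": IntakeParams(7.0, 0.7),
    "vegetables": IntakeParams(7.0, 0.6),
    "legumes": IntakeParams(2.0, 0.7),
    "chicken/turkey": IntakeParams(2.5, 0.6),
    "fish": IntakeParams(2.0, 0.7),
    "red meat": IntakeParams(2.5, 0.7),
    "soft drinks": IntakeParams(3.0, 1.0, weekend_multiplier=1.3),
    "sweets": IntakeParams(4.0, 0.9),
    "prepared foods": IntakeParams(1.5, 0.8),
    "beer": IntakeParams(1.5, 1.1, weekend_multiplier=2.0),
}

# Empirical completion-count distribution from the study cohort
# (fraction of participants completing 28, 27, ... 21 days).
DEFAULT_COMPLETION: dict[int, float] = {
    28: 0.581, 27: 0.103, 26: 0.118, 25: 0.059,
    24: 0.054, 23: 0.030, 22: 0.034, 21: 0.020,
}

#: Usability questionnaire: option probabilities mirror the study cohort's
#: observed response shares.
USABILITY_QUESTIONS: dict[str, dict[str, float]] = {
    "easy_to_complete": {
        "Strongly agree": 139 / 203, "Agree": 62 / 203,
        "Neither agree nor disagree": 2 / 203, "Disagree": 0.0,
        "Strongly disagree": 0.0,
    },
    "too_time_consuming": {
        "Strongly agree": 3 / 203, "Agree": 4 / 203,
        "Neither agree nor disagree": 4 / 203, "Disagree": 82 / 203,
        "Strongly disagree": 110 / 203,
    },
    "interesting_to_complete": {
        "Strongly agree": 48 / 203, "Agree": 111 / 203,
        "Neither agree nor disagree": 39 / 203, "Disagree": 5 / 203,
        "Strongly disagree": 0.0,
    },
    "willing_to_complete_again": {
        "Strongly agree": 57 / 203, "Agree": 104 / 203,
        "Neither agree nor disagree": 39 / 203, "Disagree": 3 / 203,
        "Strongly disagree": 0.0,
    },
    "time_to_complete": {
        "<1 min/day": 23 / 203, "Approximately 1 min/day": 54 / 203,
        "Approximately 2 min/day": 63 / 203, "Approximately 3 min/day": 41 / 203,
        "Approximately 4 min/day": 16 / 203, "5 min/day or more": 6 / 203,
    },
}


@dataclass
class CohortConfig:
    """All knobs of the synthetic study.

    Covariate marginals default to the study cohort's composition (n=203,
    56.7% women, 57.1% employees, 16.3% smokers, 66.5% active ≥150 min/week,
    34.0% BMI ≥25, mean age 32.0 SD 11.4).  Noise parameters are simulator
    knobs, not estimates: the motivating study reports no quantitative error
    model for any instrument.
    """

    n_participants: int = 203
    frac_female: float = 0.567
    frac_employee: float = 0.571
    frac_smoker: float = 0.163
    frac_active: float = 0.665  # activity >= 150 min/week
    frac_bmi_high: float = 0.340  # BMI >= 25
    age_mean: float = 32.0
    age_sd: float = 11.4
    intake: Mapping[str, IntakeParams] = field(
        default_factory=lambda: dict(DEFAULT_INTAKE)
    )
    serving_grid: tuple[float, ...] = (0.5, 1.0, 1.5)
    serving_probs: tuple[float, ...] = (0.25, 0.6, 0.15)
    ffq_noise: float = 0.2  # probability of a ±1-level misreport
    ffq_noise2: float = 0.0  # optional probability of a ±2-level misreport
    dr_noise: float = 0.1  # per-entry recording-error probability
    completion: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPLETION)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        for name in ("frac_female", "frac_employee", "frac_smoker",
                     "frac_active", "frac_bmi_high", "ffq_noise",
                     "ffq_noise2", "dr_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.ffq_noise + self.ffq_noise2 > 1.0:
            raise ValueError("ffq_noise + ffq_noise2 must not exceed 1")
        if len(self.serving_grid) != len(self.serving_probs):
            raise ValueError("serving grid and probabilities must align")
        if abs(sum(self.serving_probs) - 1.0) > 1e-9:
            raise ValueError("serving probabilities must sum to 1")
        if any(s <= 0 for s in self.serving_grid):
            raise ValueError("serving sizes must be positive")
        comp = dict(self.completion)
        if not comp:
            raise ValueError("completion distribution must be non-empty")
        if any(not 21 <= d <= 28 for d in comp):
            raise ValueError("completion support must lie within 21..28 days")
        tot = sum(comp.values())
        if tot <= 0:
            raise ValueError("completion probabilities must sum to a positive value")
        self.completion = {d: p / tot for d, p in comp.items()}

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.intake)

    def config_hash(self) -> str:
        """Stable digest of the configuration, for report provenance."""
        payload = asdict(self)
        payload["intake"] = {g: asdict(p) for g, p in self.intake.items()}
        payload["completion"] = {str(k): v for k, v in self.completion.items()}
        s = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(s.encode()).hexdigest()[:16]


@dataclass
class LatentIntake:
    """True weekly event rates: participants × food groups."""

    rates: pd.DataFrame  # index participant_id, columns food groups

    def __post_init__(self) -> None:
        if (self.rates.values < 0).any():
            raise ValueError("rates must be nonnegative")

    def row(self, participant_id: str) -> pd.Series:
        return self.rates.loc[participant_id]


def sample_cohort(
    cfg: CohortConfig, rng: np.random.Generator
) -> tuple[list[Participant], LatentIntake]:
    """Draw participants and their latent intake rates.

    Covariates are drawn independently from the configured marginals; ages
    are normal (mean, sd) truncated above 18.  λ for each group is
    log-normal with the configured median and dispersion.
    """
    n = cfg.n_participants
    ids = [f"P{i:04d}" for i in range(1, n + 1)]
    ages = cfg.age_mean + cfg.age_sd * rng.standard_normal(n)
    ages = np.clip(ages, 18.5, None)
    female = rng.random(n) < cfg.frac_female
    employee = rng.random(n) < cfg.frac_employee
    smoker = rng.random(n) < cfg.frac_smoker
    active = rng.random(n) < cfg.frac_active
    bmi_high = rng.random(n) < cfg.frac_bmi_high
    # continuous covariates consistent with the drawn binary stratum
    activity = np.where(
        active, 150 + rng.exponential(120, n), rng.uniform(0, 150, n)
    )
    bmi = np.where(
        bmi_high, 25 + rng.exponential(3.5, n), rng.uniform(18.5, 25, n)
    )
    participants = [
        Participant(
            id=ids[i],
            age=float(round(ages[i], 1)),
            gender="female" if female[i] else "male",
            occupation="employee" if employee[i] else "student",
            smoker="yes" if smoker[i] else "no",
            activity_min_per_week=float(round(activity[i], 1)),
            bmi=float(round(bmi[i], 1)),
        )
        for i in range(n)
    ]
    groups = cfg.groups
    lam = np.empty((n, len(groups)))
    for j, g in enumerate(groups):
        p = cfg.intake[g]
        if p.median_weekly == 0:
            lam[:, j] = 0.0
        else:
            lam[:, j] = rng.lognormal(np.log(p.median_weekly), p.dispersion, n)
    rates = pd.DataFrame(lam, index=ids, columns=list(groups))
    return participants, LatentIntake(rates)


@dataclass
class DiarySimulation:
    """A simulated 28-day truth diary plus the app's completion mask.

    ``truth`` holds all 28 days — the simulator keeps ground truth even for
    days the participant skipped in the app, because the dietary records
    observe those days directly.
    """

    participant_id: str
    truth: np.ndarray  # (28, n_groups), no missingness
    completed: np.ndarray  # (28,) bool
    groups: tuple[str, ...]

    @property
    def diary(self) -> AppDiary:
        servings = self.truth.copy()
        servings[~self.completed] = np.nan
        return AppDiary(
            participant_id=self.participant_id,
            servings=servings,
            completed=self.completed,
            groups=self.groups,
        )

    def realized_weekly_mean(self) -> dict[str, float]:
        """Realized weekly frequency per group over all 28 truth days."""
        daily = self.truth.mean(axis=0)
        return {g: float(daily[j] * 7.0) for j, g in enumerate(self.groups)}


def simulate_diary(
    participant_id: str,
    lam: Mapping[str, float],
    cfg: CohortConfig,
    rng: np.random.Generator,
) -> DiarySimulation:
    """Simulate 28 days of true consumption and an app completion mask.

    Each day's event count is Poisson with mean λ/7 (scaled by the group's
    weekend multiplier on weekend days); each event contributes a serving
    size drawn from the configured grid.  The completion mask keeps a
    uniformly chosen subset of days whose size follows the completion
    distribution (always ≥21 days).
    """
    groups = cfg.groups
    truth = np.zeros((N_DAYS, len(groups)))
    sizes = np.asarray(cfg.serving_grid)
    size_p = np.asarray(cfg.serving_probs)
    for j, g in enumerate(groups):
        rate = lam.get(g, 0.0) / 7.0
        m = cfg.intake[g].weekend_multiplier
        day_rates = np.array(
            [rate * (m if d in WEEKEND_DAYS else 1.0) for d in range(1, N_DAYS + 1)]
        )
        counts = rng.poisson(day_rates)
        total_events = int(counts.sum())
        if total_events:
            event_sizes = rng.choice(sizes, size=total_events, p=size_p)
            idx = np.repeat(np.arange(N_DAYS), counts)
            np.add.at(truth[:, j], idx, event_sizes)
    days_done = int(
        rng.choice(list(cfg.completion), p=list(cfg.completion.values()))
    )
    completed = np.zeros(N_DAYS, dtype=bool)
    completed[rng.choice(N_DAYS, size=days_done, replace=False)] = True
    return DiarySimulation(
        participant_id=participant_id, truth=truth,
        completed=completed, groups=groups,
    )


def select_dr_days(rng: np.random.Generator) -> list[tuple[int, str]]:
    """Schedule the 4 dietary-record days on the 28-day calendar.

    Returns 3 weekday and 1 weekend (day_index, day_type) pairs, all
    pairwise nonadjacent (difference ≥ 2), uniform over valid sets.
    Rejection sampling from the uniform product measure is uniform over the
    valid sets, which always exist on a 28-day calendar.
    """
    weekdays = np.array(sorted(set(range(1, N_DAYS + 1)) - WEEKEND_DAYS))
    weekends = np.array(sorted(WEEKEND_DAYS))
    while True:
        wd = rng.choice(weekdays, size=3, replace=False)
        we = rng.choice(weekends, size=1)
        days = np.sort(np.concatenate([wd, we]))
        if np.all(np.diff(days) >= 2):
            break
    wd_set = set(int(d) for d in wd)
    return [
        (int(d), "weekday" if int(d) in wd_set else "weekend") for d in days
    ]


def observe_dr(
    sim: DiarySimulation,
    days: Sequence[tuple[int, str]],
    cfg: CohortConfig,
    rng: np.random.Generator,
) -> DietaryRecordSet:
    """Record the true consumption on the scheduled days, with optional error.

    With probability ``dr_noise`` per (day, group) entry the recorded value
    is perturbed by ±1 serving-grid step, floored at 0 (a perturbation at 0
    can only go up).
    """
    step = float(min(cfg.serving_grid))
    entries = []
    for day, day_type in days:
        vals = {}
        for j, g in enumerate(sim.groups):
            v = float(sim.truth[day - 1, j])
            if cfg.dr_noise > 0 and rng.random() < cfg.dr_noise:
                delta = step if (v == 0 or rng.random() < 0.5) else -step
                v = max(0.0, v + delta)
            vals[g] = v
        entries.append(
            DietaryRecordEntry(day_index=day, day_type=day_type, servings=vals)
        )
    return DietaryRecordSet(participant_id=sim.participant_id, entries=entries)


def observe_ffq(
    participant_id: str,
    realized_weekly: Mapping[str, float],
    scheme: CategoryScheme,
    cfg: CohortConfig,
    rng: np.random.Generator,
) -> FFQResponse:
    """Report each group's category with long-term-recall misclassification.

    The true category is the one the realized 28-day weekly mean falls in;
    the reported level is shifted by ±1 with probability ``ffq_noise``
    (split evenly between directions; optionally ±2 with ``ffq_noise2``)
    and clamped to the scheme's range.
    """
    levels = {}
    for g, w in realized_weekly.items():
        true_level = categorize(w, scheme).level
        u = rng.random()
        if u < cfg.ffq_noise / 2:
            shift = -1
        elif u < cfg.ffq_noise:
            shift = 1
        elif u < cfg.ffq_noise + cfg.ffq_noise2 / 2:
            shift = -2
        elif u < cfg.ffq_noise + cfg.ffq_noise2:
            shift = 2
        else:
            shift = 0
        levels[g] = int(np.clip(true_level + shift, 1, scheme.k))
    return FFQResponse(participant_id=participant_id, levels=levels, scheme=scheme)


def sample_usability(
    n: int, rng: np.random.Generator,
    questions: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Draw per-participant usability responses (long format)."""
    questions = questions or USABILITY_QUESTIONS
    rows = []
    for q, opts in questions.items():
        labels = list(opts)
        probs = np.asarray(list(opts.values()), dtype=float)
        probs = probs / probs.sum()
        picks = rng.choice(len(labels), size=n, p=probs)
        for i, k in enumerate(picks):
            rows.append(
                {"participant_id": f"P{i + 1:04d}", "question": q,
                 "option": labels[int(k)]}
            )
    return pd.DataFrame(rows)


@dataclass
class StudyData:
    """Everything a simulated validation study produces."""

    config: CohortConfig
    participants: list[Participant]
    latent: LatentIntake
    simulations: dict[str, DiarySimulation]
    dr_sets: dict[str, DietaryRecordSet]
    ffq: dict[str, FFQResponse]
    usability: pd.DataFrame
    app_categories: pd.DataFrame  # participants × groups, int levels
    dr_categories: pd.DataFrame
    ffq_categories: pd.DataFrame

    def participants_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": p.id, "age": p.age, "gender": p.gender,
                    "occupation": p.occupation, "smoker": p.smoker,
                    "activity_min_per_week": p.activity_min_per_week,
                    "bmi": p.bmi,
                }
                for p in self.participants
            ]
        ).set_index("id")

    def truth_frame(self) -> pd.DataFrame:
        """Latent rates and realized weekly means, for recovery tests."""
        rows = []
        for pid, sim in self.simulations.items():
            realized = sim.realized_weekly_mean()
            for g in sim.groups:
                rows.append(
                    {
                        "participant_id": pid, "food_group": g,
                        "lambda_weekly": float(self.latent.rates.loc[pid, g]),
                        "realized_weekly_mean": realized[g],
                    }
                )
        return pd.DataFrame(rows)


def simulate_study_data(
    cfg: CohortConfig, scheme: CategoryScheme = SCHEME6
) -> StudyData:
    """Generate a full synthetic study: truth, all three instruments, categories."""
    rng = np.random.default_rng(cfg.seed)
    participants, latent = sample_cohort(cfg, rng)
    groups = list(cfg.groups)
    sims: dict[str, DiarySimulation] = {}
    dr_sets: dict[str, DietaryRecordSet] = {}
    ffq: dict[str, FFQResponse] = {}
    app_rows, dr_rows, ffq_rows = [], [], []
    for p in participants:
        lam = latent.row(p.id).to_dict()
        sim = simulate_diary(p.id, lam, cfg, rng)
        sims[p.id] = sim
        days = select_dr_days(rng)
        dr_sets[p.id] = observe_dr(sim, days, cfg, rng)
        ffq[p.id] = observe_ffq(
            p.id, sim.realized_weekly_mean(), scheme, cfg, rng
        )
        app_cat = categorize_instrument(sim.diary, scheme)
        dr_cat = categorize_instrument(dr_sets[p.id], scheme, tuple(groups))
        app_rows.append({g: app_cat[g].level for g in groups})
        dr_rows.append({g: dr_cat[g].level for g in groups})
        ffq_rows.append({g: ffq[p.id].levels[g] for g in groups})
    usability = sample_usability(cfg.n_participants, rng)
    ids = [p.id for p in participants]
    return StudyData(
        config=cfg,
        participants=participants,
        latent=latent,
        simulations=sims,
        dr_sets=dr_sets,
        ffq=ffq,
        usability=usability,
        app_categories=pd.DataFrame(app_rows, index=ids),
        dr_categories=pd.DataFrame(dr_rows, index=ids),
        ffq_categories=pd.DataFrame(ffq_rows, index=ids),
    )


def run_validation_study(cfg: CohortConfig, scheme: CategoryScheme = SCHEME6):
    """End-to-end harness: simulate, categorize, and run the full
    stratified agreement analysis for both method pairs.

    Returns ``(StudyData, StudyReport)``.
    """
    from .report import run_stratified_analysis  # local import avoids a cycle

    data = simulate_study_data(cfg, scheme)
    report = run_stratified_analysis(
        app=data.app_categories,
        ffq=data.ffq_categories,
        dr=data.dr_categories,
        participants=data.participants,
        scheme=scheme,
        usability=data.usability,
        provenance={"config_hash": data.config.config_hash(), "seed": cfg.seed},
    )
    return data, report
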