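"""Inclusion/exclusion pipeline: six inclusion rules and the >=6-of-7
maximal-exertion rule.

Inclusion requires: regular training >= 3 months, age >= 18 years, all
screened variables within +/-3 SD of the cohort mean, no medical condition,
no medication, non-smoker, and a passed maximal-exertion assessment.  The
seven exertion criteria (all inclusive at the boundary) are:

1. peak RER >= 1.10
2. VO2 plateau (stage-to-stage VO2 growth < 100 mL·min⁻¹)
3. breathing frequency >= 45 breaths·min⁻¹
4. Borg rating >= 18
5. blood lactate >= 8 mmol·L⁻¹
6. speed/power gain beyond the RCP >= 10% of the RCP value
7. peak HR within 15 bpm of predicted maximal HR (default 220 − age)

An exertion assessment passes when at least six criteria are met.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from vo2val.cohort import CPETRecord, InsufficientDataError, Sex

__all__ = [
    "EFFORT_CRITERIA",
    "EffortAssessment",
    "ExclusionLedger",
    "assess_max_effort",
    "detect_plateau",
    "outlier_screen",
    "apply_inclusion",
    "DEFAULT_SCREEN_VARIABLES",
]

EFFORT_CRITERIA: tuple[str, ...] = (
    "rer",
    "plateau",
    "fr",
    "borg",
    "lactate",
    "post_rcp_gain",
    "hr_proximity",
)

# threshold constants, inclusive at the boundary
RER_MIN = 1.10
FR_MIN = 45.0
BORG_MIN = 18
LACTATE_MIN = 8.0
POST_RCP_GAIN_MIN = 10.0
HR_PROXIMITY_BPM = 15.0
PLATEAU_GROWTH_ML_MIN = 100.0
EFFORT_CRITERIA_REQUIRED = 6
MIN_AGE_YEARS = 18.0
MIN_TRAINING_MONTHS = 3.0


@dataclass(frozen=True)
class EffortAssessment:
    """Outcome of the seven maximal-exertion criteria for one record."""

    criteria: dict[str, bool]
    missing: tuple[str, ...] = ()

    @property
    def met_count(self) -> int:
        return sum(self.criteria.values())

    @property
    def passed(self) -> bool:
        return self.met_count >= EFFORT_CRITERIA_REQUIRED

    @property
    def unmet(self) -> tuple[str, ...]:
        return tuple(k for k, v in self.criteria.items() if not v)


def default_hr_max(record: CPETRecord) -> float:
    """Predicted maximal heart rate: 220 − age (bpm)."""
    return 220.0 - record.age


def assess_max_effort(
    record: CPETRecord,
    hr_max_predictor: Callable[[CPETRecord], float] = default_hr_max,
) -> EffortAssessment:
    """Evaluate the seven maximal-exertion criteria on one record.

    A missing criterion field counts as not met and is reported in
    ``missing`` rather than raising.
    """
    values = {
        "rer": (record.rer_peak, lambda v: v >= RER_MIN),
        "plateau": (record.plateau_observed, lambda v: bool(v)),
        "fr": (record.fr_peak, lambda v: v >= FR_MIN),
        "borg": (record.borg_peak, lambda v: v >= BORG_MIN),
        "lactate": (record.la_peak, lambda v: v >= LACTATE_MIN),
        "post_rcp_gain": (
            record.post_rcp_intensity_gain_pct,
            lambda v: v >= POST_RCP_GAIN_MIN,
        ),
        "hr_proximity": (
            record.hr_peak,
            lambda v: v >= hr_max_predictor(record) - HR_PROXIMITY_BPM,
        ),
    }
    criteria: dict[str, bool] = {}
    missing: list[str] = []
    for name, (value, check) in values.items():
        if value is None or (isinstance(value, float) and np.isnan(value)):
            criteria[name] = False
            missing.append(name)
        else:
            criteria[name] = bool(check(value))
    return EffortAssessment(criteria=criteria, missing=tuple(missing))


def detect_plateau(stage_vo2: Sequence[float]) -> bool:
    """True iff VO2 growth from penultimate to final stage is < 100 mL·min⁻¹."""
    if len(stage_vo2) < 2:
        raise InsufficientDataError("plateau detection needs at least 2 stages")
    return (stage_vo2[-1] - stage_vo2[-2]) < PLATEAU_GROWTH_ML_MIN


DEFAULT_SCREEN_VARIABLES: tuple[str, ...] = (
    "vo2max_rel",
    "rer_peak",
    "la_peak",
    "fr_peak",
    "hr_peak",
    "height",
    "body_mass",
    "bmi",
)


def outlier_screen(
    cohort: Sequence[CPETRecord],
    variables: Sequence[str] = DEFAULT_SCREEN_VARIABLES,
    k: float = 3.0,
    within_sex: bool = True,
) -> list[bool]:
    """Flag records with any screened variable strictly outside mean ± k·SD.

    Means and SDs are computed once on the input cohort (single pass), by
    default within sex.  Zero-variance variables are skipped with a warning.
    """
    if len(cohort) < 2:
        raise InsufficientDataError("outlier screen needs a cohort of >= 2")
    flags = np.zeros(len(cohort), dtype=bool)
    sexes = np.array([r.sex.value for r in cohort])
    groups = [m for m in (sexes == Sex.MALE.value, sexes == Sex.FEMALE.value) if m.any()] if within_sex else [np.ones(len(cohort), dtype=bool)]
    for var in variables:
        x = np.array([float(getattr(r, var)) for r in cohort])
        for mask in groups:
            if mask.sum() < 2:
                continue
            mu = x[mask].mean()
            sd = x[mask].std(ddof=1)
            if sd == 0.0:
                warnings.warn(
                    f"outlier screen: variable {var!r} has zero variance; skipped",
                    stacklevel=2,
                )
                continue
            flags[mask] |= np.abs(x[mask] - mu) > k * sd
    return list(flags)


@dataclass
class ExclusionLedger:
    """Per-record failure reasons plus flow accounting for one filter pass."""

    reasons: dict[str, list[str]] = field(default_factory=dict)
    effort_unmet: dict[str, tuple[str, ...]] = field(default_factory=dict)
    n_in: int = 0
    n_out: int = 0

    def counts_per_rule(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rs in self.reasons.values():
            for r in rs:
                counts[r] = counts.get(r, 0) + 1
        return counts

    @property
    def n_excluded(self) -> int:
        return sum(1 for rs in self.reasons.values() if rs)

    def to_dict(self) -> dict:
        return {
            "n_in": self.n_in,
            "n_out": self.n_out,
            "n_excluded": self.n_excluded,
            "counts_per_rule": self.counts_per_rule(),
            "reasons": {k: v for k, v in self.reasons.items() if v},
            "effort_unmet": {k: list(v) for k, v in self.effort_unmet.items()},
        }


def apply_inclusion(
    cohort: Sequence[CPETRecord],
    *,
    screen_variables: Sequence[str] = DEFAULT_SCREEN_VARIABLES,
    outlier_k: float = 3.0,
    run_outlier_screen: bool = True,
    hr_max_predictor: Callable[[CPETRecord], float] = default_hr_max,
) -> tuple[list[CPETRecord], ExclusionLedger]:
    """Apply all inclusion rules; return the included cohort and a ledger.

    The outlier screen runs before the effort filter, single pass, with
    moments computed on the input cohort.  Set ``run_outlier_screen=False``
    to re-filter an already screened cohort idempotently (re-computing
    moments on a filtered cohort would otherwise move the fences).
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be non-empty")
    ledger = ExclusionLedger(n_in=len(cohort))
    if run_outlier_screen and len(cohort) >= 2:
        outlier_flags = outlier_screen(cohort, screen_variables, outlier_k)
    else:
        outlier_flags = [False] * len(cohort)

    included: list[CPETRecord] = []
    for rec, is_outlier in zip(cohort, outlier_flags):
        reasons: list[str] = []
        if rec.training_months < MIN_TRAINING_MONTHS:
            reasons.append("training")
        if rec.age < MIN_AGE_YEARS:
            reasons.append("age")
        if is_outlier:
            reasons.append("outlier")
        if rec.has_medical_condition:
            reasons.append("medical_condition")
        if rec.takes_medication:
            reasons.append("medication")
        if rec.is_smoker:
            reasons.append("smoker")
        effort = assess_max_effort(rec, hr_max_predictor)
        if not effort.passed:
            reasons.append("effort")
            ledger.effort_unmet[rec.subject_id] = effort.unmet
        ledger.reasons[rec.subject_id] = reasons
        if not reasons:
            included.append(rec)
    ledger.n_out = len(included)
    return included, ledger
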