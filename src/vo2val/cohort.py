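"""Domain types, unit conversions, tabular I/O and breath-series reduction.

A cohort is a list of :class:`CPETRecord` (one maximal cardiopulmonary
exercise test per athlete).  CSV is the canonical exchange format; every
column carries a fixed unit documented in :data:`COHORT_COLUMNS`.  Relative
VO2max (mL·min⁻¹·kg⁻¹) is the primary stored quantity; absolute values are
always derived from body mass, never stored.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Sex",
    "Modality",
    "VO2Unit",
    "CPETRecord",
    "BreathSeries",
    "CohortFormatError",
    "RecordValidationError",
    "InsufficientDataError",
    "read_cohort",
    "write_cohort",
    "cohort_to_frame",
    "vo2max_15s",
    "convert_vo2",
    "derive_absolute_vo2",
]


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Modality(str, enum.Enum):
    """Testing modality: treadmill (TE) or cycle ergometer (CE)."""

    TE = "TE"
    CE = "CE"


class VO2Unit(str, enum.Enum):
    """Closed set of VO2 units used by prediction equations.

    Conversions between any pair are defined given body mass (kg).
    """

    REL_ML_KG_MIN = "mL·min⁻¹·kg⁻¹"
    ABS_ML_MIN = "mL·min⁻¹"
    ABS_L_MIN = "L·min⁻¹"


class CohortFormatError(ValueError):
    """A cohort file is structurally unreadable (e.g. missing column)."""


class RecordValidationError(ValueError):
    """A record violates a domain invariant."""


class InsufficientDataError(ValueError):
    """Too little data for the requested reduction."""


# BMI consistency tolerance (kg·m⁻²) between the stored value and the value
# recomputed from height and mass.
_BMI_TOL = 0.1


@dataclass
class CPETRecord:
    """One athlete's maximal CPET with anthropometrics and peak physiology.

    Exactly one of ``rcp_speed`` (treadmill, km·h⁻¹) / ``rcp_power_rel``
    (cycle, W·kg⁻¹) must be present, matching ``modality``; this is the
    variable used downstream for endurance-level classification.
    """

    subject_id: str
    sex: Sex
    age: float  # years
    height: float  # cm
    body_mass: float  # kg
    bmi: float  # kg·m⁻²
    body_fat_pct: float  # %
    ffm: float  # kg, fat-free mass
    modality: Modality
    vo2max_rel: float  # mL·min⁻¹·kg⁻¹
    rer_peak: float
    la_peak: float  # mmol·L⁻¹
    fr_peak: float  # breaths·min⁻¹
    borg_peak: int  # 6-20 RPE
    hr_peak: float  # bpm
    plateau_observed: bool
    post_rcp_intensity_gain_pct: float  # % of RCP speed/power beyond RCP
    training_months: float
    rcp_speed: float | None = None  # km·h⁻¹, TE only
    rcp_power_rel: float | None = None  # W·kg⁻¹, CE only
    has_medical_condition: bool = False
    takes_medication: bool = False
    is_smoker: bool = False

    def __post_init__(self) -> None:
        self.sex = Sex(self.sex)
        self.modality = Modality(self.modality)
        if not self.height > 0:
            raise RecordValidationError(
                f"{self.subject_id}: height must be positive (got {self.height})"
            )
        if not self.body_mass > 0:
            raise RecordValidationError(
                f"{self.subject_id}: body_mass must be positive"
            )
        recomputed = self.body_mass / (self.height / 100.0) ** 2
        if abs(self.bmi - recomputed) > _BMI_TOL:
            raise RecordValidationError(
                f"{self.subject_id}: bmi {self.bmi:.2f} inconsistent with "
                f"mass/height ({recomputed:.2f})"
            )
        if not self.vo2max_rel > 0:
            raise RecordValidationError(
                f"{self.subject_id}: vo2max_rel must be positive"
            )
        if not 6 <= self.borg_peak <= 20:
            raise RecordValidationError(
                f"{self.subject_id}: borg_peak {self.borg_peak} outside 6-20"
            )
        if self.ffm > self.body_mass:
            raise RecordValidationError(
                f"{self.subject_id}: ffm {self.ffm} exceeds body mass"
            )
        has_speed = self.rcp_speed is not None
        has_power = self.rcp_power_rel is not None
        if self.modality is Modality.TE and not (has_speed and not has_power):
            raise RecordValidationError(
                f"{self.subject_id}: TE record must carry rcp_speed only"
            )
        if self.modality is Modality.CE and not (has_power and not has_speed):
            raise RecordValidationError(
                f"{self.subject_id}: CE record must carry rcp_power_rel only"
            )

    @property
    def rcp_value(self) -> float:
        """The endurance-classification variable for this record's modality."""
        v = self.rcp_speed if self.modality is Modality.TE else self.rcp_power_rel
        assert v is not None
        return v

    @property
    def hr_max_predicted(self) -> float:
        """Predicted maximal heart rate, 220 − age (bpm)."""
        return 220.0 - self.age


@dataclass(frozen=True)
class BreathSeries:
    """Irregular breath-by-breath VO2 samples (time in s, VO2 in mL·min⁻¹)."""

    times: np.ndarray
    vo2: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.vo2, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise RecordValidationError("times and vo2 must be 1-D and equal length")
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise RecordValidationError("breath times must be strictly increasing")
        if np.any(v < 0):
            raise RecordValidationError("VO2 samples must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "vo2", v)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BreathSeries":
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise CohortFormatError("breath series CSV needs two columns (s, mL·min⁻¹)")
        return cls(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))


# Canonical CSV column order with fixed units.
COHORT_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "sex",
    "age",
    "height",
    "body_mass",
    "bmi",
    "body_fat_pct",
    "ffm",
    "modality",
    "vo2max_rel",
    "rer_peak",
    "la_peak",
    "fr_peak",
    "borg_peak",
    "hr_peak",
    "plateau_observed",
    "post_rcp_intensity_gain_pct",
    "training_months",
    "rcp_speed",
    "rcp_power_rel",
    "has_medical_condition",
    "takes_medication",
    "is_smoker",
)

_BOOL_COLUMNS = {
    "plateau_observed",
    "has_medical_condition",
    "takes_medication",
    "is_smoker",
}


def cohort_to_frame(cohort: Sequence[CPETRecord]) -> pd.DataFrame:
    """Convert records to a DataFrame with the canonical column order."""
    rows = []
    for r in cohort:
        d = {f.name: getattr(r, f.name) for f in fields(r)}
        d["sex"] = r.sex.value
        d["modality"] = r.modality.value
        rows.append(d)
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def write_cohort(cohort: Sequence[CPETRecord], path: str | Path) -> None:
    """Write a cohort to CSV (UTF-8, canonical columns)."""
    cohort_to_frame(cohort).to_csv(path, index=False, encoding="utf-8")


def _row_to_record(row: pd.Series) -> CPETRecord:
    kw: dict = {}
    for col in COHORT_COLUMNS:
        val = row[col]
        if col in ("rcp_speed", "rcp_power_rel"):
            kw[col] = None if pd.isna(val) else float(val)
        elif col in _BOOL_COLUMNS:
            if isinstance(val, str):
                val = val.strip().lower() in ("true", "1", "yes")
            kw[col] = bool(val)
        elif col in ("subject_id", "sex", "modality"):
            kw[col] = str(val)
        elif col == "borg_peak":
            kw[col] = int(val)
        else:
            kw[col] = float(val)
    return CPETRecord(**kw)


def read_cohort(
    path: str | Path, *, strict: bool = True
) -> list[CPETRecord] | tuple[list[CPETRecord], list[tuple[int, str]]]:
    """Read a cohort CSV, validating every row.

    Parameters
    ----------
    path:
        CSV with the columns of :data:`COHORT_COLUMNS`.
    strict:
        If True (default) raise on the first invalid row; if False return
        ``(records, diagnostics)`` where diagnostics is a list of
        ``(row_index, message)`` for rejected rows.

    Raises
    ------
    CohortFormatError
        If a required column is missing.
    RecordValidationError
        In strict mode, for the first row violating an invariant.
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"missing required column(s): {', '.join(missing)}")
    records: list[CPETRecord] = []
    diagnostics: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        try:
            records.append(_row_to_record(row))
        except (RecordValidationError, ValueError, ZeroDivisionError) as exc:
            if strict:
                raise RecordValidationError(f"row {idx}: {exc}") from exc
            diagnostics.append((int(idx), str(exc)))
    if strict:
        return records
    return records, diagnostics


def vo2max_15s(series: BreathSeries, window_s: float = 15.0) -> float:
    """Highest 15-s averaged VO2 of a breath-by-breath series (mL·min⁻¹).

    The series is treated as a piecewise-linear signal through the breath
    samples; the value returned is the maximum over all windows
    ``[t, t + window_s]`` (t ranging over the series support) of the
    time-weighted mean.  Because the windowed mean of a piecewise-linear
    signal is itself piecewise-smooth with extrema at sample-aligned window
    edges, it suffices to evaluate windows whose start or end coincides with
    a breath time.

    Raises
    ------
    InsufficientDataError
        If the series spans less than ``window_s`` seconds.
    """
    t, v = series.times, series.vo2
    if len(t) < 2 or t[-1] - t[0] < window_s:
        raise InsufficientDataError(
            f"series spans {0.0 if len(t) == 0 else t[-1] - t[0]:.1f} s "
            f"< required {window_s:.1f} s"
        )
    # cumulative trapezoidal integral for O(1) window means
    cum = np.concatenate(([0.0], np.cumsum(np.diff(t) * (v[:-1] + v[1:]) / 2.0)))

    def integral_at(x: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(t, x, side="right") - 1
        idx = np.clip(idx, 0, len(t) - 2)
        t0, t1 = t[idx], t[idx + 1]
        v0, v1 = v[idx], v[idx + 1]
        frac = np.clip((x - t0) / (t1 - t0), 0.0, 1.0)
        vx = v0 + frac * (v1 - v0)
        return cum[idx] + (x - t0) * (v0 + vx) / 2.0

    starts = np.unique(np.concatenate([t, t - window_s]))
    starts = starts[(starts >= t[0]) & (starts + window_s <= t[-1])]
    means = (integral_at(starts + window_s) - integral_at(starts)) / window_s
    return float(np.max(means))


def convert_vo2(
    value: float, from_unit: VO2Unit, to_unit: VO2Unit, body_mass: float | None = None
) -> float:
    """Convert a VO2 value between units, given body mass (kg) when needed.

    Conversions are exact algebra: REL·mass = ABS_ML_MIN = 1000·ABS_L_MIN.
    """
    from_unit, to_unit = VO2Unit(from_unit), VO2Unit(to_unit)
    if from_unit is to_unit:
        return value
    needs_mass = VO2Unit.REL_ML_KG_MIN in (from_unit, to_unit)
    if needs_mass:
        if body_mass is None or not body_mass > 0:
            raise ValueError("body_mass (kg, > 0) required for relative conversions")
    # normalise to mL·min⁻¹
    if from_unit is VO2Unit.REL_ML_KG_MIN:
        ml_min = value * body_mass
    elif from_unit is VO2Unit.ABS_L_MIN:
        ml_min = value * 1000.0
    else:
        ml_min = value
    if to_unit is VO2Unit.REL_ML_KG_MIN:
        return ml_min / body_mass
    if to_unit is VO2Unit.ABS_L_MIN:
        return ml_min / 1000.0
    return ml_min


def derive_absolute_vo2(record: CPETRecord) -> float:
    """Absolute VO2max (mL·min⁻¹) derived from the stored relative value."""
    return record.vo2max_rel * record.body_mass
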