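"""Age and SD-based endurance stratification.

Age groups (completed years): 18-30, 31-45, 46-60, >=61.  Endurance groups
are defined by the z-score of the respiratory-compensation-point variable
(speed at RCP for treadmill, relative power for cycle), standardized within
sex x modality: z > +1.5 is high-trained (HTEA), z < -1.5 low-trained
(LTEA), |z| < 0.5 recreational (REA), and the bands 0.5 <= |z| <= 1.5
(boundaries included) form the "transition" group, which whole-population
panels keep but endurance-axis validation panels exclude.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from vo2val.cohort import CPETRecord, Modality, Sex

__all__ = [
    "AgeGroup",
    "EnduranceGroup",
    "StrataLabel",
    "age_group",
    "endurance_zscores",
    "endurance_group",
    "stratify",
    "RELIABLE_MIN_N",
]

RELIABLE_MIN_N = 100  # TRIPOD-style subgroup-reliability threshold


class AgeGroup(str, enum.Enum):
    A18_30 = "18-30"
    A31_45 = "31-45"
    A46_60 = "46-60"
    A61_PLUS = ">=61"


class EnduranceGroup(str, enum.Enum):
    HTEA = "HTEA"
    REA = "REA"
    LTEA = "LTEA"
    TRANSITION = "transition"


@dataclass(frozen=True)
class StrataLabel:
    """Full stratum assignment of one record."""

    sex: Sex
    modality: Modality
    age_group: AgeGroup
    endurance_group: EnduranceGroup
    z: float


def age_group(age: float) -> AgeGroup:
    """Bucket an age (>= 18 years) into the study's four groups.

    Age is truncated to completed whole years before bucketing, so 30.9
    falls in 18-30.
    """
    if age < 18:
        raise ValueError(f"age {age} below the study minimum of 18")
    years = math.floor(age)
    if years <= 30:
        return AgeGroup.A18_30
    if years <= 45:
        return AgeGroup.A31_45
    if years <= 60:
        return AgeGroup.A46_60
    return AgeGroup.A61_PLUS


def endurance_zscores(cohort: Sequence[CPETRecord]) -> np.ndarray:
    """Z-scores of the RCP variable, standardized within sex x modality.

    Raises if any populated stratum has fewer than 2 records or zero SD.
    """
    z = np.full(len(cohort), np.nan)
    sexes = np.array([r.sex.value for r in cohort])
    mods = np.array([r.modality.value for r in cohort])
    x = np.array([r.rcp_value for r in cohort], dtype=float)
    for sex in Sex:
        for mod in Modality:
            mask = (sexes == sex.value) & (mods == mod.value)
            if not mask.any():
                continue
            if mask.sum() < 2:
                raise ValueError(
                    f"stratum {sex.value} x {mod.value} has < 2 records; "
                    "cannot standardize"
                )
            mu = x[mask].mean()
            sd = x[mask].std(ddof=1)
            if sd == 0.0:
                raise ValueError(
                    f"stratum {sex.value} x {mod.value} has zero RCP variance"
                )
            z[mask] = (x[mask] - mu) / sd
    return z


def endurance_group(z: float) -> EnduranceGroup:
    """Map an RCP z-score to an endurance class.

    Boundaries +/-0.5 and +/-1.5 belong to the transition group, following
    the inequality directions of the classification rule.
    """
    if not np.isfinite(z):
        raise ValueError(f"z must be finite (got {z})")
    if z > 1.5:
        return EnduranceGroup.HTEA
    if z < -1.5:
        return EnduranceGroup.LTEA
    if -0.5 < z < 0.5:
        return EnduranceGroup.REA
    return EnduranceGroup.TRANSITION


def stratify(
    cohort: Sequence[CPETRecord],
) -> tuple[list[StrataLabel], dict[str, dict[str, dict]]]:
    """Assign every record a :class:`StrataLabel`; summarize subgroup sizes.

    Returns ``(labels, summary)`` where labels aligns with the cohort and
    summary maps axis ("endurance" / "age") -> subgroup name -> dict with
    ``n`` and a TRIPOD reliability flag (``n >= 100``).
    """
    z = endurance_zscores(cohort)
    labels = [
        StrataLabel(
            sex=r.sex,
            modality=r.modality,
            age_group=age_group(r.age),
            endurance_group=endurance_group(zi),
            z=float(zi),
        )
        for r, zi in zip(cohort, z)
    ]
    summary: dict[str, dict[str, dict]] = {"endurance": {}, "age": {}}
    for axis, enum_cls, attr in (
        ("endurance", EnduranceGroup, "endurance_group"),
        ("age", AgeGroup, "age_group"),
    ):
        for member in enum_cls:
            n = sum(1 for lb in labels if getattr(lb, attr) is member)
            summary[axis][member.value] = {"n": n, "reliable": n >= RELIABLE_MIN_N}
    return labels, summary
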