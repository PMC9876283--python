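"""TRIPOD-style external-validation metrics.

For each model x subgroup the engine regresses observed VO2max on predicted
VO2max (ordinary least squares) and reports:

* calibration slope C2 (1 ideal) — the OLS slope;
* calibration-in-the-large C1 (0 ideal) — either the free intercept of the
  same regression (``free_intercept``, default, intercept-scale units) or
  mean(observed) − mean(predicted) (``mean_difference``); every C1 value is
  tagged with its convention;
* adjusted R² = 1 − (1 − R²)(n − 1)/(n − 2), which can be negative;
* RMSE = sqrt(mean squared residual) of the fit, in model-native units;
* a paired mean difference (predicted − observed; positive = the model
  overestimates) with t-based 95% CI;
* a reliability flag (n >= 100 per validated subgroup).

Effect sizes follow the R² cutoffs: < 0.3 none/very weak, 0.3–0.5 weak/low,
0.5–0.7 moderate, > 0.7 high.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from vo2val.cohort import CPETRecord, InsufficientDataError, Modality, Sex, VO2Unit
from vo2val.registry import ModelSpec, builtin_models, predict_cohort
from vo2val.stratify import (
    AgeGroup,
    EnduranceGroup,
    RELIABLE_MIN_N,
    StrataLabel,
)

__all__ = [
    "C1Convention",
    "CalibrationResult",
    "MeanDifference",
    "DegenerateFitError",
    "fit_calibration",
    "calibration_in_the_large",
    "mean_difference",
    "validate",
    "effect_size_class",
]


class C1Convention(str, enum.Enum):
    FREE_INTERCEPT = "free_intercept"
    MEAN_DIFFERENCE = "mean_difference"


class DegenerateFitError(ValueError):
    """The calibration regression is undefined (constant predictor)."""


def effect_size_class(r2: float) -> str:
    """Effect-size label for an (adjusted) R² value."""
    if r2 < 0.3:
        return "none/very-weak"
    if r2 < 0.5:
        return "weak/low"
    if r2 < 0.7:
        return "moderate"
    return "high"


@dataclass(frozen=True)
class CalibrationResult:
    """C1/C2/adjusted-R²/RMSE bundle for one observed-vs-predicted fit."""

    n: int
    intercept: float
    slope: float
    r2: float
    r2_adj: float
    rmse: float
    c1: float
    c1_convention: C1Convention
    c2: float
    p_slope: float
    p_c1: float

    @property
    def reliable(self) -> bool:
        return self.n >= RELIABLE_MIN_N

    @property
    def effect_size(self) -> str:
        return effect_size_class(self.r2_adj)


@dataclass(frozen=True)
class MeanDifference:
    """Paired mean difference predicted − observed with t-based 95% CI."""

    n: int
    mean_diff: float
    ci95_low: float
    ci95_high: float
    p: float


def _as_arrays(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise ValueError("observed and predicted must be 1-D and equal length")
    return o, p


def fit_calibration(
    observed: Sequence[float],
    predicted: Sequence[float],
    c1_convention: C1Convention = C1Convention.FREE_INTERCEPT,
) -> CalibrationResult:
    """OLS of observed on predicted; slope is the calibration slope C2.

    Raises :class:`InsufficientDataError` for n < 3 and
    :class:`DegenerateFitError` for a constant predictor.
    """
    o, p = _as_arrays(observed, predicted)
    n = len(o)
    if n < 3:
        raise InsufficientDataError(f"calibration fit needs n >= 3 (got {n})")
    if np.ptp(p) == 0.0:
        raise DegenerateFitError("predicted values are constant; slope undefined")
    model = sm.OLS(o, sm.add_constant(p)).fit()
    intercept, slope = model.params
    resid = model.resid
    rmse = float(np.sqrt(np.mean(resid**2)))
    r2 = float(model.rsquared)
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    p_int, p_slope = model.pvalues
    conv = C1Convention(c1_convention)
    if conv is C1Convention.FREE_INTERCEPT:
        c1, p_c1 = float(intercept), float(p_int)
    else:
        c1 = float(np.mean(o) - np.mean(p))
        p_c1 = mean_difference(o, p).p
    return CalibrationResult(
        n=n,
        intercept=float(intercept),
        slope=float(slope),
        r2=r2,
        r2_adj=float(r2_adj),
        rmse=rmse,
        c1=c1,
        c1_convention=conv,
        c2=float(slope),
        p_slope=float(p_slope),
        p_c1=p_c1,
    )


def calibration_in_the_large(
    observed: Sequence[float],
    predicted: Sequence[float],
    convention: C1Convention = C1Convention.FREE_INTERCEPT,
) -> tuple[float, C1Convention]:
    """Calibration-in-the-large under the requested convention, tagged.

    ``mean_difference`` returns mean(observed) − mean(predicted);
    ``free_intercept`` returns the intercept of the calibration regression.
    """
    conv = C1Convention(convention)
    o, p = _as_arrays(observed, predicted)
    if conv is C1Convention.MEAN_DIFFERENCE:
        return float(np.mean(o) - np.mean(p)), conv
    return fit_calibration(o, p).intercept, conv


def mean_difference(
    observed: Sequence[float], predicted: Sequence[float]
) -> MeanDifference:
    """Mean of (predicted − observed) with paired t-based 95% CI.

    Positive values mean the model overestimates.  With zero-variance
    differences the t statistic is undefined; p is reported as 1.0 and the
    CI collapses to the point estimate.
    """
    o, p = _as_arrays(observed, predicted)
    n = len(o)
    if n < 2:
        raise InsufficientDataError(f"mean difference needs n >= 2 (got {n})")
    d = p - o
    m = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        return MeanDifference(n=n, mean_diff=m, ci95_low=m, ci95_high=m, p=1.0)
    se = sd / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, n - 1)
    tstat = m / se
    pval = float(2.0 * stats.t.sf(abs(tstat), n - 1))
    return MeanDifference(
        n=n,
        mean_diff=m,
        ci95_low=m - tcrit * se,
        ci95_high=m + tcrit * se,
        p=pval,
    )


_AXES = ("whole", "endurance", "age")


def _subgroups_for_axis(axis: str) -> list[str]:
    if axis == "whole":
        return ["all"]
    if axis == "endurance":
        # transition excluded from endurance-axis validation panels
        return [
            EnduranceGroup.HTEA.value,
            EnduranceGroup.REA.value,
            EnduranceGroup.LTEA.value,
        ]
    if axis == "age":
        return [g.value for g in AgeGroup]
    raise ValueError(f"unknown axis {axis!r}")


def validate(
    cohort: Sequence[CPETRecord],
    labels: Sequence[StrataLabel],
    models: Iterable[ModelSpec] | None = None,
    axes: Sequence[str] = _AXES,
    c1_convention: C1Convention = C1Convention.FREE_INTERCEPT,
    min_n: int = 3,
) -> pd.DataFrame:
    """Calibration metrics per model x sex x modality x subgroup.

    One row per cell, in the model's native unit.  The endurance axis
    excludes the transition group; the whole-population axis keeps it.
    Degenerate cells (n below ``min_n`` or constant predictions) are emitted
    with an ``error`` marker rather than dropped.
    """
    if len(cohort) != len(labels):
        raise ValueError("cohort and labels must align")
    specs = list(models) if models is not None else builtin_models()
    preds = predict_cohort(cohort, specs)
    preds = preds[preds["applicable"] & (preds["error"] == "")]
    by_subject = {r.subject_id: (r, lb) for r, lb in zip(cohort, labels)}

    rows = []
    for spec in specs:
        sub = preds[preds["model_id"] == spec.model_id]
        if sub.empty:
            continue
        sub_ids = sub["subject_id"].to_numpy()
        obs = sub["observed"].to_numpy(float)
        prd = sub["predicted"].to_numpy(float)
        rec_lb = [by_subject[s] for s in sub_ids]
        for axis in axes:
            for group in _subgroups_for_axis(axis):
                for sex in sorted(spec.sex_applicability, key=lambda s: s.value, reverse=True):
                    for mod in sorted(spec.modality_applicability, key=lambda m: m.value, reverse=True):
                        mask = np.array(
                            [
                                r.sex is sex
                                and r.modality is mod
                                and (
                                    axis == "whole"
                                    or (
                                        axis == "endurance"
                                        and lb.endurance_group.value == group
                                    )
                                    or (axis == "age" and lb.age_group.value == group)
                                )
                                for r, lb in rec_lb
                            ]
                        )
                        n = int(mask.sum())
                        row = {
                            "model_id": spec.model_id,
                            "source": spec.source_label,
                            "unit": spec.output_unit.value,
                            "axis": axis,
                            "subgroup": group,
                            "sex": sex.value,
                            "modality": mod.value,
                            "n": n,
                            "reliable": n >= RELIABLE_MIN_N,
                            "r2_adj": np.nan,
                            "rmse": np.nan,
                            "c1": np.nan,
                            "c1_convention": C1Convention(c1_convention).value,
                            "c2": np.nan,
                            "p_slope": np.nan,
                            "p_c1": np.nan,
                            "effect_size": "",
                            "mean_diff": np.nan,
                            "ci95_low": np.nan,
                            "ci95_high": np.nan,
                            "p_mean_diff": np.nan,
                            "error": "",
                        }
                        o, p = obs[mask], prd[mask]
                        if n < max(min_n, 3):
                            row["error"] = "insufficient n"
                        else:
                            try:
                                cal = fit_calibration(o, p, c1_convention)
                            except DegenerateFitError:
                                row["error"] = "degenerate fit"
                            else:
                                md = mean_difference(o, p)
                                row.update(
                                    r2_adj=cal.r2_adj,
                                    rmse=cal.rmse,
                                    c1=cal.c1,
                                    c2=cal.c2,
                                    p_slope=cal.p_slope,
                                    p_c1=cal.p_c1,
                                    effect_size=cal.effect_size,
                                    mean_diff=md.mean_diff,
                                    ci95_low=md.ci95_low,
                                    ci95_high=md.ci95_high,
                                    p_mean_diff=md.p,
                                )
                        rows.append(row)
    return pd.DataFrame(rows)
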