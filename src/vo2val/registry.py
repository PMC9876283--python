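"""Registry of published VO2max prediction equations.

Thirteen equations from eight publications, each carried as a
:class:`ModelSpec` with applicability metadata (which sexes, which testing
modalities), its native output unit, and a pure evaluation function over a
:class:`~vo2val.cohort.CPETRecord`.  Observed VO2max is always converted to
the model's native unit before any comparison, so validation never mixes
units.

The built-in set mirrors the validated literature panel: the Wilson &
Tanaka and Fitzgerald et al. meta-analytic age regressions (single-sex),
the two sex-specific Wasserman/Hansen cycle equations, three FRIEND-registry
cycle-ergometry equations of Kokkinos et al. (male, female, combined), the
Mylius et al. reference equation, the FRIEND treadmill equation of Myers
and colleagues, the allometric and additive treadmill models of Nevill et
al., and the athlete-derived treadmill/cycle equations of Petek et al.
Coefficient values are kept in this one reviewable module; users whose
edition of a source differs can register replacements or load linear
models from a declarative YAML/JSON file.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from vo2val.cohort import CPETRecord, Modality, Sex, VO2Unit, convert_vo2

__all__ = [
    "ModelSpec",
    "ModelRegistry",
    "builtin_models",
    "applicable_models",
    "predict_cohort",
    "linear_model_spec",
    "load_model_file",
]

BOTH_SEXES = frozenset({Sex.MALE, Sex.FEMALE})
BOTH_MODALITIES = frozenset({Modality.TE, Modality.CE})
LB_PER_KG = 2.20462


@dataclass(frozen=True)
class ModelSpec:
    """One prediction equation with applicability metadata.

    ``evaluate`` is a pure function record -> predicted VO2max in
    ``output_unit``; it must be deterministic and finite for any valid
    in-range record.
    """

    model_id: str
    source_label: str
    citation: str
    sex_applicability: frozenset[Sex]
    modality_applicability: frozenset[Modality]
    output_unit: VO2Unit
    required_predictors: tuple[str, ...]
    evaluate: Callable[[CPETRecord], float]

    def __post_init__(self) -> None:
        if not self.required_predictors:
            raise ValueError(f"{self.model_id}: required_predictors is empty")
        if not self.sex_applicability or not self.modality_applicability:
            raise ValueError(f"{self.model_id}: empty applicability set")

    def applies_to(self, sex: Sex, modality: Modality) -> bool:
        return sex in self.sex_applicability and modality in self.modality_applicability


def _female(record: CPETRecord) -> float:
    return 1.0 if record.sex is Sex.FEMALE else 0.0


def builtin_models() -> list[ModelSpec]:
    """The thirteen built-in prediction equations (fresh instances)."""
    specs = [
        ModelSpec(
            model_id="wilson",
            source_label="Wilson et al.",
            citation="Wilson & Tanaka (2000), meta-analytic age regression, "
            "endurance-trained men",
            sex_applicability=frozenset({Sex.MALE}),
            modality_applicability=BOTH_MODALITIES,
            output_unit=VO2Unit.REL_ML_KG_MIN,
            required_predictors=("age",),
            evaluate=lambda r: 75.4 - 0.46 * r.age,
        ),
        ModelSpec(
            model_id="fitzgerald",
            source_label="Fitzgerald et al.",
            citation="Fitzgerald, Tanaka & Tran (1997), meta-analytic age "
            "regression, endurance-trained women",
            sex_applicability=frozenset({Sex.FEMALE}),
            modality_applicability=BOTH_MODALITIES,
            output_unit=VO2Unit.REL_ML_KG_MIN,
            required_predictors=("age",),
            evaluate=lambda r: 70.7 - 0.62 * r.age,
        ),
        ModelSpec(
            model_id="wasserman_male",
            source_label="Wasserman et al.",
            citation="Wasserman/Hansen predicted VO2max, men: "
            "mass x (50.72 - 0.372 x age)",
            sex_applicability=frozenset({Sex.MALE}),
            modality_applicability=BOTH_MODALITIES,
            output_unit=VO2Unit.ABS_ML_MIN,
            required_predictors=("age", "body_mass"),
            evaluate=lambda r: r.body_mass * (50.72 - 0.372 * r.age),
        ),
        ModelSpec(
            model_id="wasserman_female",
            source_label="Wasserman et al.",
            citation="Wasserman/Hansen predicted VO2max, women: "
            "(mass + 43) x (22.78 - 0.17 x age)",
            sex_applicability=frozenset({Sex.FEMALE}),
            modality_applicability=BOTH_MODALITIES,
            output_unit=VO2Unit.ABS_ML_MIN,
            required_predictors=("age", "body_mass"),
            evaluate=lambda r: (r.body_mass + 43.0) * (22.78 - 0.17 * r.age),
        ),
        ModelSpec(
            model_id="kokkinos_male",
            source_label="Kokkinos et al. (1)",
            citation="Kokkinos et al., FRIEND registry cycle ergometry, men",
            sex_applicability=frozenset({Sex.MALE}),
            modality_applicability=frozenset({Modality.CE}),
            output_unit=VO2Unit.REL_ML_KG_MIN,
            required_predictors=("age",),
            evaluate=lambda r: 55.6 - 0.28 * r.age,
        ),
        ModelSpec(
            model_id="kokkinos_female",
            source_label="Kokkinos et al. (2)",
            citation="Kokkinos et al., FRIEND registry cycle ergometry, women",
            sex_applicability=frozenset({Sex.FEMALE}),
            modality_applicability=frozenset({Modality.CE}),
            output_unit=VO2Unit.REL_ML_KG_MIN,
            required_predictors=("age",),
            evaluate=lambda r: 52.9 - 0.23 * r.age,
        ),
        ModelSpec(
            model_id="kokkinos_combined",
            source_label="Kokkinos et al. (3)",
            citation="Kokkinos et al., FRIEND registry cycle ergometry, "
            "both sexes",
            sex_applicability=BOTH_SEXES,
            modality_applicability=frozenset({Modality.CE}),
            output_unit=VO2Unit.REL_ML_KG_MIN,
            required_predictors=("age", "sex"),
            evaluate=lambda r: 55.9 - 0.27 * r.age - 3.8 * _female(r),
        ),
        ModelSpec(
            model_id="mylius",
            source_label="Mylius et al.",
            citation="Mylius et al. (2015), cycle-ergometry reference "
            "equation, sex-specific",
            sex_applicability=BOTH_SEXES,
            modality_applicability=frozenset({Modality.CE}),
            output_unit=VO2Unit.ABS_ML_MIN,
            required_predictors=("age", "height", "sex"),
            evaluate=lambda r: (
                -2000.0 + 30.0 * r.height - 10.0 * r.age
                if r.sex is Sex.MALE
                else -1552.0 + 24.0 * r.height - 8.0 * r.age
            ),
        ),
        ModelSpec(
            model_id="myers",
            source_label="Myers et al.",
            citation="FRIEND treadmill equation: 79.9 - 0.39 x age - 13.7 x "
            "sex(F=1) - 0.127 x weight(lb)",
            sex_applicability=BOTH_SEXES,
            modality_applicability=frozenset({Modality.TE}),
            output_unit=VO2Unit.REL_ML_KG_MIN,
            required_predictors=("age", "sex", "body_mass"),
            evaluate=lambda r: 79.9
            - 0.39 * r.age
            - 13.7 * _female(r)
            - 0.127 * r.body_mass * LB_PER_KG,
        ),
        ModelSpec(
            model_id="nevill_allometric",
            source_label="Nevill et al. (1)",
            citation="Nevill et al., allometric treadmill model "
            "(mass exponent -0.33, exponential age decay, sex factor)",
            sex_applicability=BOTH_SEXES,
            modality_applicability=frozenset({Modality.TE}),
            output_unit=VO2Unit.REL_ML_KG_MIN,
            required_predictors=("age", "sex", "body_mass"),
            evaluate=lambda r: 236.0
            * r.body_mass**-0.33
            * math.exp(-0.0062 * r.age)
            * (0.72 if r.sex is Sex.FEMALE else 1.0),
        ),
        ModelSpec(
            model_id="nevill_additive",
            source_label="Nevill et al. (2)",
            citation="Nevill et al., additive treadmill model "
            "(linear in age, mass and sex)",
            sex_applicability=BOTH_SEXES,
            modality_applicability=frozenset({Modality.TE}),
            output_unit=VO2Unit.REL_ML_KG_MIN,
            required_predictors=("age", "sex", "body_mass"),
            evaluate=lambda r: 57.5 - 0.21 * r.age - 0.07 * r.body_mass - 8.0 * _female(r),
        ),
        ModelSpec(
            model_id="petek_te",
            source_label="Petek et al.",
            citation="Petek et al. (2022), athlete-derived treadmill "
            "equation (L·min⁻¹)",
            sex_applicability=BOTH_SEXES,
            modality_applicability=frozenset({Modality.TE}),
            output_unit=VO2Unit.ABS_L_MIN,
            required_predictors=("age", "sex", "body_mass"),
            evaluate=lambda r: 1.83 + 0.035 * r.body_mass - 0.013 * r.age - 1.11 * _female(r),
        ),
        ModelSpec(
            model_id="petek_ce",
            source_label="Petek et al.",
            citation="Petek et al. (2022), athlete-derived cycle-ergometry "
            "equation (L·min⁻¹)",
            sex_applicability=BOTH_SEXES,
            modality_applicability=frozenset({Modality.CE}),
            output_unit=VO2Unit.ABS_L_MIN,
            required_predictors=("age", "sex", "body_mass"),
            evaluate=lambda r: 1.69 + 0.035 * r.body_mass - 0.013 * r.age - 0.91 * _female(r),
        ),
    ]
    assert len(specs) == 13
    return specs


class ModelRegistry:
    """Built-in equations plus user-registered ones, addressable by id."""

    def __init__(self, include_builtin: bool = True) -> None:
        self._specs: dict[str, ModelSpec] = {}
        if include_builtin:
            for spec in builtin_models():
                self._specs[spec.model_id] = spec

    def register(self, spec: ModelSpec) -> "ModelRegistry":
        if spec.model_id in self._specs:
            raise ValueError(f"model id {spec.model_id!r} already registered")
        self._specs[spec.model_id] = spec
        return self

    def get(self, model_id: str) -> ModelSpec:
        return self._specs[model_id]

    def __contains__(self, model_id: str) -> bool:
        return model_id in self._specs

    def __iter__(self):
        return iter(self._specs.values())

    def __len__(self) -> int:
        return len(self._specs)

    def applicable(self, sex: Sex, modality: Modality) -> list[ModelSpec]:
        sex, modality = Sex(sex), Modality(modality)
        return [s for s in self if s.applies_to(sex, modality)]


def applicable_models(
    sex: Sex, modality: Modality, registry: ModelRegistry | None = None
) -> list[ModelSpec]:
    """Models applicable to a (sex, modality) pair, built-ins by default."""
    reg = registry if registry is not None else ModelRegistry()
    return reg.applicable(sex, modality)


def predict_cohort(
    cohort: Sequence[CPETRecord],
    models: Iterable[ModelSpec] | ModelRegistry | None = None,
) -> pd.DataFrame:
    """Evaluate every applicable model on every record.

    Returns a long-format table with one row per record x model, columns
    ``subject_id, model_id, unit, applicable, observed, predicted, error``.
    Observed VO2max is converted to each model's native unit; cells outside
    a model's (sex, modality) applicability carry ``applicable=False`` and
    NaN values, never zeros.  A missing required predictor yields a
    row-level ``error`` entry instead of an exception.
    """
    specs = list(models) if models is not None else builtin_models()
    rows = []
    for rec in cohort:
        for spec in specs:
            row = {
                "subject_id": rec.subject_id,
                "model_id": spec.model_id,
                "unit": spec.output_unit.value,
                "applicable": spec.applies_to(rec.sex, rec.modality),
                "observed": np.nan,
                "predicted": np.nan,
                "error": "",
            }
            if row["applicable"]:
                row["observed"] = convert_vo2(
                    rec.vo2max_rel,
                    VO2Unit.REL_ML_KG_MIN,
                    spec.output_unit,
                    rec.body_mass,
                )
                missing = [
                    p
                    for p in spec.required_predictors
                    if getattr(rec, p, None) is None
                ]
                if missing:
                    row["error"] = f"missing predictor(s): {', '.join(missing)}"
                else:
                    pred = float(spec.evaluate(rec))
                    if not np.isfinite(pred):
                        row["error"] = "non-finite prediction"
                    else:
                        row["predicted"] = pred
            rows.append(row)
    return pd.DataFrame(rows)


def linear_model_spec(
    model_id: str,
    output_unit: VO2Unit,
    intercept: float,
    terms: dict[str, float] | None = None,
    sexes: Iterable[Sex | str] = ("male", "female"),
    modalities: Iterable[Modality | str] = ("TE", "CE"),
    source_label: str = "",
    citation: str = "user-defined linear model",
) -> ModelSpec:
    """Build a ModelSpec for a linear formula over record fields.

    ``terms`` maps record field names to coefficients; the special field
    ``female`` contributes its coefficient for female records.
    """
    terms = dict(terms or {})

    def evaluate(record: CPETRecord) -> float:
        total = intercept
        for name, coef in terms.items():
            if name == "female":
                total += coef * _female(record)
            else:
                total += coef * float(getattr(record, name))
        return total

    return ModelSpec(
        model_id=model_id,
        source_label=source_label or model_id,
        citation=citation,
        sex_applicability=frozenset(Sex(s) for s in sexes),
        modality_applicability=frozenset(Modality(m) for m in modalities),
        output_unit=VO2Unit(output_unit),
        required_predictors=tuple(t for t in terms if t != "female") or ("age",),
        evaluate=evaluate,
    )


_UNIT_ALIASES = {
    "rel": VO2Unit.REL_ML_KG_MIN,
    "ml_kg_min": VO2Unit.REL_ML_KG_MIN,
    "ml_min": VO2Unit.ABS_ML_MIN,
    "l_min": VO2Unit.ABS_L_MIN,
}


def load_model_file(path: str | Path) -> list[ModelSpec]:
    """Load simple linear models from a declarative YAML/JSON file.

    Each entry: ``{name, unit (rel|ml_min|l_min), intercept, terms: {field:
    coef}, sexes: [...], modalities: [...]}``.
    """
    text = Path(path).read_text(encoding="utf-8")
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    specs = []
    for entry in data:
        specs.append(
            linear_model_spec(
                model_id=entry["name"],
                output_unit=_UNIT_ALIASES.get(str(entry["unit"]).lower(), entry["unit"]),
                intercept=float(entry.get("intercept", 0.0)),
                terms={k: float(v) for k, v in entry.get("terms", {}).items()},
                sexes=entry.get("sexes", ("male", "female")),
                modalities=entry.get("modalities", ("TE", "CE")),
                source_label=entry.get("source", entry["name"]),
                citation=entry.get("citation", "declarative model file"),
            )
        )
    return specs
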