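"""Table rendering, end-to-end pipeline and plot-ready exports.

Two output tiers: machine CSV/JSON at full float precision, and human
tables rounded to two decimals with ``‡`` marking subgroups below the
n >= 100 reliability threshold and ``n/a`` for non-applicable sex/model
cells.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from vo2val import __version__
from vo2val.cohort import (
    CPETRecord,
    cohort_to_frame,
    read_cohort,
    write_cohort,
)
from vo2val.eligibility import apply_inclusion
from vo2val.registry import ModelSpec, builtin_models, predict_cohort
from vo2val.stratify import RELIABLE_MIN_N, stratify
from vo2val.synthetic import GeneratorConfig, default_config, generate_cohort
from vo2val.validation import C1Convention, fit_calibration, validate

__all__ = [
    "render_performance_table",
    "run_pipeline",
    "export_regression_data",
    "PipelineConfig",
]

log = logging.getLogger("vo2val")

VO2_WINDOW_S = 15.0  # averaging window used for the VO2max definition

_METRIC_COLS = ("r2_adj", "rmse", "c1", "c2")


class ReportError(RuntimeError):
    """A report cannot be rendered from the supplied metrics."""


def render_performance_table(
    metrics: pd.DataFrame,
    axis: str = "endurance",
    metric_cols: Sequence[str] = _METRIC_COLS,
) -> pd.DataFrame:
    """Render a human-readable model-performance table for one axis.

    One row per model (grouped by modality panel), one column block per
    sex x subgroup with the requested metrics; values rounded to 2
    decimals; ``‡`` marks subgroups with n < 100; ``n/a`` fills cells for
    which the model does not apply.  Raises :class:`ReportError` listing
    missing cells if the metrics table does not cover the layout.
    """
    sel = metrics[metrics["axis"] == axis]
    if sel.empty:
        raise ReportError(f"no metric rows for axis {axis!r}")
    subgroups = list(dict.fromkeys(sel["subgroup"]))
    models = list(dict.fromkeys(zip(sel["model_id"], sel["source"], sel["unit"], sel["modality"])))

    # layout completeness check: every applicable model must have a row for
    # every subgroup of the axis (n=0 rows count as present)
    missing = []
    for model_id, _, _, modality in models:
        have = sel[(sel["model_id"] == model_id) & (sel["modality"] == modality)]
        for sg in subgroups:
            for sex in have["sex"].unique():
                cell = have[(have["subgroup"] == sg) & (have["sex"] == sex)]
                if cell.empty:
                    missing.append((model_id, modality, sex, sg))
    if missing:
        raise ReportError(f"missing metric cells: {missing}")

    out_rows = []
    for model_id, source, unit, modality in models:
        row: dict[str, str] = {
            "model": f"{source} ({unit})",
            "modality": modality,
        }
        have = sel[(sel["model_id"] == model_id) & (sel["modality"] == modality)]
        for sex in ("male", "female"):
            for sg in subgroups:
                cell = have[(have["subgroup"] == sg) & (have["sex"] == sex)]
                if cell.empty:
                    for m in metric_cols:
                        row[f"{sex}|{sg}|{m}"] = "n/a"
                    continue
                c = cell.iloc[0]
                marker = "‡" if c["n"] < RELIABLE_MIN_N else ""
                for m in metric_cols:
                    v = c[m]
                    if c["error"] or not np.isfinite(v):
                        row[f"{sex}|{sg}|{m}"] = f"–{marker}"
                    else:
                        row[f"{sex}|{sg}|{m}"] = f"{v:.2f}{marker}"
        out_rows.append(row)
    return pd.DataFrame(out_rows)


def export_regression_data(
    cohort: Sequence[CPETRecord],
    models: Sequence[ModelSpec] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready (predicted, observed) pairs and fitted-line coefficients.

    Returns ``(pairs, fits)``: pairs holds one row per record x applicable
    model; fits holds, per model x sex x modality, the OLS intercept/slope
    plus the quantities (residual variance, predictor mean, predictor sum
    of squares, n) needed to draw a 95% confidence band externally.  The
    fitted coefficients equal those of the validation engine by
    construction (same estimator).
    """
    specs = list(models) if models is not None else builtin_models()
    preds = predict_cohort(cohort, specs)
    pairs = preds[preds["applicable"] & (preds["error"] == "")].copy()
    by_subject = {r.subject_id: r for r in cohort}
    pairs["sex"] = [by_subject[s].sex.value for s in pairs["subject_id"]]
    pairs["modality"] = [by_subject[s].modality.value for s in pairs["subject_id"]]

    fit_rows = []
    for (model_id, sex, mod), grp in pairs.groupby(["model_id", "sex", "modality"]):
        o = grp["observed"].to_numpy(float)
        p = grp["predicted"].to_numpy(float)
        n = len(o)
        if n < 3 or np.ptp(p) == 0.0:
            continue
        cal = fit_calibration(o, p)
        resid = o - (cal.intercept + cal.slope * p)
        sigma2 = float(resid @ resid / (n - 2)) if n > 2 else np.nan
        fit_rows.append(
            {
                "model_id": model_id,
                "sex": sex,
                "modality": mod,
                "n": n,
                "intercept": cal.intercept,
                "slope": cal.slope,
                "sigma2": sigma2,
                "x_mean": float(p.mean()),
                "sxx": float(((p - p.mean()) ** 2).sum()),
            }
        )
    return pairs.drop(columns=["applicable", "error"]), pd.DataFrame(fit_rows)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run configuration."""

    n: int = 2000
    seed: int = 0
    input_csv: str | None = None  # read instead of generate when set
    c1_convention: str = C1Convention.FREE_INTERCEPT.value
    min_n: int = 3
    axes: tuple[str, ...] = ("whole", "endurance", "age")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """generate (or read) → filter → classify → predict → validate → report.

    Writes cohort, included cohort + exclusion ledger, stratified cohort,
    predictions, metrics, rendered tables, and a manifest making the bundle
    reproducible.  Returns the manifest dict.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "generate"
    try:
        if config.input_csv:
            cohort = read_cohort(config.input_csv)
            gen_cfg = None
        else:
            gen_cfg = default_config(n=config.n, seed=config.seed)
            cohort = generate_cohort(gen_cfg)
        write_cohort(cohort, out / "cohort.csv")
        log.info("generate: %d records", len(cohort))

        stage = "filter"
        included, ledger = apply_inclusion(cohort)
        write_cohort(included, out / "included.csv")
        (out / "exclusion_ledger.json").write_text(
            json.dumps(ledger.to_dict(), indent=2), encoding="utf-8"
        )
        log.info("filter: %d in / %d out", ledger.n_in, ledger.n_out)

        stage = "classify"
        labels, strata_summary = stratify(included)
        annotated = cohort_to_frame(included)
        annotated["age_group"] = [lb.age_group.value for lb in labels]
        annotated["endurance_group"] = [lb.endurance_group.value for lb in labels]
        annotated["rcp_z"] = [lb.z for lb in labels]
        annotated.to_csv(out / "classified.csv", index=False, encoding="utf-8")

        stage = "predict"
        specs = builtin_models()
        preds = predict_cohort(included, specs)
        preds.to_csv(out / "predictions.csv", index=False, encoding="utf-8")

        stage = "validate"
        metrics = validate(
            included,
            labels,
            specs,
            axes=config.axes,
            c1_convention=C1Convention(config.c1_convention),
            min_n=config.min_n,
        )
        metrics.to_csv(out / "metrics.csv", index=False, encoding="utf-8")

        stage = "report"
        for axis in config.axes:
            table = render_performance_table(metrics, axis=axis)
            table.to_csv(out / f"table_{axis}.csv", index=False, encoding="utf-8")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    cfg_dict = dataclasses.asdict(config)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "package": "vo2val",
        "version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_sha256": cfg_hash,
        "vo2_window_s": VO2_WINDOW_S,
        "n_generated": len(cohort),
        "n_included": len(included),
        "strata": strata_summary,
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return manifest
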