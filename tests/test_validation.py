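"""Calibration engine: OLS oracle equivalence, conventions, subgroup tables."""

import numpy as np
import pytest

from vo2val.cohort import InsufficientDataError
from vo2val.eligibility import apply_inclusion
from vo2val.registry import builtin_models, linear_model_spec
from vo2val.stratify import stratify
from vo2val.synthetic import DefectSpec, default_config, generate_cohort, inject_predictions
from vo2val.validation import (
    C1Convention,
    DegenerateFitError,
    MeanDifference,
    calibration_in_the_large,
    effect_size_class,
    fit_calibration,
    mean_difference,
    validate,
)


def ols_oracle(o: np.ndarray, p: np.ndarray) -> dict:
    """Closed-form two-pass simple OLS of o on p (independent of statsmodels)."""
    n = len(o)
    pm, om = p.mean(), o.mean()
    sxx = np.sum((p - pm) ** 2)
    sxy = np.sum((p - pm) * (o - om))
    slope = sxy / sxx
    intercept = om - slope * pm
    resid = o - intercept - slope * p
    sse = np.sum(resid**2)
    sst = np.sum((o - om) ** 2)
    r2 = 1.0 - sse / sst
    return {
        "slope": slope,
        "intercept": intercept,
        "r2": r2,
        "r2_adj": 1.0 - (1.0 - r2) * (n - 1) / (n - 2),
        "rmse": np.sqrt(sse / n),
    }


class TestFitCalibration:
    def test_identity_gives_perfect_calibration(self):
        x = np.linspace(40.0, 60.0, 50)
        cal = fit_calibration(x, x)
        assert cal.slope == pytest.approx(1.0, abs=1e-12)
        assert cal.intercept == pytest.approx(0.0, abs=1e-9)
        assert cal.r2_adj == pytest.approx(1.0, abs=1e-12)
        assert cal.rmse == pytest.approx(0.0, abs=1e-9)
        assert cal.c2 == cal.slope

    def test_doubling_gives_slope_two(self):
        p = np.linspace(30.0, 50.0, 40)
        cal = fit_calibration(2.0 * p, p)
        assert cal.slope == pytest.approx(2.0, abs=1e-12)
        assert cal.intercept == pytest.approx(0.0, abs=1e-9)
        assert cal.rmse == pytest.approx(0.0, abs=1e-9)

    def test_matches_closed_form_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 60))
            p = rng.normal(50, 5, n)
            o = rng.normal(50, 5, n)
            cal = fit_calibration(o, p)
            exp = ols_oracle(o, p)
            for key in ("slope", "intercept", "r2_adj", "rmse"):
                assert getattr(cal, key if key != "slope" else "slope") == pytest.approx(
                    exp[key], abs=1e-10, rel=1e-10
                )

    def test_r2_equals_squared_pearson(self, rng):
        p = rng.normal(50, 5, 200)
        o = 0.7 * p + rng.normal(0, 3, 200)
        cal = fit_calibration(o, p)
        assert cal.r2 == pytest.approx(np.corrcoef(o, p)[0, 1] ** 2, abs=1e-12)

    def test_negative_adjusted_r2_on_uncorrelated_pairs(self, rng):
        found = False
        for seed in range(20):
            r = np.random.default_rng(seed)
            o, p = r.normal(size=10), r.normal(size=10)
            if fit_calibration(o, p).r2_adj < 0:
                found = True
                break
        assert found

    def test_degenerate_and_insufficient_inputs(self):
        with pytest.raises(DegenerateFitError):
            fit_calibration([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        with pytest.raises(InsufficientDataError):
            fit_calibration([1.0, 2.0], [1.0, 2.0])

    def test_order_invariance(self, rng):
        p = rng.normal(50, 5, 100)
        o = 0.9 * p + rng.normal(0, 2, 100)
        a = fit_calibration(o, p)
        idx = rng.permutation(100)
        b = fit_calibration(o[idx], p[idx])
        assert a.slope == pytest.approx(b.slope, abs=1e-12)
        assert a.rmse == pytest.approx(b.rmse, abs=1e-12)


class TestCalibrationInTheLarge:
    def test_identity_zero_under_both_conventions(self):
        x = np.linspace(40, 60, 30)
        for conv in C1Convention:
            val, tag = calibration_in_the_large(x, x, conv)
            assert val == pytest.approx(0.0, abs=1e-9)
            assert tag is conv

    def test_pure_shift_mean_difference_convention(self):
        o = np.linspace(40, 60, 30)
        val, _ = calibration_in_the_large(o, o - 5.0, C1Convention.MEAN_DIFFERENCE)
        assert val == pytest.approx(5.0)

    def test_recovers_injected_defect(self):
        cohort = generate_cohort(default_config(n=10_000, seed=51))
        obs, pred = inject_predictions(cohort, DefectSpec(c0=10, c1=0.8, noise_sd=2, seed=5))
        c1, _ = calibration_in_the_large(obs, pred, C1Convention.FREE_INTERCEPT)
        cal = fit_calibration(obs, pred)
        assert c1 == pytest.approx(10.0, abs=1.0)
        assert cal.slope == pytest.approx(0.8, abs=0.02)


class TestMeanDifference:
    def test_underestimation_sign(self):
        md = mean_difference([50.0, 52.0], [48.0, 50.0])
        assert md.mean_diff == pytest.approx(-2.0)

    def test_zero_variance_edge(self):
        md = mean_difference([50.0, 52.0, 54.0], [50.0, 52.0, 54.0])
        assert md.mean_diff == 0.0 and md.p == 1.0
        assert md.ci95_low == md.ci95_high == 0.0

    def test_matches_textbook_t_interval(self, rng):
        from scipy import stats as st

        o = rng.normal(50, 5, 40)
        p = o + rng.normal(1.0, 2.0, 40)
        md = mean_difference(o, p)
        d = p - o
        se = d.std(ddof=1) / np.sqrt(len(d))
        tcrit = st.t.ppf(0.975, len(d) - 1)
        assert md.ci95_low == pytest.approx(d.mean() - tcrit * se, abs=1e-12)
        assert md.ci95_high == pytest.approx(d.mean() + tcrit * se, abs=1e-12)
        tt = st.ttest_rel(p, o)
        assert md.p == pytest.approx(tt.pvalue, abs=1e-12)

    def test_n1_raises(self):
        with pytest.raises(InsufficientDataError):
            mean_difference([50.0], [48.0])


class TestEffectSize:
    @pytest.mark.parametrize(
        "r2, label",
        [(0.1, "none/very-weak"), (0.4, "weak/low"), (0.6, "moderate"), (0.8, "high")],
    )
    def test_cutoffs(self, r2, label):
        assert effect_size_class(r2) == label


@pytest.fixture(scope="module")
def validated():
    cohort = generate_cohort(default_config(n=1500, seed=61))
    included, _ = apply_inclusion(cohort)
    labels, _ = stratify(included)
    metrics = validate(included, labels)
    return included, labels, metrics


class TestValidate:
    def test_row_count_is_panels_times_subgroups(self, validated):
        _, _, metrics = validated
        # per model: (sexes x modalities applicable) x (1 whole + 3 endurance + 4 age)
        expected = sum(
            len(m.sex_applicability) * len(m.modality_applicability) * 8
            for m in builtin_models()
        )
        assert len(metrics) == expected

    def test_transition_absent_from_endurance_axis(self, validated):
        _, _, metrics = validated
        endurance_groups = set(metrics[metrics["axis"] == "endurance"]["subgroup"])
        assert endurance_groups == {"HTEA", "REA", "LTEA"}

    def test_whole_axis_includes_all_records(self, validated):
        included, _, metrics = validated
        whole = metrics[(metrics["axis"] == "whole") & (metrics["model_id"] == "myers")]
        n_te = sum(1 for r in included if r.modality.value == "TE")
        assert whole["n"].sum() == n_te

    def test_reliability_flag_thresholds(self, validated):
        _, _, metrics = validated
        assert (metrics["reliable"] == (metrics["n"] >= 100)).all()

    def test_degenerate_rows_marked_not_dropped(self, validated):
        included, labels, _ = validated
        const = linear_model_spec("const40", "mL·min⁻¹·kg⁻¹", 40.0)
        metrics = validate(included, labels, [const])
        fitted = metrics[metrics["error"] == ""]
        assert len(fitted) == 0
        assert set(metrics["error"]) <= {"degenerate fit", "insufficient n"}

    def test_perfect_model_scores_perfectly(self, validated):
        included, labels, _ = validated
        perfect = linear_model_spec(
            "oracle", "mL·min⁻¹·kg⁻¹", 0.0, terms={"vo2max_rel": 1.0}
        )
        metrics = validate(included, labels, [perfect])
        ok = metrics[metrics["error"] == ""]
        assert (ok["c2"] - 1.0).abs().max() < 1e-9
        assert (ok["r2_adj"] - 1.0).abs().max() < 1e-9
        assert ok["rmse"].max() < 1e-9
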