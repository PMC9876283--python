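"""Domain types, unit conversions, CSV round trips and the 15-s VO2 filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vo2val.cohort import (
    BreathSeries,
    CohortFormatError,
    InsufficientDataError,
    RecordValidationError,
    VO2Unit,
    convert_vo2,
    derive_absolute_vo2,
    read_cohort,
    vo2max_15s,
    write_cohort,
)
from vo2val.synthetic import default_config, generate_cohort

from conftest import make_record


class TestRecordInvariants:
    def test_valid_record_constructs(self):
        make_record()

    @pytest.mark.parametrize(
        "overrides",
        [
            {"bmi": 30.0},  # inconsistent with mass/height
            {"vo2max_rel": 0.0},
            {"vo2max_rel": -5.0},
            {"borg_peak": 5},
            {"borg_peak": 21},
            {"ffm": 80.0},  # exceeds body mass of 75
            {"rcp_speed": None},  # TE record without its RCP variable
            {"rcp_power_rel": 3.0},  # TE record with both RCP variables
            {"height": 0.0},
        ],
    )
    def test_invariant_violations_rejected(self, overrides):
        with pytest.raises(RecordValidationError):
            make_record(**overrides)

    def test_ce_record_carries_power_only(self):
        rec = make_record(modality="CE")
        assert rec.rcp_speed is None and rec.rcp_power_rel == 3.5
        assert rec.rcp_value == 3.5


class TestCohortIO:
    def test_three_row_csv_roundtrip(self, tmp_path):
        cohort = [make_record(subject_id=f"S{i}") for i in range(3)]
        path = tmp_path / "c.csv"
        write_cohort(cohort, path)
        back = read_cohort(path)
        assert len(back) == 3

    def test_missing_column_names_the_column(self, tmp_path):
        cohort = [make_record()]
        path = tmp_path / "c.csv"
        write_cohort(cohort, path)
        text = path.read_text()
        broken = text.replace("vo2max_rel", "vo2")
        path.write_text(broken)
        with pytest.raises(CohortFormatError, match="vo2max_rel"):
            read_cohort(path)

    def test_invalid_row_rejected_with_diagnostics(self, tmp_path):
        cohort = [make_record(subject_id="OK"), make_record(subject_id="BAD")]
        path = tmp_path / "c.csv"
        write_cohort(cohort, path)
        lines = path.read_text().splitlines()
        # zero out height of the second record -> BMI invariant unverifiable
        lines[2] = lines[2].replace("180.0", "0.0", 1)
        path.write_text("\n".join(lines))
        records, diagnostics = read_cohort(path, strict=False)
        assert len(records) == 1 and records[0].subject_id == "OK"
        assert len(diagnostics) == 1 and diagnostics[0][0] == 1

    def test_synthetic_roundtrip_is_lossless(self, tmp_path):
        cohort = generate_cohort(default_config(n=100, seed=11))
        path = tmp_path / "c.csv"
        write_cohort(cohort, path)
        back = read_cohort(path)
        assert len(back) == len(cohort)
        for a, b in zip(cohort, back):
            assert a.subject_id == b.subject_id
            assert a.sex is b.sex and a.modality is b.modality
            for f in ("age", "height", "body_mass", "vo2max_rel", "rer_peak",
                      "la_peak", "hr_peak", "post_rcp_intensity_gain_pct"):
                assert getattr(a, f) == pytest.approx(getattr(b, f), rel=0, abs=1e-9)
            assert (a.rcp_speed is None) == (b.rcp_speed is None)


class TestVO2Max15s:
    def test_constant_series(self):
        s = BreathSeries(np.arange(0, 61, 1.0), np.full(61, 4000.0))
        assert vo2max_15s(s) == pytest.approx(4000.0)

    def test_plateau_block_dominates(self):
        t = np.arange(0, 121, 1.0)
        v = np.full_like(t, 3000.0)
        v[(t >= 60) & (t <= 75)] = 4000.0  # a full 15-s block at 4000
        assert vo2max_15s(BreathSeries(t, v)) == pytest.approx(4000.0)

    def test_linear_ramp_matches_brute_force_oracle(self):
        t = np.arange(0.0, 601.0, 1.0)
        v = 2000.0 + (t / 600.0) * 2000.0
        result = vo2max_15s(BreathSeries(t, v))
        # independent oracle: trapezoidal means of every sample-aligned window
        best = -np.inf
        for i, start in enumerate(t):
            end = start + 15.0
            if end > t[-1]:
                break
            grid = np.linspace(start, end, 151)
            vals = np.interp(grid, t, v)
            best = max(best, np.trapezoid(vals, grid) / 15.0)
        assert result == pytest.approx(best, rel=1e-9)
        assert result == pytest.approx(3975.0, rel=1e-9)  # midpoint of last window

    def test_leading_baseline_invariance(self):
        t = np.arange(0.0, 121.0, 1.0)
        v = np.where(t >= 100, 4200.0, 3100.0)
        base = vo2max_15s(BreathSeries(t, v))
        t2 = np.concatenate([np.arange(-60.0, 0.0, 1.0), t])
        v2 = np.concatenate([np.full(60, 1500.0), v])
        assert vo2max_15s(BreathSeries(t2, v2)) == pytest.approx(base)

    def test_short_series_raises(self):
        s = BreathSeries(np.array([0.0, 5.0, 10.0]), np.array([3.0, 3.0, 3.0]))
        with pytest.raises(InsufficientDataError):
            vo2max_15s(s)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        bump=st.floats(min_value=0.0, max_value=2000.0),
        n=st.integers(min_value=30, max_value=120),
    )
    def test_monotone_in_pointwise_ordering(self, bump, n):
        """A pointwise-larger series never yields a smaller 15-s maximum."""
        rng = np.random.default_rng(n)
        t = np.cumsum(rng.uniform(0.5, 2.0, size=n))
        v = rng.uniform(2000.0, 4000.0, size=n)
        lo = vo2max_15s(BreathSeries(t, v))
        hi = vo2max_15s(BreathSeries(t, v + bump))
        assert hi >= lo - 1e-9


class TestUnitConversion:
    def test_abs_ml_to_l(self):
        assert convert_vo2(4000, VO2Unit.ABS_ML_MIN, VO2Unit.ABS_L_MIN) == 4.0

    def test_abs_to_rel(self):
        assert convert_vo2(4000, VO2Unit.ABS_ML_MIN, VO2Unit.REL_ML_KG_MIN, 80) == 50.0

    def test_rel_to_abs_hand_value(self):
        # 52.97 mL·min⁻¹·kg⁻¹ x 70 kg = 3707.9 mL·min⁻¹
        got = convert_vo2(52.97, VO2Unit.REL_ML_KG_MIN, VO2Unit.ABS_ML_MIN, 70)
        assert got == pytest.approx(3707.9)

    def test_missing_mass_raises(self):
        with pytest.raises(ValueError):
            convert_vo2(50, VO2Unit.REL_ML_KG_MIN, VO2Unit.ABS_ML_MIN)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        value=st.floats(min_value=0.5, max_value=6000.0),
        mass=st.floats(min_value=40.0, max_value=140.0),
        order=st.permutations([VO2Unit.REL_ML_KG_MIN, VO2Unit.ABS_ML_MIN, VO2Unit.ABS_L_MIN]),
    )
    def test_conversion_cycles_return_start(self, value, mass, order):
        """Any cycle of conversions is the identity within 1e-9 relative."""
        x = value
        units = list(order) + [order[0]]
        for a, b in zip(units[:-1], units[1:]):
            x = convert_vo2(x, a, b, mass)
        assert x == pytest.approx(value, rel=1e-9)

    def test_derive_absolute_consistent_with_convert(self):
        for i in range(10):
            rec = make_record(vo2max_rel=40.0 + i, body_mass=60.0 + i, subject_id=f"r{i}")
            assert derive_absolute_vo2(rec) == pytest.approx(
                convert_vo2(rec.vo2max_rel, VO2Unit.REL_ML_KG_MIN, VO2Unit.ABS_ML_MIN, rec.body_mass)
            )
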