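import numpy as np
import pytest

from vo2val.cohort import CPETRecord, Modality, Sex


def make_record(**overrides) -> CPETRecord:
    """A valid male treadmill record passing all seven exertion criteria."""
    kw = dict(
        subject_id="T0001",
        sex=Sex.MALE,
        age=30.0,
        height=180.0,
        body_mass=75.0,
        bmi=75.0 / 1.8**2,
        body_fat_pct=15.0,
        ffm=75.0 * 0.85,
        modality=Modality.TE,
        vo2max_rel=55.0,
        rer_peak=1.15,
        la_peak=10.0,
        fr_peak=50.0,
        borg_peak=19,
        hr_peak=185.0,
        plateau_observed=True,
        post_rcp_intensity_gain_pct=15.0,
        training_months=24.0,
        rcp_speed=15.0,
        rcp_power_rel=None,
    )
    kw.update(overrides)
    if "modality" in overrides:
        m = Modality(overrides["modality"])
        if m is Modality.CE and "rcp_power_rel" not in overrides:
            kw["rcp_speed"], kw["rcp_power_rel"] = None, 3.5
    if (
        ("body_mass" in overrides or "height" in overrides)
        and "bmi" not in overrides
        and kw["height"] > 0
    ):
        kw["bmi"] = kw["body_mass"] / (kw["height"] / 100.0) ** 2
        kw["ffm"] = min(kw["ffm"], kw["body_mass"])
    return CPETRecord(**kw)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic synthetic cohort reused across read-only tests."""
    from vo2val.synthetic import default_config, generate_cohort

    return generate_cohort(default_config(n=400, seed=7))
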