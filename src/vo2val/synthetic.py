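"""Synthetic CPET cohort generator calibrated to printed population parameters.

The generator draws athletes with the marginal structure the validation
pipeline assumes: a male/female mix, per-sex anthropometrics (truncated
normals), a per-sex treadmill/cycle split, per sex x modality relative
VO2max, and a respiratory-compensation-point (RCP) variable correlated with
VO2max inside each stratum (this correlation is what makes SD-based
endurance classification meaningful).  Age and VO2max are tied through a
Gaussian copula on (age, latent fitness).

Effort variables (RER, lactate, breathing frequency, Borg, heart-rate
margin) default to distributions under which most — not all — athletes
satisfy each maximal-exertion criterion, so the eligibility filter has
realistic work to do.  ``contaminate`` additionally plants records that
violate one named criterion each, with a log, for filter round-trip tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from vo2val.cohort import CPETRecord, Modality, Sex

__all__ = [
    "TruncatedNormal",
    "StratumVO2",
    "GeneratorConfig",
    "DefectSpec",
    "default_config",
    "generate_cohort",
    "inject_predictions",
    "contaminate",
    "DEFECT_KINDS",
]


@lru_cache(maxsize=None)
def _match_truncnorm(
    mean: float, sd: float, lower: float, upper: float
) -> tuple[float, float]:
    """Location/scale of a normal whose truncation to [lower, upper] has the
    requested mean and SD (moment matching, so configured marginals are the
    marginals actually generated)."""
    if np.isinf(lower) and np.isinf(upper):
        return mean, sd

    def moments(params: np.ndarray) -> np.ndarray:
        loc, log_scale = params
        scale = np.exp(log_scale)
        a, b = (lower - loc) / scale, (upper - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return np.array([m - mean, np.sqrt(v) - sd])

    x0 = np.array([mean, np.log(sd)])
    if np.max(np.abs(moments(x0))) < 1e-9:  # truncation effectively inactive
        return mean, sd
    sol = optimize.root(moments, x0=x0)
    if np.max(np.abs(moments(sol.x))) > 1e-6:
        raise ValueError(
            f"cannot match truncated-normal moments mean={mean}, sd={sd} "
            f"on [{lower}, {upper}]"
        )
    return float(sol.x[0]), float(np.exp(sol.x[1]))


@dataclass(frozen=True)
class TruncatedNormal:
    """Target mean/SD with truncation bounds (all in data units).

    ``mean``/``sd`` are the moments of the *truncated* distribution; the
    underlying normal's location and scale are solved by moment matching so
    that samples actually have the configured mean and SD.
    """

    mean: float
    sd: float
    lower: float = -np.inf
    upper: float = np.inf

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError(f"sd must be positive (got {self.sd})")

    def ppf(self, u: np.ndarray) -> np.ndarray:
        loc, scale = _match_truncnorm(self.mean, self.sd, self.lower, self.upper)
        a = (self.lower - loc) / scale
        b = (self.upper - loc) / scale
        return stats.truncnorm.ppf(u, a, b, loc=loc, scale=scale)


@dataclass(frozen=True)
class StratumVO2:
    """Relative VO2max mean/SD (mL·min⁻¹·kg⁻¹) for one sex x modality cell."""

    mean: float
    sd: float


@dataclass(frozen=True)
class GeneratorConfig:
    """All distributional parameters of the synthetic cohort.

    Defaults reproduce the study population this package emulates:
    84.76% male; male age 35.04 (9.58) / female 32.25 (8.99) years;
    heights 179.42 (6.60) / 167.19 (6.88) cm; masses 77.23 (10.32) /
    60.60 (8.73) kg; body fat 15.68 (4.55) / 22.04 (5.46) %; treadmill
    fractions 3330/4459 (male) and 671/801 (female); relative VO2max
    54.10 (6.93) male-TE, 51.92 (8.05) male-CE, 48.79 (6.67) female-TE,
    49.05 (6.64) female-CE.  Fat-free mass is computed from mass and body
    fat, never sampled.
    """

    n: int = 5260
    male_fraction: float = 0.8476
    # per-sex anthropometrics
    age: dict[Sex, TruncatedNormal] = field(
        default_factory=lambda: {
            Sex.MALE: TruncatedNormal(35.04, 9.58, lower=18.0),
            Sex.FEMALE: TruncatedNormal(32.25, 8.99, lower=18.0),
        }
    )
    height: dict[Sex, TruncatedNormal] = field(
        default_factory=lambda: {
            Sex.MALE: TruncatedNormal(179.42, 6.60, lower=140.0, upper=220.0),
            Sex.FEMALE: TruncatedNormal(167.19, 6.88, lower=130.0, upper=210.0),
        }
    )
    body_mass: dict[Sex, TruncatedNormal] = field(
        default_factory=lambda: {
            Sex.MALE: TruncatedNormal(77.23, 10.32, lower=40.0, upper=140.0),
            Sex.FEMALE: TruncatedNormal(60.60, 8.73, lower=35.0, upper=120.0),
        }
    )
    body_fat_pct: dict[Sex, TruncatedNormal] = field(
        default_factory=lambda: {
            Sex.MALE: TruncatedNormal(15.68, 4.55, lower=3.0, upper=45.0),
            Sex.FEMALE: TruncatedNormal(22.04, 5.46, lower=5.0, upper=50.0),
        }
    )
    te_probability: dict[Sex, float] = field(
        default_factory=lambda: {
            Sex.MALE: 3330.0 / 4459.0,
            Sex.FEMALE: 671.0 / 801.0,
        }
    )
    vo2max: dict[tuple[Sex, Modality], StratumVO2] = field(
        default_factory=lambda: {
            (Sex.MALE, Modality.TE): StratumVO2(54.10, 6.93),
            (Sex.MALE, Modality.CE): StratumVO2(51.92, 8.05),
            (Sex.FEMALE, Modality.TE): StratumVO2(48.79, 6.67),
            (Sex.FEMALE, Modality.CE): StratumVO2(49.05, 6.64),
        }
    )
    age_vo2_corr: float = -0.4
    rcp_vo2_corr: float = 0.9
    # RCP variable: speed at RCP (km·h⁻¹) for TE, relative power (W·kg⁻¹) for CE
    rcp: dict[tuple[Sex, Modality], StratumVO2] = field(
        default_factory=lambda: {
            (Sex.MALE, Modality.TE): StratumVO2(15.0, 1.8),
            (Sex.MALE, Modality.CE): StratumVO2(3.5, 0.6),
            (Sex.FEMALE, Modality.TE): StratumVO2(13.5, 1.6),
            (Sex.FEMALE, Modality.CE): StratumVO2(3.1, 0.5),
        }
    )
    # effort-variable distributions (shared across sexes)
    rer: TruncatedNormal = TruncatedNormal(1.14, 0.04, lower=0.7)
    lactate: TruncatedNormal = TruncatedNormal(10.0, 2.0, lower=0.5)
    fr: TruncatedNormal = TruncatedNormal(55.0, 8.0, lower=10.0)
    post_rcp_gain: TruncatedNormal = TruncatedNormal(15.0, 3.0, lower=0.0)
    hr_margin_mean: float = 5.0  # HR_peak = HRmax_pred − |N(mean, sd)|
    hr_margin_sd: float = 5.0
    borg_values: tuple[int, ...] = (18, 19, 20)
    training_months_log_mean: float = 3.58  # log-months; exp(3.58) ≈ 36
    training_months_log_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must be in [0, 1]")
        for s, p in self.te_probability.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"te_probability[{s}] must be in [0, 1]")
        for tn in (*self.age.values(),):
            if tn.lower < 18.0:
                raise ValueError("age truncation must keep age >= 18")
        for sv in (*self.vo2max.values(), *self.rcp.values()):
            if not sv.sd > 0:
                raise ValueError("stratum SDs must be positive")
        if not -1.0 < self.age_vo2_corr < 1.0:
            raise ValueError("age_vo2_corr must lie in (-1, 1)")
        if not -1.0 < self.rcp_vo2_corr < 1.0:
            raise ValueError("rcp_vo2_corr must lie in (-1, 1)")


@dataclass(frozen=True)
class DefectSpec:
    """Linear miscalibration planted between observed and predicted values.

    Generates pairs with observed = c0 + c1·predicted + Normal(0, noise_sd),
    so that a calibration fit should recover intercept c0 and slope c1.
    """

    c0: float = 0.0
    c1: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.c1 == 0:
            raise ValueError("c1 = 0 leaves the calibration slope undefined")


def default_config(**overrides) -> GeneratorConfig:
    """Config whose marginals equal the emulated study's printed values."""
    return GeneratorConfig(**overrides)


def generate_cohort(config: GeneratorConfig | None = None) -> list[CPETRecord]:
    """Draw a synthetic cohort of maximal CPET records.

    Deterministic for a fixed config (the seed lives in the config).  Sample
    means/SDs of every configured marginal converge to the configured values;
    the RCP variable has correlation ``rcp_vo2_corr`` with relative VO2max
    within each sex x modality stratum.
    """
    cfg = config or default_config()
    if cfg.n <= 0:
        raise ValueError(f"cohort size must be positive (got {cfg.n})")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n

    male = rng.random(n) < cfg.male_fraction
    sexes = np.where(male, Sex.MALE.value, Sex.FEMALE.value)
    p_te = np.where(male, cfg.te_probability[Sex.MALE], cfg.te_probability[Sex.FEMALE])
    te = rng.random(n) < p_te
    modalities = np.where(te, Modality.TE.value, Modality.CE.value)

    # Gaussian copula: z_age and latent fitness share corr age_vo2_corr;
    # the RCP variable loads on fitness with corr rcp_vo2_corr.
    z_age = rng.standard_normal(n)
    rho_a, rho_r = cfg.age_vo2_corr, cfg.rcp_vo2_corr
    z_fit = rho_a * z_age + np.sqrt(1.0 - rho_a**2) * rng.standard_normal(n)
    z_rcp = rho_r * z_fit + np.sqrt(1.0 - rho_r**2) * rng.standard_normal(n)

    def per_sex(dists: dict[Sex, TruncatedNormal], u: np.ndarray) -> np.ndarray:
        out = np.empty(n)
        for sex, mask in ((Sex.MALE, male), (Sex.FEMALE, ~male)):
            if mask.any():
                out[mask] = dists[sex].ppf(u[mask])
        return out

    age = per_sex(cfg.age, stats.norm.cdf(z_age))
    height = per_sex(cfg.height, rng.random(n))
    mass = per_sex(cfg.body_mass, rng.random(n))
    bf = per_sex(cfg.body_fat_pct, rng.random(n))

    vo2_mean = np.empty(n)
    vo2_sd = np.empty(n)
    rcp_mean = np.empty(n)
    rcp_sd = np.empty(n)
    for (sex, mod), sv in cfg.vo2max.items():
        mask = (sexes == sex.value) & (modalities == mod.value)
        vo2_mean[mask], vo2_sd[mask] = sv.mean, sv.sd
        rv = cfg.rcp[(sex, mod)]
        rcp_mean[mask], rcp_sd[mask] = rv.mean, rv.sd
    vo2 = np.maximum(vo2_mean + vo2_sd * z_fit, 10.0)
    rcp_val = np.maximum(rcp_mean + rcp_sd * z_rcp, 0.1)

    rer = cfg.rer.ppf(rng.random(n))
    la = cfg.lactate.ppf(rng.random(n))
    fr = cfg.fr.ppf(rng.random(n))
    gain = cfg.post_rcp_gain.ppf(rng.random(n))
    borg = rng.choice(np.array(cfg.borg_values), size=n)
    hr_margin = np.abs(rng.normal(cfg.hr_margin_mean, cfg.hr_margin_sd, size=n))
    hr_peak = 220.0 - age - hr_margin
    training = np.maximum(
        3.0, rng.lognormal(cfg.training_months_log_mean, cfg.training_months_log_sd, n)
    )

    bmi = mass / (height / 100.0) ** 2
    ffm = mass * (1.0 - bf / 100.0)

    records: list[CPETRecord] = []
    for i in range(n):
        is_te = te[i]
        records.append(
            CPETRecord(
                subject_id=f"EA{i + 1:06d}",
                sex=Sex(sexes[i]),
                age=float(age[i]),
                height=float(height[i]),
                body_mass=float(mass[i]),
                bmi=float(bmi[i]),
                body_fat_pct=float(bf[i]),
                ffm=float(ffm[i]),
                modality=Modality(modalities[i]),
                vo2max_rel=float(vo2[i]),
                rer_peak=float(rer[i]),
                la_peak=float(la[i]),
                fr_peak=float(fr[i]),
                borg_peak=int(borg[i]),
                hr_peak=float(hr_peak[i]),
                plateau_observed=True,
                post_rcp_intensity_gain_pct=float(gain[i]),
                training_months=float(training[i]),
                rcp_speed=float(rcp_val[i]) if is_te else None,
                rcp_power_rel=None if is_te else float(rcp_val[i]),
            )
        )
    return records


def inject_predictions(
    cohort: Sequence[CPETRecord], defect: DefectSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Build a pseudo-model with a known calibration defect.

    The cohort's relative VO2max values serve as the predictions; observed
    values are manufactured as ``c0 + c1·predicted + Normal(0, noise_sd)``.
    Regressing observed on predicted should recover (c0, c1), which makes
    the pair a recovery target for the calibration engine.

    Returns ``(observed, predicted)`` arrays (mL·min⁻¹·kg⁻¹).
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be non-empty")
    rng = np.random.default_rng(defect.seed)
    predicted = np.array([r.vo2max_rel for r in cohort], dtype=float)
    noise = rng.normal(0.0, defect.noise_sd, size=len(predicted)) if defect.noise_sd else 0.0
    observed = defect.c0 + defect.c1 * predicted + noise
    return observed, predicted


# Named eligibility/effort defects contaminate() can plant, and how.
DEFECT_KINDS: tuple[str, ...] = (
    "age",
    "smoker",
    "rer",
    "borg",
    "lactate",
    "fr",
    "hr_proximity",
    "plateau",
    "post_rcp_gain",
    "outlier",
)


def contaminate(
    cohort: Sequence[CPETRecord], fraction: float, seed: int = 0
) -> tuple[list[CPETRecord], list[tuple[str, str]]]:
    """Plant eligibility violations in a fraction of records.

    ``round(fraction·n)`` records are each modified to violate exactly one
    named criterion, drawn round-robin from :data:`DEFECT_KINDS` in a
    seed-shuffled order.  Under the >=6-of-7 maximal-exertion rule a single
    broken effort criterion does not by itself exclude a record — it is
    detectable at the criterion level — whereas inclusion-rule defects
    (age, smoker, outlier) always exclude.

    Returns ``(new_cohort, log)`` where log lists ``(subject_id, defect)``.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    n = len(cohort)
    k = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    out = list(cohort)
    log: list[tuple[str, str]] = []
    if k == 0:
        return out, log
    idx = rng.choice(n, size=k, replace=False)
    kinds = list(DEFECT_KINDS)
    rng.shuffle(kinds)

    # within-sex VO2max stats of the *input* cohort, for the outlier defect
    vo2_stats: dict[Sex, tuple[float, float]] = {}
    for sex in Sex:
        vals = np.array([r.vo2max_rel for r in cohort if r.sex is sex])
        if len(vals) >= 2:
            vo2_stats[sex] = (float(vals.mean()), float(vals.std(ddof=1)))

    for j, i in enumerate(idx):
        r = out[i]
        kind = kinds[j % len(kinds)]
        if kind == "age":
            margin = r.hr_max_predicted - r.hr_peak
            r = replace(r, age=17.0, hr_peak=(220.0 - 17.0) - margin)
        elif kind == "smoker":
            r = replace(r, is_smoker=True)
        elif kind == "rer":
            r = replace(r, rer_peak=1.02)
        elif kind == "borg":
            r = replace(r, borg_peak=16)
        elif kind == "lactate":
            r = replace(r, la_peak=6.0)
        elif kind == "fr":
            r = replace(r, fr_peak=40.0)
        elif kind == "hr_proximity":
            r = replace(r, hr_peak=r.hr_max_predicted - 25.0)
        elif kind == "plateau":
            r = replace(r, plateau_observed=False)
        elif kind == "post_rcp_gain":
            r = replace(r, post_rcp_intensity_gain_pct=5.0)
        elif kind == "outlier":
            mu, sd = vo2_stats.get(r.sex, (r.vo2max_rel, 5.0))
            r = replace(r, vo2max_rel=mu + 5.0 * sd)
        out[i] = r
        log.append((r.subject_id, kind))
    return out, log
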