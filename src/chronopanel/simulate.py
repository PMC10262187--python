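"""Synthetic household-panel cohort generator with planted effects.

Emulates the statistical structure the analysis pipeline assumes, so that
every pipeline stage can be validated by parameter recovery:

* households of 1-6 members sharing a household ID (and a household random
  intercept in every biomarker),
* age- and sex-dependent chronotype (sex-specific cubic age trends plus
  person-level noise),
* social jetlag driven by chronotype, age, work hours, commuting and time
  stress, right-skewed with a point mass at zero,
* raw MCTQ-style bed/wake clock times constructed so that scoring exactly
  recovers the planted mid-sleeps, durations, and social jetlag,
* fasting-biomarker panel with planted fixed effects (social jetlag on
  total/LDL cholesterol; extreme-chronotype deviation on HDL,
  triglycerides and the atherogenic index), lab batch offsets, and a
  morning sampling time correlated with chronotype,
* a paired follow-up wave in which a "home office" subgroup receives
  planted within-person shifts of chronotype, social jetlag and sleep
  duration.

All randomness flows from ``numpy.random.default_rng`` seeded per stage
from the master seed, so identical (config, seed) pairs give identical
tables on any platform.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .clock import to_canonical_window
from .normalize import ANCHOR_AGE

# stage offsets for per-stage RNG streams
_STAGE_COHORT, _STAGE_MCTQ, _STAGE_BIO, _STAGE_FOLLOWUP = 1, 2, 3, 4


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class DemographicsModel:
    n_participants: int = 1600
    household_size_probs: tuple = (0.30, 0.44, 0.14, 0.08, 0.03, 0.01)
    head_age_mean: float = 52.0
    head_age_sd: float = 16.5
    age_min: float = 18.0
    age_max: float = 97.0
    p_female: float = 0.52
    # employment probability: p_work_max * expit((retire_age - age) / retire_scale)
    p_work_max: float = 0.92
    retire_age: float = 62.0
    retire_scale: float = 3.0


@dataclass
class ChronotypeModel:
    """Sex-specific cubic age trend of MSF_sc plus person-level noise.

    Coefficients are ascending-order polynomials on raw age in years,
    anchored so predicted MSF_sc runs from ~4.9 h at 18 to ~3.2 h at 90.
    """

    male_coef: tuple = (6.129625668, -0.08298467872, 0.00087880627, -3.53818295e-06)
    female_coef: tuple = (5.853983957, -0.07799072659, 0.0008307394675, -3.311122429e-06)
    person_sd: float = 0.9
    #: population mean MSF_sc implied by the defaults (used as centering
    #: reference for downstream models); refreshed by calibration.
    reference: float = 3.84


@dataclass
class SjlModel:
    """Social jetlag: zero-inflated gamma with a log-linear mean.

    log mu = intercept + coefficients on centered chronotype, age, work
    hours, commuting, time stress, sex and work status. The gamma component
    is strictly positive (no truncation needed); exact zeros come from the
    mixture weights.
    """

    gamma_shape: float = 2.05
    intercept: float = -0.079
    coef_chronotype: float = 0.18  # per h of MSF_sc above 4
    coef_age: float = -0.011  # per year above 50
    coef_male: float = 0.097
    coef_work_hours: float = 0.05  # per 10 h/week above 40 (workers)
    coef_commute: float = 0.04  # per 3.5 h/week of commuting (workers)
    coef_stress: float = 0.04  # per 5 points of time stress above 15
    nonworker_shift: float = -0.35
    p_zero_worker: float = 0.08
    p_zero_nonworker: float = 0.30


@dataclass
class SleepModel:
    sd_w_mean: float = 7.1
    sd_w_sd: float = 0.7
    oversleep_base: float = 0.5  # free-day oversleep intercept, h
    oversleep_per_sjl: float = 0.3
    oversleep_sd: float = 0.45
    nonworker_oversleep: float = 0.1
    nonworker_oversleep_sd: float = 0.2
    p_alarm_free: float = 0.10
    workday_probs: tuple = (0.10, 0.80, 0.10)  # 4, 5, 6 workdays for workers


@dataclass
class SamplingTimeModel:
    """Morning blood-draw time: later chronotypes come in later."""

    mean: float = 8.32
    slope: float = 0.188  # h per h of chronotype
    noise_sd: float = 1.114  # total SD targets 1.13 h


@dataclass
class BiomarkerModel:
    """Linear model for one biomarker on derived predictors.

    ``effects`` maps predictor names (SJL, MSF_sc_c, MAD, sex_female,
    age_c, BMI_c, diseases, sampling_time_c) to slopes on the outcome's
    units.
    """

    intercept: float
    effects: dict = field(default_factory=dict)
    hh_sd: float = 0.0
    resid_sd: float = 1.0
    floor: float | None = None


def _default_biomarkers() -> dict:
    return {
        "CHL": BiomarkerModel(
            intercept=5.3,
            effects={
                "SJL": 0.13, "MSF_sc_c": -0.025, "sex_female": 0.25,
                "age_c": 0.012, "BMI_c": 0.02, "diseases": 0.04,
            },
            hh_sd=0.30, resid_sd=0.95, floor=1.5,
        ),
        "LDL": BiomarkerModel(
            intercept=3.1,
            effects={
                "SJL": 0.109, "MSF_sc_c": -0.018, "sex_female": 0.08,
                "age_c": 0.004, "BMI_c": 0.01, "diseases": 0.035,
            },
            hh_sd=0.28, resid_sd=0.90, floor=0.5,
        ),
        "HDL": BiomarkerModel(
            intercept=1.45,
            effects={
                "SJL": 0.01, "MAD": -0.032, "sex_female": 0.25,
                "age_c": 0.002, "BMI_c": -0.025, "diseases": -0.005,
            },
            hh_sd=0.10, resid_sd=0.25, floor=0.4,
        ),
        "TAG": BiomarkerModel(
            intercept=1.6,
            effects={
                "SJL": -0.018, "MAD": 0.085, "sex_female": -0.15,
                "age_c": 0.003, "BMI_c": 0.04, "diseases": 0.01,
            },
            hh_sd=0.20, resid_sd=0.70, floor=0.2,
        ),
        "AIP": BiomarkerModel(
            intercept=0.02,
            effects={
                "SJL": -0.021, "MAD": 0.078, "sex_female": -0.12,
                "age_c": 0.0005, "BMI_c": 0.012, "diseases": 0.004,
            },
            hh_sd=0.08, resid_sd=0.28, floor=None,
        ),
        "glucose": BiomarkerModel(
            intercept=5.4,
            effects={"age_c": 0.015, "BMI_c": 0.05},
            hh_sd=0.25, resid_sd=1.1, floor=2.5,
        ),
        "CRP": BiomarkerModel(
            intercept=1.8,
            effects={"BMI_c": 0.15, "diseases": 0.10},
            hh_sd=0.30, resid_sd=2.2, floor=0.05,
        ),
        "cortisol": BiomarkerModel(
            intercept=470.0,
            effects={"sampling_time_c": -28.0, "MSF_sc_c": 25.2},
            hh_sd=25.0, resid_sd=135.0, floor=30.0,
        ),
        "testosterone": BiomarkerModel(
            intercept=9.5,
            effects={"sex_female": -15.6, "age_c": -0.04},
            hh_sd=0.8, resid_sd=3.5, floor=0.2,
        ),
        "DHEAS": BiomarkerModel(
            intercept=5.5,
            effects={"sex_female": -1.2, "age_c": -0.05},
            hh_sd=0.5, resid_sd=2.2, floor=0.3,
        ),
    }


@dataclass
class LabModel:
    n_labs: int = 8
    #: SD of the planted per-lab constant offset, per marker.
    offset_sd: dict = field(default_factory=lambda: {
        "CHL": 0.12, "LDL": 0.10, "HDL": 0.05, "TAG": 0.08, "AIP": 0.03,
        "glucose": 0.12, "CRP": 0.15, "cortisol": 18.0,
        "testosterone": 0.5, "DHEAS": 0.3,
    })


@dataclass
class FollowupModel:
    """Planted within-person two-wave shifts (minutes)."""

    home_office_n: int = 400
    min_baseline_sjl: float = 0.5  # home-office eligibility, h
    delta_msf_sc_min: float = 11.0
    delta_sjl_min: float = -18.6
    delta_sd_week_min: float = 12.6
    paired_noise_sd_min: float = 10.0
    control_sleep_delta_min: float = -6.0


@dataclass
class CovariateModel:
    work_hours_mean: float = 41.0
    work_hours_male_shift: float = 3.0
    work_hours_sd: float = 7.0
    commute_shape: float = 2.0
    commute_mean: float = 3.5  # weekly hours
    stress_base: float = 2.8  # per-item 1-5 latent mean
    stress_work_coef: float = 0.012  # per weekly work hour
    stress_item_sd: float = 0.9
    disease_base_p: float = 0.02
    disease_age_p: float = 0.004  # per year above 18
    bmi_mean: float = 26.5
    bmi_age_coef: float = 0.05
    bmi_sd: float = 4.0
    height_mean: dict = field(default_factory=lambda: {"male": 1.78, "female": 1.65})
    height_sd: float = 0.07


@dataclass
class GeneratorConfig:
    """All planted effect sizes, distributions and noise scales."""

    demographics: DemographicsModel = field(default_factory=DemographicsModel)
    covariates: CovariateModel = field(default_factory=CovariateModel)
    chronotype: ChronotypeModel = field(default_factory=ChronotypeModel)
    sjl: SjlModel = field(default_factory=SjlModel)
    sleep: SleepModel = field(default_factory=SleepModel)
    sampling_time: SamplingTimeModel = field(default_factory=SamplingTimeModel)
    biomarkers: dict = field(default_factory=_default_biomarkers)
    labs: LabModel = field(default_factory=LabModel)
    followup: FollowupModel = field(default_factory=FollowupModel)
    aip_mode: str = "direct"  # 'direct' | 'derived'
    exact_times: bool = True  # emit exact decimal hours; False rounds to 1 min

    def __post_init__(self):
        if self.aip_mode not in ("direct", "derived"):
            raise ValueError(f"aip_mode must be 'direct' or 'derived', got {self.aip_mode!r}")
        if not 0 <= self.sjl.p_zero_worker <= 1 or not 0 <= self.sjl.p_zero_nonworker <= 1:
            raise ValueError("zero-SJL probabilities must lie in [0, 1]")
        if abs(sum(self.demographics.household_size_probs) - 1.0) > 1e-9:
            raise ValueError("household_size_probs must sum to 1")

    # -- persistence ------------------------------------------------------
    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "GeneratorConfig":
        raw = yaml.safe_load(text)
        kwargs = {}
        mapping = {
            "demographics": DemographicsModel,
            "covariates": CovariateModel,
            "chronotype": ChronotypeModel,
            "sjl": SjlModel,
            "sleep": SleepModel,
            "sampling_time": SamplingTimeModel,
            "labs": LabModel,
            "followup": FollowupModel,
        }
        for key, typ in mapping.items():
            if key in raw:
                sub = raw.pop(key)
                for k, v in list(sub.items()):
                    if isinstance(v, list):
                        sub[k] = tuple(v)
                kwargs[key] = typ(**sub)
        if "biomarkers" in raw:
            kwargs["biomarkers"] = {
                name: BiomarkerModel(**m) for name, m in raw.pop("biomarkers").items()
            }
        kwargs.update(raw)
        return cls(**kwargs)


@dataclass
class SyntheticCohort:
    """Generated tables plus the hidden truth used for recovery checks."""

    cohort: pd.DataFrame
    truth: pd.DataFrame
    lab_offsets: pd.DataFrame | None
    config: GeneratorConfig
    seed: int
    followup: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Stage 1: households, demographics, covariates


def generate_cohort(config: GeneratorConfig, seed: int) -> pd.DataFrame:
    """Households, members, demographics and lifestyle covariates."""
    d, cv = config.demographics, config.covariates
    rng = _rng(seed, _STAGE_COHORT)

    sizes = []
    total = 0
    while total < d.n_participants:
        s = int(rng.choice(np.arange(1, 7), p=d.household_size_probs))
        s = min(s, d.n_participants - total)
        sizes.append(s)
        total += s

    rows = []
    pid = 0
    for hh, size in enumerate(sizes):
        head_age = float(np.clip(rng.normal(d.head_age_mean, d.head_age_sd), d.age_min, d.age_max))
        head_sex = "female" if rng.random() < d.p_female else "male"
        for member in range(size):
            if member == 0:
                age, sex = head_age, head_sex
            elif member == 1:
                age = float(np.clip(head_age + rng.normal(0, 4), d.age_min, d.age_max))
                if rng.random() < 0.85:
                    sex = "male" if head_sex == "female" else "female"
                else:
                    sex = "female" if rng.random() < d.p_female else "male"
            else:
                age = float(np.clip(head_age - 27 + rng.normal(0, 5), d.age_min, d.age_max))
                sex = "female" if rng.random() < d.p_female else "male"
            rows.append({"participant_id": f"P{pid:06d}", "household_id": f"H{hh:05d}",
                         "age": age, "sex": sex})
            pid += 1
    df = pd.DataFrame(rows)
    n = len(df)
    age = df["age"].to_numpy()
    male = (df["sex"] == "male").to_numpy()

    from scipy.special import expit

    p_work = d.p_work_max * expit((d.retire_age - age) / d.retire_scale)
    employed = rng.random(n) < p_work
    work_hours = np.where(
        employed,
        np.clip(rng.normal(cv.work_hours_mean + cv.work_hours_male_shift * male,
                           cv.work_hours_sd), 10, 70),
        0.0,
    )
    commute = np.where(
        employed,
        rng.gamma(cv.commute_shape, cv.commute_mean / cv.commute_shape, n),
        0.0,
    )

    stress_latent = cv.stress_base + cv.stress_work_coef * work_hours
    items = {}
    for i in range(1, 6):
        vals = np.clip(np.round(rng.normal(stress_latent, cv.stress_item_sd)), 1, 5)
        items[f"stress_item_{i}"] = vals.astype(int)
    p_dis = np.clip(cv.disease_base_p + cv.disease_age_p * (age - 18.0), 0, 0.6)
    for i in range(1, 14):
        items[f"disease_item_{i}"] = (rng.random(n) < p_dis).astype(int)
    for k, v in items.items():
        df[k] = v
    df["time_stress"] = sum(items[f"stress_item_{i}"] for i in range(1, 6))
    df["diseases"] = sum(items[f"disease_item_{i}"] for i in range(1, 14))

    bmi = np.clip(rng.normal(cv.bmi_mean + cv.bmi_age_coef * (age - 50.0), cv.bmi_sd), 16, 45)
    height = np.where(
        male,
        rng.normal(cv.height_mean["male"], cv.height_sd, n),
        rng.normal(cv.height_mean["female"], cv.height_sd, n),
    )
    df["height_m"] = np.round(height, 3)
    df["weight_kg"] = np.round(bmi * height**2, 1)
    df["employed"] = employed
    df["work_hours"] = np.round(work_hours, 1)
    df["commute_hours"] = np.round(commute, 2)
    return df


# ---------------------------------------------------------------------------
# Stage 2: chronotype, social jetlag, raw MCTQ clock times


def _chronotype_trend(config: ChronotypeModel, sex, age):
    age = np.asarray(age, dtype=float)
    male_pred = np.polynomial.polynomial.polyval(age, np.asarray(config.male_coef))
    female_pred = np.polynomial.polynomial.polyval(age, np.asarray(config.female_coef))
    return np.where(np.asarray(sex, dtype=object) == "male", male_pred, female_pred)


def generate_mctq_raw(cohort: pd.DataFrame, config: GeneratorConfig, seed: int):
    """Planted circadian targets and the raw clock times that encode them.

    Returns ``(raw, truth)``. Clock times are constructed as
    ``onset = mid - SD/2``, ``end = mid + SD/2`` (mod 24) so that MCTQ
    scoring recovers the planted targets exactly (to 1e-9 h in exact mode).
    """
    ch, sj, sl = config.chronotype, config.sjl, config.sleep
    rng = _rng(seed, _STAGE_MCTQ)
    n = len(cohort)
    age = cohort["age"].to_numpy(float)
    sex = cohort["sex"].to_numpy(object)
    male = (sex == "male").astype(float)
    employed = cohort["employed"].to_numpy(bool)

    person_noise = rng.normal(0.0, ch.person_sd, n)
    trend = _chronotype_trend(ch, sex, age)
    msf_sc = trend + person_noise

    eta = (
        sj.intercept
        + sj.coef_chronotype * (msf_sc - 4.0)
        + sj.coef_age * (age - 50.0)
        + sj.coef_male * male
        + np.where(employed, sj.coef_work_hours * (cohort["work_hours"].to_numpy() - 40.0) / 10.0, 0.0)
        + np.where(employed, sj.coef_commute * cohort["commute_hours"].to_numpy() / 3.5, 0.0)
        + sj.coef_stress * (cohort["time_stress"].to_numpy() - 15.0) / 5.0
        + np.where(employed, 0.0, sj.nonworker_shift)
    )
    mu = np.exp(eta)
    sjl = rng.gamma(sj.gamma_shape, mu / sj.gamma_shape, n)
    p_zero = np.where(employed, sj.p_zero_worker, sj.p_zero_nonworker)
    sjl = np.where(rng.random(n) < p_zero, 0.0, sjl)

    sd_w = np.clip(rng.normal(sl.sd_w_mean, sl.sd_w_sd, n), 4.0, 11.0)
    oversleep = np.where(
        employed,
        rng.normal(sl.oversleep_base + sl.oversleep_per_sjl * sjl, sl.oversleep_sd),
        rng.normal(sl.nonworker_oversleep, sl.nonworker_oversleep_sd),
    )
    oversleep = np.maximum(oversleep, 0.0)
    sd_f = np.clip(sd_w + oversleep, 4.0, 13.0)

    workdays = np.where(
        employed,
        rng.choice([4, 5, 6], size=n, p=sl.workday_probs),
        0,
    ).astype(int)
    sd_week = (workdays * sd_w + (7 - workdays) * sd_f) / 7.0
    msf = np.where(sd_f > sd_w, msf_sc + (sd_f - sd_week) / 2.0, msf_sc)
    msw = msf - sjl  # workday mid-sleep earlier: social clock advances it

    alarm_free = rng.random(n) < sl.p_alarm_free

    bamid = 10.0 + 0.8 * (msf_sc - 4.0) + rng.normal(0, 1.2, n)
    alert_dur = np.clip(rng.normal(6.0, 1.0, n), 2.0, 12.0)

    def clock(mid, dur, half):
        t = (mid + half * dur / 2.0) % 24.0
        if not config.exact_times:
            t = np.round(t * 60.0) / 60.0 % 24.0
        return t

    raw = pd.DataFrame({
        "participant_id": cohort["participant_id"].to_numpy(),
        "sleep_onset_work": clock(msw, sd_w, -1),
        "sleep_end_work": clock(msw, sd_w, +1),
        "sleep_onset_free": clock(msf, sd_f, -1),
        "sleep_end_free": clock(msf, sd_f, +1),
        "alarm_free": alarm_free,
        "workdays_per_week": workdays,
        "alertness_start": clock(bamid, alert_dur, -1),
        "alertness_end": clock(bamid, alert_dur, +1),
        "age": age,
        "sex": sex,
    })

    anchor = 0.5 * (
        np.polynomial.polynomial.polyval(ANCHOR_AGE, np.asarray(ch.male_coef))
        + np.polynomial.polynomial.polyval(ANCHOR_AGE, np.asarray(ch.female_coef))
    )
    msf_sasc = person_noise + anchor
    mad = np.abs(msf_sasc - np.median(msf_sasc))

    truth = pd.DataFrame({
        "participant_id": cohort["participant_id"].to_numpy(),
        "true_MSF_sc": msf_sc,
        "true_SJL": sjl,
        "true_MSW": to_canonical_window(msw),
        "true_MSF": to_canonical_window(msf),
        "true_SD_w": sd_w,
        "true_SD_f": sd_f,
        "true_SD_week": sd_week,
        "true_MSF_sasc": msf_sasc,
        "true_MAD": mad,
        "true_Bamid": bamid,
    })
    return raw, truth


# ---------------------------------------------------------------------------
# Stage 3: biomarkers


def generate_biomarkers(cohort: pd.DataFrame, truth: pd.DataFrame,
                        config: GeneratorConfig, seed: int):
    """Lab-batched fasting biomarker panel with planted fixed effects.

    Returns ``(panel, lab_offsets)``. Household intercepts are shared
    within households per marker; each household's samples are processed by
    one of ``n_labs`` laboratories whose constant offsets are planted and
    recoverable by median-centering.
    """
    rng = _rng(seed, _STAGE_BIO)
    n = len(cohort)
    st = config.sampling_time
    ch = config.chronotype

    msf_sc = truth["true_MSF_sc"].to_numpy()
    sampling = st.mean + st.slope * (msf_sc - ch.reference) + rng.normal(0, st.noise_sd, n)

    predictors = {
        "SJL": truth["true_SJL"].to_numpy(),
        "MSF_sc_c": msf_sc - ch.reference,
        "MAD": truth["true_MAD"].to_numpy(),
        "sex_female": (cohort["sex"] == "female").to_numpy(float),
        "age_c": cohort["age"].to_numpy(float) - 50.0,
        "BMI_c": (cohort["weight_kg"] / cohort["height_m"] ** 2).to_numpy(float) - 26.5,
        "diseases": cohort["diseases"].to_numpy(float),
        "sampling_time_c": sampling - st.mean,
    }

    households = cohort["household_id"].to_numpy()
    hh_codes, hh_index = np.unique(households, return_inverse=True)
    lab_of_hh = rng.integers(0, config.labs.n_labs, len(hh_codes))
    lab_ids = np.array([f"L{k}" for k in lab_of_hh])[hh_index]

    panel = pd.DataFrame({
        "participant_id": cohort["participant_id"].to_numpy(),
        "lab_id": lab_ids,
        "sampling_time": sampling,
    })
    offset_rows = []
    markers = dict(config.biomarkers)
    for name, model in markers.items():
        if name == "AIP" and config.aip_mode == "derived":
            continue
        hh_eff = rng.normal(0, model.hh_sd, len(hh_codes))[hh_index]
        lab_sd = config.labs.offset_sd.get(name, 0.0)
        offsets = rng.normal(0, lab_sd, config.labs.n_labs)
        y = model.intercept + hh_eff + rng.normal(0, model.resid_sd, n)
        for pred, coef in model.effects.items():
            y = y + coef * predictors[pred]
        y = y + offsets[lab_of_hh][hh_index]
        if model.floor is not None:
            clipped = y < model.floor
            y = np.where(clipped, model.floor, y)
        panel[name] = y
        for k in range(config.labs.n_labs):
            offset_rows.append({"marker": name, "lab_id": f"L{k}", "offset": offsets[k]})
    if config.aip_mode == "derived":
        panel["AIP"] = np.log10(panel["TAG"] / panel["HDL"])
    lab_offsets = pd.DataFrame(offset_rows)
    return panel, lab_offsets


# ---------------------------------------------------------------------------
# Stage 4: paired follow-up wave


def generate_followup_wave(wave1: pd.DataFrame, config: GeneratorConfig, seed: int) -> pd.DataFrame:
    """Paired second-wave circadian variables with planted home-office shifts.

    ``wave1`` must carry participant_id, employed, commute_hours and the
    wave-1 circadian variables (MSF_sc, SJL, SD_week — scored or true).
    The home-office subgroup is drawn from commuting workers with baseline
    SJL >= ``min_baseline_sjl`` and receives the planted within-person
    shifts plus paired noise; the SJL shift is applied as a reflected
    subtraction (|SJL - D|) so the SJL >= 0 floor cannot distort the
    planted mean. Controls keep chronotype/SJL and lose a little sleep.
    """
    fu = config.followup
    rng = _rng(seed, _STAGE_FOLLOWUP)
    cols = {}
    for target, options in {
        "MSF_sc": ("MSF_sc", "true_MSF_sc"),
        "SJL": ("SJL", "true_SJL"),
        "SD_week": ("SD_week", "true_SD_week"),
    }.items():
        for c in options:
            if c in wave1.columns:
                cols[target] = c
                break
        else:
            raise KeyError(f"generate_followup_wave: no column for {target} in wave1")

    eligible = (
        wave1["employed"].astype(bool)
        & (wave1["commute_hours"] > 0)
        & (wave1[cols["SJL"]] >= fu.min_baseline_sjl)
    ).to_numpy()
    idx_eligible = np.flatnonzero(eligible)
    if fu.home_office_n > len(idx_eligible):
        raise ValueError(
            f"home_office_n={fu.home_office_n} exceeds {len(idx_eligible)} eligible workers"
        )
    home_idx = rng.choice(idx_eligible, size=fu.home_office_n, replace=False)
    home = np.zeros(len(wave1), dtype=bool)
    home[home_idx] = True
    workers = wave1["employed"].to_numpy(bool)

    noise_h = fu.paired_noise_sd_min / 60.0
    msf1 = wave1[cols["MSF_sc"]].to_numpy(float)
    sjl1 = wave1[cols["SJL"]].to_numpy(float)
    sdw1 = wave1[cols["SD_week"]].to_numpy(float)

    d_msf = np.where(home, fu.delta_msf_sc_min / 60.0, 0.0) + rng.normal(0, noise_h, len(wave1))
    shrink = np.where(home, -fu.delta_sjl_min / 60.0, 0.0) + rng.normal(0, noise_h, len(wave1))
    d_sleep = np.where(
        home, fu.delta_sd_week_min / 60.0, fu.control_sleep_delta_min / 60.0
    ) + rng.normal(0, noise_h, len(wave1))

    out = pd.DataFrame({
        "participant_id": wave1["participant_id"].to_numpy(),
        "home_office": home,
        "worker": workers,
        "MSF_sc_w1": msf1,
        "SJL_w1": sjl1,
        "SD_week_w1": sdw1,
        "MSF_sc_w2": msf1 + d_msf,
        "SJL_w2": np.abs(sjl1 - shrink),
        "SD_week_w2": sdw1 + d_sleep,
    })
    return out[workers].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Convenience: full dataset


def generate_dataset(config: GeneratorConfig | None = None, seed: int = 0,
                     followup: bool = False) -> SyntheticCohort:
    """Run all generator stages and merge into one cohort table."""
    config = GeneratorConfig() if config is None else config
    cohort = generate_cohort(config, seed)
    raw, truth = generate_mctq_raw(cohort, config, seed)
    panel, lab_offsets = generate_biomarkers(cohort, truth, config, seed)
    merged = cohort.merge(raw.drop(columns=["age", "sex"]), on="participant_id")
    merged = merged.merge(panel, on="participant_id")
    result = SyntheticCohort(
        cohort=merged, truth=truth, lab_offsets=lab_offsets, config=config, seed=seed
    )
    if followup:
        wave1 = merged[["participant_id", "employed", "commute_hours"]].merge(
            truth[["participant_id", "true_MSF_sc", "true_SJL", "true_SD_week"]],
            on="participant_id",
        )
        result.followup = generate_followup_wave(wave1, config, seed)
    return result
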