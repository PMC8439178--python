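"""Synthetic hospital-worker cohort generator.

Emulates the statistical structure the downstream analyses assume: a
baseline table of demographics and psychometric scores, weekly stress
surveys at irregular 5-10-day spacing with a subject random intercept and
AR(1) residual autocorrelation over the survey sequence, daily exposure
surveys, sparse nonuniform within-day SDNN recordings following a 24-h
cosinor whose amplitude and acrophase depend on baseline-trait tertials,
and a single-wave community case-count curve.

Baseline trait distributions default to the published cohort summary
(n=361; age 36.8 (10.1) y; BMI 25.7 (5.8); 69.3% female; PSS-4 5.3 (3.1);
CD-RISC-2 5.7 (1.4); optimism 19.1 (4.2); emotional support 6.8 (1.5);
QoL 7.8 (1.5)).  All randomness flows from one master seed through named
substreams, so each table can be regenerated independently and two runs
with the same configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .periods import assign_periods
from .stress import tertialize

__all__ = [
    "SimulationConfig",
    "ConfigError",
    "generate_cohort",
    "generate_weekly_surveys",
    "generate_daily_surveys",
    "generate_hrv_observations",
    "nyc_style_case_curve",
    "simulate_all",
    "write_tables",
]


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""

    def __init__(self, field_name, message):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


_ROLE_PROBS = {
    "resident": 0.08,
    "fellow": 0.03,
    "attending": 0.28,
    "nurse": 0.43,
    "staff_other": 0.18,
}

# chance that a responded day involves patient-area exposure, by role
_CLINICAL_DAY_PROB = {
    "resident": 0.65,
    "fellow": 0.60,
    "attending": 0.55,
    "nurse": 0.70,
    "staff_other": 0.0,
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Defaults reproduce the published study conditions where stated (cohort
    size, survey cadence, baseline score distributions) and field-realistic
    values elsewhere; see the methods note for the rationale of each free
    choice.
    """

    n_subjects: int = 361
    study_days: int = 60
    weekly_gap_range: tuple = (5, 10)
    daily_response_prob: float = 0.7
    hrv_obs_per_day_mean: float = 4.0
    cosinor_mesor: float = 40.0
    cosinor_amplitude_by_tertial: tuple = (12.0, 10.0, 6.0)
    cosinor_acrophase_by_tertial: tuple = (-2.0, -2.0, -2.6)
    subject_intercept_sd: float = 8.0
    hrv_noise_sd: float = 10.0
    hrv_group_trait: str = "emotional_support"
    stress_fixed_effects: dict = field(
        default_factory=lambda: {
            "intercept": 5.3,
            "mean_case_count": 0.8,
            "emotional_support": -0.6,
            "cd_risc2": -0.5,
            "qol": -0.5,
        }
    )
    stress_ar1_phi: float = 0.6
    stress_resid_sd: float = 2.0
    stress_subject_sd: float = 1.5
    case_curve_peak: float = 6000.0
    case_curve_peak_day: int = 20
    case_curve_width: float = 0.8
    start_date: dt.date = dt.date(2020, 4, 29)
    enrollment_stagger_days: int = 14
    pcr_positive_prob: float = 0.08
    antibody_positive_prob: float = 0.10
    clinical_day_prob_by_role: dict = field(
        default_factory=lambda: dict(_CLINICAL_DAY_PROB)
    )
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.n_subjects < 0:
            raise ConfigError("n_subjects", "must be nonnegative")
        if self.study_days < 1:
            raise ConfigError("study_days", "must be at least 1")
        lo, hi = self.weekly_gap_range
        if not (1 <= lo <= hi):
            raise ConfigError("weekly_gap_range", "must satisfy 1 <= lo <= hi")
        for name in ("daily_response_prob", "pcr_positive_prob",
                     "antibody_positive_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(name, "must be a probability in [0, 1]")
        for name in ("hrv_obs_per_day_mean", "subject_intercept_sd",
                     "hrv_noise_sd", "stress_resid_sd", "stress_subject_sd",
                     "case_curve_peak"):
            if getattr(self, name) < 0:
                raise ConfigError(name, "must be nonnegative")
        if not (0.0 <= self.stress_ar1_phi < 1.0):
            raise ConfigError("stress_ar1_phi", "must lie in [0, 1)")
        for name in ("cosinor_amplitude_by_tertial", "cosinor_acrophase_by_tertial"):
            if len(getattr(self, name)) != 3:
                raise ConfigError(name, "needs exactly 3 entries (low, medium, high)")
        if any(a < 0 for a in self.cosinor_amplitude_by_tertial):
            raise ConfigError("cosinor_amplitude_by_tertial", "must be nonnegative")
        for role, p in self.clinical_day_prob_by_role.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError("clinical_day_prob_by_role",
                                  f"probability for {role!r} not in [0, 1]")

    # -- (de)serialisation ------------------------------------------------

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(sorted(unknown)[0], "unknown configuration field")
        for tup in ("weekly_gap_range", "cosinor_amplitude_by_tertial",
                    "cosinor_acrophase_by_tertial"):
            if tup in d and d[tup] is not None:
                d[tup] = tuple(d[tup])
        if "start_date" in d and isinstance(d["start_date"], str):
            d["start_date"] = dt.date.fromisoformat(d["start_date"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["start_date"] = self.start_date.isoformat()
        for tup in ("weekly_gap_range", "cosinor_amplitude_by_tertial",
                    "cosinor_acrophase_by_tertial"):
            d[tup] = list(d[tup])
        return d


def _rng(config, stream):
    """Named substream of the master seed (deterministic, independent)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,))
    )


_STREAMS = {"cohort": 0, "weekly": 1, "daily": 2, "hrv": 3, "cases": 4}


def generate_cohort(config):
    """Baseline table: one row per participant with trait scores and role."""
    config.validate()
    rng = _rng(config, _STREAMS["cohort"])
    n = config.n_subjects
    if n == 0:
        return pd.DataFrame(
            columns=[
                "participant_id", "enrollment_date", "age", "gender", "bmi",
                "role", "pss4", "cd_risc2", "emotional_support", "qol",
                "optimism", "anxiety_depression", "covid_pcr_positive_date",
                "covid_antibody_positive_date",
            ]
        )
    pid = [f"P{i + 1:04d}" for i in range(n)]
    enroll_offset = rng.integers(0, config.enrollment_stagger_days + 1, size=n)
    enrollment = [config.start_date + dt.timedelta(days=int(o)) for o in enroll_offset]
    age = np.clip(rng.normal(36.8, 10.1, n), 22, 75).round(1)
    gender = np.where(rng.random(n) < 0.693, "female", "male")
    bmi = np.clip(rng.normal(25.7, 5.8, n), 16, 55).round(1)
    roles = rng.choice(list(_ROLE_PROBS), p=list(_ROLE_PROBS.values()), size=n)
    pss4 = np.clip(np.rint(rng.normal(5.3, 3.1, n)), 0, 16).astype(int)
    cd_risc2 = np.clip(np.rint(rng.normal(5.7, 1.4, n)), 0, 8).astype(int)
    emo = np.clip(np.rint(rng.normal(6.8, 1.5, n)), 2, 10).astype(int)
    qol = np.clip(np.rint(rng.normal(7.8, 1.5, n)), 2, 10).astype(int)
    optimism = np.clip(np.rint(rng.normal(19.1, 4.2, n)), 6, 30).astype(int)
    anxdep = rng.random(n) < 0.206

    pcr_pos = rng.random(n) < config.pcr_positive_prob
    pcr_day = rng.integers(7, max(8, config.study_days), size=n)
    pcr_date = [
        enrollment[i] + dt.timedelta(days=int(pcr_day[i])) if pcr_pos[i] else pd.NaT
        for i in range(n)
    ]
    ab_pos = rng.random(n) < config.antibody_positive_prob
    ab_day = rng.integers(7, max(8, config.study_days), size=n)
    ab_date = [
        enrollment[i] + dt.timedelta(days=int(ab_day[i])) if ab_pos[i] else pd.NaT
        for i in range(n)
    ]
    return pd.DataFrame(
        {
            "participant_id": pid,
            "enrollment_date": enrollment,
            "age": age,
            "gender": gender,
            "bmi": bmi,
            "role": roles,
            "pss4": pss4,
            "cd_risc2": cd_risc2,
            "emotional_support": emo,
            "qol": qol,
            "optimism": optimism,
            "anxiety_depression": anxdep,
            "covid_pcr_positive_date": pcr_date,
            "covid_antibody_positive_date": ab_date,
        }
    )


def _zscore(v):
    v = np.asarray(v, dtype=float)
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else v - v.mean()


def generate_weekly_surveys(cohort, config, case_series=None):
    """Weekly PSS-4/QoL table with AR(1) within-subject stress residuals.

    The linear predictor applies ``stress_fixed_effects`` to z-scored
    baseline traits (and to the z-scored mean case count over each survey's
    period window, and post-diagnosis flags, when those keys are present);
    a subject intercept and an AR(1) residual over the survey sequence are
    added, and the score is rounded and clamped to the legal 0-16 range.
    """
    if not len(cohort):
        raise ValueError("cohort must be nonempty")
    config.validate()
    rng = _rng(config, _STREAMS["weekly"])
    effects = dict(config.stress_fixed_effects)
    intercept = effects.pop("intercept", 0.0)

    needs_cases = "mean_case_count" in effects
    if needs_cases and case_series is None:
        case_series = nyc_style_case_curve(config)
    case_lookup = {}
    if needs_cases:
        cs = case_series.copy()
        cs["date"] = pd.to_datetime(cs["date"]).dt.date
        case_lookup = dict(zip(cs["date"], cs["cases"].astype(float)))

    lo, hi = config.weekly_gap_range
    baseline_z = {}
    for key in effects:
        if key in cohort.columns and key not in ("mean_case_count",):
            col = cohort[key]
            if col.dtype == bool or key == "anxiety_depression":
                baseline_z[key] = col.astype(float).to_numpy()
            else:
                baseline_z[key] = _zscore(col)
        elif key == "gender_male":
            baseline_z[key] = (cohort["gender"] == "male").astype(float).to_numpy()

    rows = []
    for i, rec in enumerate(cohort.itertuples(index=False)):
        enr = rec.enrollment_date
        dates = []
        day = int(rng.integers(lo, hi + 1))
        while day <= config.study_days:
            dates.append(enr + dt.timedelta(days=day))
            day += int(rng.integers(lo, hi + 1))
        if not dates:
            continue
        periods = assign_periods(dates, rec.participant_id, enrollment_date=enr)
        b_i = rng.normal(0.0, config.stress_subject_sd)
        phi = config.stress_ar1_phi
        e = rng.normal(0.0, config.stress_resid_sd)
        for k, per in enumerate(periods):
            if k > 0:
                e = phi * e + np.sqrt(1 - phi**2) * rng.normal(
                    0.0, config.stress_resid_sd
                )
            lp = intercept + b_i
            for key, beta in effects.items():
                if key in baseline_z:
                    lp += beta * baseline_z[key][i]
                elif key == "mean_case_count":
                    window = [
                        per.window_start + dt.timedelta(days=d)
                        for d in range(per.n_days)
                    ]
                    mcc = np.mean([case_lookup.get(d, 0.0) for d in window])
                    rows_mcc = mcc  # z-scored globally below
                    lp += 0.0  # placeholder; case term added after z-scoring
                elif key.startswith("post_pcr"):
                    d0 = rec.covid_pcr_positive_date
                    flag = False
                    if not pd.isna(d0):
                        delta = (per.survey_date - d0).days
                        if key == "post_pcr_2wk":
                            flag = 0 < delta <= 14
                        elif key == "post_pcr_4wk":
                            flag = 0 < delta <= 28
                        else:
                            flag = delta > 0
                    lp += beta * float(flag)
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "date": per.survey_date,
                    "_lp": lp,
                    "_e": e,
                    "_mcc": rows_mcc if needs_cases else np.nan,
                    "qol": int(np.clip(np.rint(rec.qol + rng.normal(0, 0.8)), 2, 10)),
                }
            )
    tab = pd.DataFrame(rows)
    if needs_cases and len(tab):
        tab["_lp"] = tab["_lp"] + effects["mean_case_count"] * _zscore(tab["_mcc"])
    pss = tab["_lp"] + tab["_e"]
    tab["pss4"] = np.clip(np.rint(pss), 0, 16).astype(int)
    return tab[["participant_id", "date", "pss4", "qol"]]


def generate_daily_surveys(cohort, config):
    """Daily exposure/symptom table; one row per responded subject-day."""
    config.validate()
    rng = _rng(config, _STREAMS["daily"])
    rows = []
    for rec in cohort.itertuples(index=False):
        p_clin = config.clinical_day_prob_by_role.get(rec.role, 0.0)
        for day in range(config.study_days):
            if rng.random() >= config.daily_response_prob:
                continue
            if rng.random() < p_clin:
                care = "covid_facing" if rng.random() < 0.5 else "noncovid_facing"
            else:
                care = rng.choice(
                    ["no_patient_care", "remote", "not_working"], p=[0.3, 0.3, 0.4]
                )
            severity = 0 if rng.random() < 0.85 else int(rng.integers(1, 11))
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "date": rec.enrollment_date + dt.timedelta(days=day),
                    "care_type": care,
                    "symptom_severity": severity,
                    "left_home": bool(rng.random() < 0.7),
                    "public_transport": bool(rng.random() < 0.3),
                    "quarantined": bool(rng.random() < 0.02),
                }
            )
    cols = ["participant_id", "date", "care_type", "symptom_severity",
            "left_home", "public_transport", "quarantined"]
    return pd.DataFrame(rows, columns=cols)


def generate_hrv_observations(cohort, config):
    """Sparse SDNN table following tertial-specific 24-h cosinor rhythms.

    For each subject-day, a Poisson number of uniformly timed recordings;
    SDNN = M + b_i + A_g cos(2*pi*t/24 + phi_g) + noise, floored at 0, with
    (A_g, phi_g) indexed by the subject's tertial of ``hrv_group_trait``.
    """
    if not len(cohort):
        return pd.DataFrame(columns=["participant_id", "timestamp", "sdnn_ms"])
    config.validate()
    rng = _rng(config, _STREAMS["hrv"])
    try:
        tert = tertialize(cohort[config.hrv_group_trait])
        g_idx = pd.Categorical(tert).codes  # 0 low, 1 medium, 2 high
    except ValueError:
        # degenerate cohorts (single subject / identical scores): use the
        # medium-tertial rhythm for everyone
        g_idx = np.ones(len(cohort), dtype=int)
    amps = np.asarray(config.cosinor_amplitude_by_tertial)
    phis = np.asarray(config.cosinor_acrophase_by_tertial)
    omega = 2 * np.pi / 24.0
    rows = []
    for i, rec in enumerate(cohort.itertuples(index=False)):
        b_i = rng.normal(0.0, config.subject_intercept_sd)
        A, phi = amps[g_idx[i]], phis[g_idx[i]]
        counts = rng.poisson(config.hrv_obs_per_day_mean, size=config.study_days)
        total = int(counts.sum())
        if total == 0:
            continue
        days = np.repeat(np.arange(config.study_days), counts)
        hours = rng.uniform(0.0, 24.0, size=total)
        sdnn = (
            config.cosinor_mesor
            + b_i
            + A * np.cos(omega * hours + phi)
            + rng.normal(0.0, config.hrv_noise_sd, size=total)
        )
        sdnn = np.maximum(sdnn, 0.0)
        base = dt.datetime.combine(rec.enrollment_date, dt.time())
        for d, h, v in zip(days, hours, sdnn):
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "timestamp": base + dt.timedelta(days=int(d), hours=float(h)),
                    "sdnn_ms": float(v),
                }
            )
    return pd.DataFrame(rows, columns=["participant_id", "timestamp", "sdnn_ms"])


def nyc_style_case_curve(config):
    """Single smooth log-normal-shaped daily case wave for the community.

    Covers one week before the study start through the last possible survey
    date; peaks at ``case_curve_peak`` on day ``case_curve_peak_day``
    (counted from the study start date).
    """
    config.validate()
    lead = 7
    n_days = lead + config.study_days + config.enrollment_stagger_days + 7
    offsets = np.arange(-lead, n_days - lead)
    u = offsets + lead + 1.0  # strictly positive day index
    u_star = config.case_curve_peak_day + lead + 1.0
    w = config.case_curve_width
    shape = np.exp(-np.log(u / u_star) ** 2 / (2 * w**2))
    cases = np.rint(config.case_curve_peak * shape).astype(int)
    dates = [config.start_date + dt.timedelta(days=int(o)) for o in offsets]
    return pd.DataFrame({"date": dates, "cases": cases})


def simulate_all(config):
    """Generate every table; returns a dict of DataFrames."""
    cohort = generate_cohort(config)
    cases = nyc_style_case_curve(config)
    if len(cohort):
        weekly = generate_weekly_surveys(cohort, config, case_series=cases)
        daily = generate_daily_surveys(cohort, config)
        hrv = generate_hrv_observations(cohort, config)
    else:
        weekly = pd.DataFrame(columns=["participant_id", "date", "pss4", "qol"])
        daily = generate_daily_surveys(cohort, config)
        hrv = generate_hrv_observations(cohort, config)
    return {
        "baseline": cohort,
        "weekly": weekly,
        "daily": daily,
        "hrv": hrv,
        "cases": cases,
    }


def write_tables(tables, out_dir):
    """Write the generated tables as CSV with ISO-8601 dates/timestamps."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = str(path)
    return paths
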