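"""Synthetic registry generator with known ground truth.

Emulates the statistical structure of a national laboratory/administrative
registry: persons with covariates drawn from configurable marginals, linear
true-eGFR trajectories from a progressor/non-progressor mixture, an irregular
gamma-renewal visit process, multiplicative lognormal measurement noise,
transient AKI excursions, and competing death / hospitalization / emigration
processes. Every stream hangs off one global seed through
``numpy.random.SeedSequence`` spawning, so toggling one component never
perturbs the others.

Times are integer-valued days since the simulation epoch (day 0); the
enrollment window and administrative end are expressed on the same axis.
Default marginals are registry-like (55% female, 18% diabetes, 62%
hypertension, 21% CVD, 67% missing uACR, median age ~75) and all overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Tuple

import numpy as np
import pandas as pd

from ckdflow.egfr import EQUATION_CONSTANTS, UMOL_PER_MGDL
from ckdflow.errors import ConfigError

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_cohort",
    "invert_ckdepi_2009",
    "true_cif",
    "simulate_two_cause",
]

DAYS_PER_YEAR = 365.25


@dataclass
class SimConfig:
    """All knobs of the generator; defaults give a registry-like cohort."""

    n_persons: int = 1000
    seed: int = 0

    # timeline (days since epoch); default: 3y lookback, 2y window, ~3y follow-up
    enrollment_start: float = 1096.0
    enrollment_end: float = 1826.0
    admin_end: float = 3290.0

    # covariate marginals
    female_fraction: float = 0.55
    age_mean: float = 75.0
    age_sd: float = 9.0
    age_min: float = 20.0
    age_max: float = 99.0
    diabetes_prev: float = 0.18
    hypertension_prev: float = 0.62
    cvd_prev: float = 0.21
    uacr_missing_fraction: float = 0.67
    # stage probabilities among observed uACR (renormalized internally)
    uacr_stage_probs: Tuple[float, float, float] = (0.667, 0.25, 0.083)

    # trajectory model
    baseline_egfr_mean: float = 72.0
    baseline_egfr_sd: float = 9.0
    egfr_floor: float = 5.0
    progressor_intercept: float = -2.8
    coef_male: float = 0.35
    coef_a2: float = 0.8
    coef_a3: float = 1.6
    coef_missing_uacr: float = 0.0
    coef_diabetes: float = 0.5
    coef_htn_cvd: float = 0.4
    slope_nonprogressor_mean: float = -1.0
    slope_nonprogressor_sd: float = 1.0
    slope_progressor_mean: float = -8.0
    slope_progressor_sd: float = 3.0

    # observation process
    visit_gap_mean_days: float = 120.0
    visit_gap_shape: float = 1.5
    comorbid_visit_rate_factor: float = 1.4  # visit rate multiplier for dm/htn
    noise_cv: float = 0.06
    inpatient_fraction: float = 0.0

    # AKI injection
    aki_rate_per_year: float = 0.0
    aki_multiplier_range: Tuple[float, float] = (1.5, 3.0)
    aki_duration_range_days: Tuple[float, float] = (3.0, 14.0)

    # competing processes (rates per person-year unless noted)
    death_model: str = "gompertz"  # or "exponential"
    death_rate: float = 0.06  # exponential model only
    gompertz_b: float = 7.6e-5  # baseline hazard at age 0 (per year)
    gompertz_theta: float = 0.09  # log-hazard slope per year of age
    hospitalization_rate: float = 0.25
    emigration_rate: float = 0.005
    krt_rate: float = 0.0

    def validate(self) -> None:
        probs = [
            self.female_fraction,
            self.diabetes_prev,
            self.hypertension_prev,
            self.cvd_prev,
            self.uacr_missing_fraction,
            self.inpatient_fraction,
            *self.uacr_stage_probs,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigError("probabilities must lie in [0, 1]")
        if self.n_persons < 1:
            raise ConfigError("n_persons must be >= 1")
        for name in ("age_sd", "baseline_egfr_sd", "slope_nonprogressor_sd", "slope_progressor_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.baseline_egfr_mean <= self.egfr_floor:
            raise ConfigError("baseline eGFR mean lies at/below the trajectory floor")
        if not (self.enrollment_start <= self.enrollment_end <= self.admin_end):
            raise ConfigError("require enrollment_start <= enrollment_end <= admin_end")
        if self.noise_cv < 0 or self.aki_rate_per_year < 0:
            raise ConfigError("noise_cv and aki_rate_per_year must be >= 0")
        if self.death_model not in ("gompertz", "exponential"):
            raise ConfigError("death_model must be 'gompertz' or 'exponential'")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Latent state emitted alongside the observable tables."""

    persons: pd.DataFrame  # baseline_egfr, true_slope, progressor, latent times
    aki_intervals: pd.DataFrame  # person_id, start, end, multiplier


def invert_ckdepi_2009(target_egfr: float, age: float, sex: str) -> float:
    """Creatinine (µmol/L) whose 2009 CKD-EPI eGFR equals ``target_egfr``.

    Closed-form piecewise inverse across the kappa breakpoint; vectorized
    over arrays.
    """
    c = EQUATION_CONSTANTS["2009"]
    egfr = np.asarray(target_egfr, dtype=float)
    if np.any(egfr <= 0):
        raise ConfigError("target eGFR must be positive")
    female = np.asarray(sex) == "female"
    kappa = np.where(female, c["kappa"]["female"], c["kappa"]["male"])
    alpha = np.where(female, c["alpha"]["female"], c["alpha"]["male"])
    base = egfr / (
        c["scale"] * c["age_base"] ** np.asarray(age, dtype=float)
        * np.where(female, c["female_factor"], 1.0)
    )
    # base >= 1 -> Scr <= kappa branch (exponent alpha); else the beta branch
    ratio = np.where(base >= 1.0, base ** (1.0 / alpha), base ** (1.0 / c["beta"]))
    scr = kappa * ratio * UMOL_PER_MGDL
    if scr.ndim == 0:
        return float(scr)
    return scr


def true_cif(config: SimConfig, cause: str, horizon_days: float) -> float:
    """Closed-form cumulative incidence for the constant-hazard causes.

    Only defined when death is exponential; causes are ``"death"`` and
    ``"hospitalization"`` with rates per person-year.
    """
    if config.death_model != "exponential":
        raise ConfigError("true_cif requires death_model='exponential' (constant hazards)")
    lams = {"death": config.death_rate, "hospitalization": config.hospitalization_rate}
    if cause not in lams:
        raise ConfigError(f"unknown cause {cause!r}")
    total = sum(lams.values())
    t_years = horizon_days / DAYS_PER_YEAR
    if total == 0:
        return 0.0
    return lams[cause] / total * (1.0 - np.exp(-total * t_years))


def simulate_two_cause(
    n: int,
    lambda1: float,
    lambda2: float,
    admin_years: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Constant-hazard two-cause data (times in years, codes 0/1/2).

    Latent exponential times per cause; the earlier one wins, administrative
    censoring at ``admin_years``. Used as the estimator's parameter-recovery
    benchmark against the closed form in :func:`true_cif`.
    """
    t1 = rng.exponential(1.0 / lambda1, size=n) if lambda1 > 0 else np.full(n, np.inf)
    t2 = rng.exponential(1.0 / lambda2, size=n) if lambda2 > 0 else np.full(n, np.inf)
    t = np.minimum(np.minimum(t1, t2), admin_years)
    codes = np.where(t >= admin_years, 0, np.where(t1 < t2, 1, 2))
    return t, codes


def _draw_gompertz_death_age(age_now: np.ndarray, b: float, theta: float, rng) -> np.ndarray:
    """Age at death given survival to ``age_now``, hazard b*exp(theta*age)."""
    u = rng.uniform(size=age_now.shape)
    # H(a) - H(a0) = (b/theta)(e^{theta a} - e^{theta a0}) = -log u
    return np.log(np.exp(theta * age_now) - theta * np.log(u) / b) / theta


def simulate_cohort(config: SimConfig) -> Tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (persons, measurements, ground_truth) for one seed.

    ``persons`` columns: person_id, sex, birth_time, diabetes, hypertension,
    cvd, uacr_mg_g, death_time, emigration_time, krt_time,
    first_admission_time. ``measurements`` columns: person_id, time,
    creatinine_umol_l, setting. Deterministic given the config (byte-identical
    reruns for a fixed seed).
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(6)
    rng_cov = np.random.default_rng(streams[0])
    rng_visits = np.random.default_rng(streams[1])
    rng_noise = np.random.default_rng(streams[2])
    rng_aki = np.random.default_rng(streams[3])
    rng_events = np.random.default_rng(streams[4])

    n = config.n_persons
    person_id = np.arange(1, n + 1)
    female = rng_cov.uniform(size=n) < config.female_fraction
    sex = np.where(female, "female", "male")
    age0 = np.clip(
        rng_cov.normal(config.age_mean, config.age_sd, size=n), config.age_min, config.age_max
    )
    birth_time = np.round(-age0 * DAYS_PER_YEAR)
    age0 = -birth_time / DAYS_PER_YEAR  # keep latent age consistent with the emitted table
    diabetes = rng_cov.uniform(size=n) < config.diabetes_prev
    hypertension = rng_cov.uniform(size=n) < config.hypertension_prev
    cvd = rng_cov.uniform(size=n) < config.cvd_prev

    uacr_missing = rng_cov.uniform(size=n) < config.uacr_missing_fraction
    stage_probs = np.asarray(config.uacr_stage_probs, dtype=float)
    stage_probs = stage_probs / stage_probs.sum()
    stage_idx = rng_cov.choice(3, size=n, p=stage_probs)  # 0=A1, 1=A2, 2=A3
    uacr = np.empty(n)
    uacr[stage_idx == 0] = rng_cov.uniform(2.0, 29.9, size=int((stage_idx == 0).sum()))
    uacr[stage_idx == 1] = rng_cov.uniform(30.0, 300.0, size=int((stage_idx == 1).sum()))
    uacr[stage_idx == 2] = rng_cov.uniform(300.5, 1500.0, size=int((stage_idx == 2).sum()))
    uacr_out = np.where(uacr_missing, np.nan, uacr)

    logit = (
        config.progressor_intercept
        + config.coef_male * (~female)
        + np.where(uacr_missing, config.coef_missing_uacr,
                   np.choose(stage_idx, [0.0, config.coef_a2, config.coef_a3]))
        + config.coef_diabetes * diabetes
        + config.coef_htn_cvd * (hypertension | cvd)
    )
    p_prog = 1.0 / (1.0 + np.exp(-logit))
    progressor = rng_cov.uniform(size=n) < p_prog
    slope = np.where(
        progressor,
        rng_cov.normal(config.slope_progressor_mean, config.slope_progressor_sd, size=n),
        rng_cov.normal(config.slope_nonprogressor_mean, config.slope_nonprogressor_sd, size=n),
    )
    baseline = rng_cov.normal(config.baseline_egfr_mean, config.baseline_egfr_sd, size=n)
    baseline = np.maximum(baseline, config.egfr_floor + 1.0)

    # latent competing event times (days since epoch)
    if config.death_model == "gompertz":
        death_age = _draw_gompertz_death_age(age0, config.gompertz_b, config.gompertz_theta, rng_events)
        death_time = (death_age - age0) * DAYS_PER_YEAR
    else:
        death_time = (
            rng_events.exponential(1.0 / config.death_rate, size=n) * DAYS_PER_YEAR
            if config.death_rate > 0
            else np.full(n, np.inf)
        )

    def _exp_times(rate):
        if rate <= 0:
            return np.full(n, np.inf)
        return rng_events.exponential(1.0 / rate, size=n) * DAYS_PER_YEAR

    hosp_time = _exp_times(config.hospitalization_rate)
    emig_time = _exp_times(config.emigration_rate)
    krt_time = _exp_times(config.krt_rate)

    obs_end = np.minimum(np.minimum(death_time, emig_time), config.admin_end)

    sigma = np.sqrt(np.log1p(config.noise_cv**2)) if config.noise_cv > 0 else 0.0
    lo_m, hi_m = config.aki_multiplier_range
    lo_d, hi_d = config.aki_duration_range_days

    kappa_f, kappa_m = 0.7, 0.9
    c2009 = EQUATION_CONSTANTS["2009"]

    meas_pid, meas_time, meas_creat = [], [], []
    aki_rows = []
    gap_shape = config.visit_gap_shape
    for i in range(n):
        end_i = obs_end[i]
        if end_i <= 0:
            continue
        gap_mean = config.visit_gap_mean_days
        if diabetes[i] or hypertension[i]:
            gap_mean /= config.comorbid_visit_rate_factor
        n_max = int(end_i / gap_mean * 1.8) + 12
        gaps = rng_visits.gamma(gap_shape, gap_mean / gap_shape, size=n_max)
        first = rng_visits.uniform(0.0, gap_mean)
        visits = first + np.concatenate(([0.0], np.cumsum(gaps)))
        visits = visits[visits <= end_i]
        if visits.size == 0:
            continue
        visits = np.unique(np.round(visits))

        # AKI excursions over the observation span
        aki_mult = np.ones(visits.size)
        if config.aki_rate_per_year > 0:
            n_epi = rng_aki.poisson(config.aki_rate_per_year * end_i / DAYS_PER_YEAR)
            for _ in range(n_epi):
                start = rng_aki.uniform(0.0, end_i)
                dur = rng_aki.uniform(lo_d, hi_d)
                mult = rng_aki.uniform(lo_m, hi_m)
                inside = (visits >= start) & (visits <= start + dur)
                aki_mult[inside] = np.maximum(aki_mult[inside], mult)
                aki_rows.append((person_id[i], start, start + dur, mult))

        true_egfr = np.maximum(baseline[i] + slope[i] * visits / DAYS_PER_YEAR, config.egfr_floor)
        age_at = age0[i] + visits / DAYS_PER_YEAR
        kappa = kappa_f if female[i] else kappa_m
        alpha = c2009["alpha"]["female" if female[i] else "male"]
        sexfac = c2009["female_factor"] if female[i] else 1.0
        base = true_egfr / (c2009["scale"] * c2009["age_base"] ** age_at * sexfac)
        ratio = np.where(base >= 1.0, base ** (1.0 / alpha), base ** (1.0 / c2009["beta"]))
        creat = kappa * ratio * UMOL_PER_MGDL

        if sigma > 0:
            creat = creat * rng_noise.lognormal(-sigma**2 / 2.0, sigma, size=creat.size)
        creat = creat * aki_mult

        meas_pid.append(np.full(visits.size, person_id[i]))
        meas_time.append(visits)
        meas_creat.append(creat)

    if meas_pid:
        measurements = pd.DataFrame(
            {
                "person_id": np.concatenate(meas_pid),
                "time": np.concatenate(meas_time),
                "creatinine_umol_l": np.concatenate(meas_creat),
            }
        )
    else:
        measurements = pd.DataFrame(columns=["person_id", "time", "creatinine_umol_l"])
    if config.inpatient_fraction > 0:
        inpat = rng_noise.uniform(size=len(measurements)) < config.inpatient_fraction
        measurements["setting"] = np.where(inpat, "inpatient", "outpatient")
    else:
        measurements["setting"] = "outpatient"

    def _finite_or_nan(x):
        return np.where(np.isfinite(x), np.round(x, 1), np.nan)

    persons = pd.DataFrame(
        {
            "person_id": person_id,
            "sex": sex,
            "birth_time": birth_time,
            "diabetes": diabetes.astype(int),
            "hypertension": hypertension.astype(int),
            "cvd": cvd.astype(int),
            "uacr_mg_g": np.round(uacr_out, 1),
            "death_time": _finite_or_nan(death_time),
            "emigration_time": _finite_or_nan(emig_time),
            "krt_time": _finite_or_nan(krt_time),
            "first_admission_time": _finite_or_nan(hosp_time),
        }
    )
    truth_persons = pd.DataFrame(
        {
            "person_id": person_id,
            "baseline_egfr": baseline,
            "true_slope": slope,
            "progressor": progressor.astype(int),
            "p_progressor": p_prog,
            "death_time": death_time,
            "hospitalization_time": hosp_time,
            "emigration_time": emig_time,
            "obs_end": obs_end,
        }
    )
    aki_intervals = pd.DataFrame(
        aki_rows, columns=["person_id", "start", "end", "multiplier"]
    )
    return persons, measurements, GroundTruth(truth_persons, aki_intervals)
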