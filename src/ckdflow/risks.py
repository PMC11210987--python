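"""Competing-risk estimation: Aalen–Johansen cumulative incidence.

Implements the Aalen–Johansen estimator for cause-specific cumulative
incidence with right censoring, the Aalen-type counting-process variance,
and pointwise confidence intervals on the log(-log) scale so bounds stay in
[0, 1]. Also provides stratified estimation, the risk-marker heat-map table
(sex x albuminuria x diabetes x hypertension/CVD at 1- and 3-year horizons)
and a Table-1-style cohort summary.

Input convention: one row per subject with a follow-up ``time`` (days since
index) and a ``code``: 0 censored, 1 event of interest, 2 competing death.
At tied times events precede censorings; different causes tied at one time
share the hazard denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from ckdflow.egfr import albuminuria_stage
from ckdflow.errors import InvalidInputError

__all__ = [
    "RiskCurve",
    "RiskAt",
    "aalen_johansen",
    "risk_at",
    "stratified_risks",
    "heatmap_table",
    "cohort_summary",
    "AGE_GROUP_EDGES",
    "age_group",
]

#: age strata as reported in the cohort description
AGE_GROUP_EDGES = (50, 60, 70, 80, 90)


@dataclass
class RiskCurve:
    """Cause-specific cumulative incidence evaluated at the event times.

    ``times`` are the distinct uncensored event times (any cause); ``cif``,
    ``se`` and the CI bounds are right-continuous step values at those times.
    """

    cause: int
    times: np.ndarray
    cif: np.ndarray
    se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    survival: np.ndarray
    n_subjects: int
    max_follow_up: float
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "cif": self.cif,
                "se": self.se,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "survival": self.survival,
            }
        )


class RiskAt(NamedTuple):
    risk: float
    ci_lower: float
    ci_upper: float
    truncated: bool


def _validate(times, codes):
    t = np.asarray(times, dtype=float)
    c = np.asarray(codes)
    if t.shape != c.shape:
        raise InvalidInputError("times and codes must have equal length")
    if t.size == 0:
        raise InvalidInputError("no subjects supplied")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise InvalidInputError("follow-up times must be finite and >= 0")
    if not np.all(np.isin(c, (0, 1, 2))):
        raise InvalidInputError("codes must be 0 (censored), 1 (event) or 2 (death)")
    return t, c.astype(int)


def aalen_johansen(
    times: Sequence[float],
    codes: Sequence[int],
    causes: Iterable[int] = (1, 2),
    alpha: float = 0.05,
) -> Dict[int, RiskCurve]:
    """Aalen–Johansen cumulative incidence per cause, with CIs.

    Returns a dict mapping each cause in ``causes`` to its
    :class:`RiskCurve`. With no competing events the cause-1 curve equals the
    complement of the Kaplan–Meier survivor function.
    """
    t, c = _validate(times, codes)
    n = t.size
    order = np.argsort(t, kind="stable")
    t, c = t[order], c[order]

    event_times = np.unique(t[c > 0])
    m = event_times.size
    # risk set: events precede censorings at tied times, so everyone with
    # follow-up >= s is at risk at s
    n_at_risk = n - np.searchsorted(t, event_times, side="left")

    d_total = np.zeros(m)
    d_cause: Dict[int, np.ndarray] = {}
    for k in (1, 2):
        tk = t[c == k]
        left = np.searchsorted(tk, event_times, side="left")
        right = np.searchsorted(tk, event_times, side="right")
        d_cause[k] = (right - left).astype(float)
        d_total += d_cause[k]

    hazard = d_total / n_at_risk
    survival = np.cumprod(1.0 - hazard)
    s_minus = np.concatenate(([1.0], survival[:-1]))

    z = norm.ppf(1.0 - alpha / 2.0)
    curves: Dict[int, RiskCurve] = {}
    for k in causes:
        dk = d_cause.get(k, np.zeros(m))
        increments = s_minus * dk / n_at_risk
        cif = np.cumsum(increments)

        # Aalen-type variance, expanded to cumulative sums:
        # var(F(t)) = sum_{s<=t} (F(t)-F(s))^2 a(s)
        #           + sum_{s<=t} S(s-)^2 (n-dk)/n * dk/n^2
        #           - 2 sum_{s<=t} (F(t)-F(s)) S(s-) dk/n^2
        # with a(s) = d(s) / (n(s) (n(s)-d(s))).
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(n_at_risk > d_total, d_total / (n_at_risk * (n_at_risk - d_total)), 0.0)
        b = s_minus * dk / n_at_risk**2
        cum_a = np.cumsum(a)
        cum_aF = np.cumsum(a * cif)
        cum_aF2 = np.cumsum(a * cif**2)
        cum_b = np.cumsum(b)
        cum_bF = np.cumsum(b * cif)
        cum_c = np.cumsum(s_minus**2 * (n_at_risk - dk) / n_at_risk * dk / n_at_risk**2)
        var = (
            cif**2 * cum_a - 2 * cif * cum_aF + cum_aF2
            + cum_c
            - 2 * (cif * cum_b - cum_bF)
        )
        se = np.sqrt(np.maximum(var, 0.0))

        lo = np.zeros(m)
        hi = np.zeros(m)
        interior = (cif > 0) & (cif < 1) & (se > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            theta_se = np.where(interior, se / np.abs(cif * np.log(cif)), 0.0)
        expo = np.clip(z * theta_se[interior], None, 50.0)  # cif**e^50 underflows to 0 anyway
        lo[interior] = cif[interior] ** np.exp(expo)
        hi[interior] = cif[interior] ** np.exp(-expo)
        degenerate = ~interior
        lo[degenerate] = cif[degenerate]
        hi[degenerate] = cif[degenerate]

        curves[k] = RiskCurve(
            cause=int(k),
            times=event_times.copy(),
            cif=cif,
            se=se,
            ci_lower=lo,
            ci_upper=hi,
            survival=survival.copy(),
            n_subjects=n,
            max_follow_up=float(t.max()),
            alpha=alpha,
        )
    return curves


def risk_at(curve: RiskCurve, horizon: float) -> RiskAt:
    """Right-continuous step evaluation of a risk curve at ``horizon`` days.

    Before the first event the risk is 0. Beyond the last follow-up time the
    last value is returned with ``truncated=True``.
    """
    if horizon < 0:
        raise InvalidInputError("horizon must be >= 0")
    truncated = horizon > curve.max_follow_up
    idx = np.searchsorted(curve.times, horizon, side="right") - 1
    if idx < 0:
        return RiskAt(0.0, 0.0, 0.0, truncated)
    return RiskAt(
        float(curve.cif[idx]),
        float(curve.ci_lower[idx]),
        float(curve.ci_upper[idx]),
        truncated,
    )


def stratified_risks(
    outcome_table: pd.DataFrame,
    strata: pd.Series,
    cause: int = 1,
    alpha: float = 0.05,
) -> Dict[object, RiskCurve]:
    """Aalen–Johansen per stratum.

    ``outcome_table`` needs columns ``person_id``, ``time``, ``code``;
    ``strata`` maps person_id to a stratum label. Empty strata (or strata
    with no subjects after the join) are omitted.
    """
    labels = outcome_table["person_id"].map(strata)
    out: Dict[object, RiskCurve] = {}
    for label, group in outcome_table.groupby(labels, observed=True, dropna=True):
        if len(group) == 0:
            continue
        out[label] = aalen_johansen(group["time"], group["code"], causes=(cause,), alpha=alpha)[cause]
    return out


def age_group(age_years: float) -> str:
    """Map an age to the reporting strata 18-49, 50-59, ..., 90+."""
    if age_years < AGE_GROUP_EDGES[0]:
        return "18-49"
    for lo, hi in zip(AGE_GROUP_EDGES[:-1], AGE_GROUP_EDGES[1:]):
        if age_years < hi:
            return f"{lo}-{hi - 1}"
    return "90+"


def _covariate_frame(persons: pd.DataFrame) -> pd.DataFrame:
    cov = persons.set_index("person_id")
    alb = cov["uacr_mg_g"].map(lambda v: albuminuria_stage(None if pd.isna(v) else v))
    return pd.DataFrame(
        {
            "sex": cov["sex"],
            "albuminuria": alb,
            "diabetes": cov["diabetes"].astype(bool),
            "htn_or_cvd": cov["hypertension"].astype(bool) | cov["cvd"].astype(bool),
        }
    )


def heatmap_table(
    outcome_table: pd.DataFrame,
    persons: pd.DataFrame,
    horizons: Sequence[float] = (365.0, 1095.0),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Risk-marker heat-map cells for the (confirmed) rapid-progression outcome.

    One row per sex x albuminuria x diabetes x hypertension/CVD combination
    and horizon. Persons with missing albuminuria form their own displayed
    stratum rather than being dropped. Empty cells are kept with
    ``empty=True`` and NaN risks.
    """
    cov = _covariate_frame(persons)
    merged = outcome_table.merge(cov, left_on="person_id", right_index=True, how="left")
    rows = []
    for sex in ("female", "male"):
        for alb in ("A1", "A2", "A3", "missing"):
            for dm in (False, True):
                for hc in (False, True):
                    cell = merged[
                        (merged["sex"] == sex)
                        & (merged["albuminuria"] == alb)
                        & (merged["diabetes"] == dm)
                        & (merged["htn_or_cvd"] == hc)
                    ]
                    for horizon in horizons:
                        row = {
                            "sex": sex,
                            "albuminuria": alb,
                            "diabetes": dm,
                            "htn_or_cvd": hc,
                            "horizon_days": horizon,
                            "n": len(cell),
                            "empty": len(cell) == 0,
                            "risk": np.nan,
                            "ci_lower": np.nan,
                            "ci_upper": np.nan,
                        }
                        if len(cell) > 0:
                            curve = aalen_johansen(cell["time"], cell["code"], causes=(1,), alpha=alpha)[1]
                            est = risk_at(curve, horizon)
                            row.update(risk=est.risk, ci_lower=est.ci_lower, ci_upper=est.ci_upper)
                        rows.append(row)
    return pd.DataFrame(rows)


def _quantiles(values: pd.Series):
    v = values.dropna().to_numpy(dtype=float)
    if v.size == 0:
        return (np.nan, np.nan, np.nan)
    return tuple(np.quantile(v, [0.5, 0.25, 0.75]))


def cohort_summary(persons: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Tidy Table-1-style description of the incident cohort.

    Returns rows (variable, level, n, percent, median, q1, q3); percentages
    are over non-missing denominators of each categorical variable.
    """
    df = cohort.merge(persons, on="person_id", how="left", suffixes=("", "_p"))
    cov = _covariate_frame(persons).loc[df["person_id"]].reset_index()
    rows = []

    def add_categorical(variable, series):
        counts = series.value_counts(dropna=False)
        denom = int(counts.sum())
        for level, n in counts.items():
            rows.append(
                {
                    "variable": variable,
                    "level": str(level),
                    "n": int(n),
                    "percent": 100.0 * n / denom if denom else np.nan,
                    "median": np.nan,
                    "q1": np.nan,
                    "q3": np.nan,
                }
            )

    def add_numeric(variable, series):
        med, q1, q3 = _quantiles(series)
        rows.append(
            {
                "variable": variable,
                "level": "",
                "n": int(series.notna().sum()),
                "percent": np.nan,
                "median": med,
                "q1": q1,
                "q3": q3,
            }
        )

    add_categorical("sex", df["sex"])
    if "age_at_index" in df.columns:
        add_numeric("age_years", df["age_at_index"])
        add_categorical("age_group", df["age_at_index"].map(age_group))
    add_categorical("substage", df["substage"])
    for flag in ("diabetes", "hypertension", "cvd"):
        add_categorical(flag, df[flag].astype(bool))
    add_categorical("albuminuria", cov["albuminuria"])
    add_numeric("inclusion_egfr", df["inclusion_egfr"])
    if "uacr_mg_g" in df.columns:
        add_numeric("uacr_mg_g", df["uacr_mg_g"])
    if "egfr_tests_prior_year" in df.columns:
        add_numeric("egfr_tests_prior_year", df["egfr_tests_prior_year"])
    return pd.DataFrame(rows)
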