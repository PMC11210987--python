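"""Incident CKD stage G3 case finding and progression outcome detection.

All functions here operate on one person's AKI-filtered, time-sorted eGFR
series given as parallel arrays of times (days since a fixed epoch) and eGFR
values. Calendar arithmetic never enters; "within a year" means within
365 days and slopes are per 365.25 days.

Outcome codes follow the competing-risk convention used by the estimator:
0 = censored, 1 = event of interest, 2 = death before the event.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ckdflow.egfr import gfr_stage_rank
from ckdflow.errors import ContractViolationError, InvalidInputError

__all__ = [
    "IncidentCkdRecord",
    "SlopeFit",
    "OutcomeRecord",
    "find_incident_ckd_g3",
    "classify_substage",
    "fit_egfr_slope",
    "detect_rapid_progression",
    "detect_category_drop",
    "detect_kidney_failure",
    "resolve_outcome",
    "OUTCOMES",
    "G3_LOWER",
    "G3_UPPER",
    "PAIR_GAP_DAYS",
]

DAYS_PER_YEAR = 365.25
G3_LOWER = 30.0
G3_UPPER = 60.0
G3B_UPPER = 45.0
PAIR_GAP_DAYS = 90.0
KIDNEY_FAILURE_EGFR = 15.0

RAPID_DROP = 5.0
RAPID_SLOPE = -5.0
RAPID_MIN_POINTS = 3
RAPID_SPAN_DAYS = 90.0
RAPID_WINDOW_DAYS = 365.0
CONFIRM_MIN_DAYS = 30.0
CONFIRM_MAX_DAYS = 180.0

CATEGORY_DROP_FRACTION = 0.75

OUTCOMES = ("rapid", "potential_rapid", "category_drop", "kidney_failure", "hospitalization")


@dataclass(frozen=True)
class IncidentCkdRecord:
    person_id: object
    index_time: float
    inclusion_egfr: float
    substage: str  # "G3a" or "G3b"

    def __post_init__(self):
        if not (G3_LOWER <= self.inclusion_egfr < G3_UPPER):
            raise ContractViolationError("inclusion eGFR must lie in [30, 60)")


@dataclass(frozen=True)
class SlopeFit:
    slope: float  # mL/min/1.73 m² per year
    intercept: float
    n_points: int
    span_days: float


@dataclass(frozen=True)
class OutcomeRecord:
    person_id: object
    outcome: str
    time: float  # days since index
    code: int  # 0 censored, 1 event, 2 competing death

    def __post_init__(self):
        if self.time < 0:
            raise ContractViolationError("outcome time precedes index")
        if self.code not in (0, 1, 2):
            raise InvalidInputError(f"unknown outcome code {self.code}")


def _as_sorted_series(times, egfr):
    t = np.asarray(times, dtype=float)
    e = np.asarray(egfr, dtype=float)
    if t.shape != e.shape:
        raise ContractViolationError("times and egfr must have equal length")
    if np.any(np.diff(t) < 0):
        raise ContractViolationError("series must be sorted by time")
    return t, e


def find_incident_ckd_g3(
    times: Sequence[float],
    egfr: Sequence[float],
    enrollment_start: float,
    enrollment_end: float,
    lookback_years: float = 3.0,
    krt_time: Optional[float] = None,
    person_id=None,
    return_reason: bool = False,
):
    """Find a person's incident CKD G3 index, or ``None``.

    Scans the AKI-filtered series (restricted to the lookback + enrollment
    horizon) for the earliest pair of eGFR values in [30, 60) separated by
    >=90 days. The pair's second measurement defines the index time and the
    inclusion eGFR. Returns ``None`` when the first qualifying pair completes
    before ``enrollment_start`` (prevalent disease), after ``enrollment_end``,
    or when kidney replacement therapy predates the index.

    With ``return_reason=True`` returns ``(record_or_None, reason)`` where
    reason is one of ``included / no_qualifying_pair / prevalent /
    after_window / prior_krt``.
    """
    t, e = _as_sorted_series(times, egfr)
    horizon_start = enrollment_start - lookback_years * DAYS_PER_YEAR
    keep = t >= horizon_start
    t, e = t[keep], e[keep]

    in_band = (e >= G3_LOWER) & (e < G3_UPPER)
    record, reason = None, "no_qualifying_pair"
    first_band_time = None
    for i in range(len(t)):
        if not in_band[i]:
            continue
        if first_band_time is None:
            first_band_time = t[i]
            continue
        if t[i] - first_band_time >= PAIR_GAP_DAYS:
            index_time, inclusion = t[i], e[i]
            if index_time < enrollment_start:
                reason = "prevalent"
            elif index_time > enrollment_end:
                reason = "after_window"
            elif krt_time is not None and krt_time < index_time:
                reason = "prior_krt"
            else:
                substage = classify_substage(t, e, index_time)
                record = IncidentCkdRecord(person_id, index_time, inclusion, substage)
                reason = "included"
            break
    if return_reason:
        return record, reason
    return record


def classify_substage(times, egfr, index_time: float) -> str:
    """G3b iff two eGFR values in [30, 45) at/before index are >=90 days apart."""
    t, e = _as_sorted_series(times, egfr)
    band = (e >= G3_LOWER) & (e < G3B_UPPER) & (t <= index_time)
    tb = t[band]
    if tb.size >= 2 and tb.max() - tb.min() >= PAIR_GAP_DAYS:
        return "G3b"
    return "G3a"


def fit_egfr_slope(times, egfr) -> SlopeFit:
    """OLS of eGFR on time (time in years); slope in mL/min/1.73 m²/yr."""
    t, e = _as_sorted_series(times, egfr)
    if t.size < 2:
        raise InvalidInputError("slope fit needs at least two points")
    ty = t / DAYS_PER_YEAR
    tbar, ebar = ty.mean(), e.mean()
    sxx = np.sum((ty - tbar) ** 2)
    if sxx == 0:
        raise InvalidInputError("slope fit degenerate: all times identical")
    slope = np.sum((ty - tbar) * (e - ebar)) / sxx
    intercept = ebar - slope * tbar
    return SlopeFit(float(slope), float(intercept), int(t.size), float(t.max() - t.min()))


def _qualifies_as_m1(t, e, i, inclusion_egfr, index_time):
    """Clauses on a candidate m1 at position i: drop, window size/span, slope."""
    ti, ei = t[i], e[i]
    if ti <= index_time or ei > inclusion_egfr - RAPID_DROP:
        return False
    w = (t > ti - RAPID_WINDOW_DAYS) & (t <= ti)
    if w.sum() < RAPID_MIN_POINTS:
        return False
    tw = t[w]
    if ti - tw.min() < RAPID_SPAN_DAYS:
        return False
    return fit_egfr_slope(tw, e[w]).slope <= RAPID_SLOPE


def detect_rapid_progression(
    times,
    egfr,
    record: IncidentCkdRecord,
    require_confirmation: bool = True,
) -> Optional[float]:
    """Time of (confirmed or potential) rapid progression, or ``None``.

    ``times``/``egfr`` is the person's full AKI-filtered series including
    pre-index measurements; those participate in slope windows but are never
    candidates. A candidate m1 must (a) sit >=5 below the inclusion eGFR,
    (b) give an OLS slope <= -5/yr over m1 plus all measurements in the
    preceding 365 days, and (c) have >=3 points in that window spanning
    >=90 days from its first measurement to m1.

    In confirmed mode m1 additionally needs a measurement 30-180 days later
    that is <= m1's eGFR or itself satisfies (a)-(c); the event time is the
    earliest such confirmatory time over all candidates. In potential mode
    the event time is the first qualifying m1. Failed candidates never block
    later ones.
    """
    t, e = _as_sorted_series(times, egfr)
    post = np.flatnonzero(t > record.index_time)
    qualifies_cache: dict = {}

    def qualifies(i):
        if i not in qualifies_cache:
            qualifies_cache[i] = _qualifies_as_m1(t, e, i, record.inclusion_egfr, record.index_time)
        return qualifies_cache[i]

    best: Optional[float] = None
    for i in post:
        if best is not None and t[i] + CONFIRM_MIN_DAYS >= best:
            break  # no later candidate can confirm earlier
        if not qualifies(i):
            continue
        if not require_confirmation:
            return float(t[i])
        window = np.flatnonzero(
            (t - t[i] >= CONFIRM_MIN_DAYS) & (t - t[i] <= CONFIRM_MAX_DAYS)
        )
        for j in window:
            if e[j] <= e[i] or qualifies(j):
                if best is None or t[j] < best:
                    best = float(t[j])
                break
    return best


def detect_category_drop(times, egfr, record: IncidentCkdRecord) -> Optional[float]:
    """First post-index measurement with >=25% eGFR drop and a worse GFR category."""
    t, e = _as_sorted_series(times, egfr)
    inclusion_rank = gfr_stage_rank(record.inclusion_egfr)
    post = (t > record.index_time) & (e <= CATEGORY_DROP_FRACTION * record.inclusion_egfr)
    hits = np.flatnonzero(post)
    for i in hits:
        if gfr_stage_rank(e[i]) > inclusion_rank:
            return float(t[i])
    return None


def detect_kidney_failure(times, egfr, krt_time: Optional[float] = None) -> Optional[float]:
    """Earliest of (second of a <15 eGFR pair >=90 days apart) and KRT."""
    t, e = _as_sorted_series(times, egfr)
    low = e < KIDNEY_FAILURE_EGFR
    pair_time = None
    first_low = None
    for i in range(len(t)):
        if not low[i]:
            continue
        if first_low is None:
            first_low = t[i]
        elif t[i] - first_low >= PAIR_GAP_DAYS:
            pair_time = float(t[i])
            break
    candidates = [x for x in (pair_time, krt_time) if x is not None]
    return min(candidates) if candidates else None


def resolve_outcome(
    person_id,
    outcome: str,
    index_time: float,
    event_time: Optional[float],
    death_time: Optional[float],
    emigration_time: Optional[float],
    admin_end: float,
) -> OutcomeRecord:
    """Assign the competing-risk code for one person/outcome.

    Event wins ties with death; death wins ties with censoring (events
    precede censorings). Censor time is min(emigration, admin_end). Times in
    the returned record are days since index.
    """
    if event_time is not None and event_time < index_time:
        raise ContractViolationError("event time precedes index time")
    censor = admin_end if emigration_time is None else min(emigration_time, admin_end)
    if event_time is not None and (death_time is None or event_time <= death_time) and event_time <= censor:
        return OutcomeRecord(person_id, outcome, event_time - index_time, 1)
    if death_time is not None and death_time <= censor:
        return OutcomeRecord(person_id, outcome, death_time - index_time, 2)
    return OutcomeRecord(person_id, outcome, max(censor - index_time, 0.0), 0)
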