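"""Independent brute-force oracle implementations used only by the tests.

Everything here is written as plain, slow, obviously-correct Python with
explicit loops — deliberately sharing no code path with the package — so the
package implementations can be checked against them on fuzzed inputs.
"""

from __future__ import annotations

import math

DAYS_PER_YEAR = 365.25


# ---------------------------------------------------------------- AKI

def oracle_aki_onsets(times, values):
    """O(n^2) pairwise scan of both KDIGO onset criteria."""
    onsets = []
    n = len(times)
    for i in range(n):
        hit = False
        for j in range(n):
            if times[j] < times[i] and times[i] - times[j] <= 2.0:
                if values[i] - values[j] >= 26.5:
                    hit = True
        baseline = None
        for j in range(n):
            if times[j] < times[i] and times[i] - times[j] <= 7.0:
                if baseline is None or values[j] < baseline:
                    baseline = values[j]
        if baseline is not None and values[i] >= 1.5 * baseline:
            hit = True
        if hit:
            onsets.append(times[i])
    return onsets


def oracle_episodes(times, values, onsets):
    """Direct transliteration of the episode rule, then interval merging."""
    raw = []
    for onset in sorted(onsets):
        baseline = None
        for j in range(len(times)):
            if onset - 7.0 <= times[j] < onset:
                if baseline is None or values[j] < baseline:
                    baseline = values[j]
        if baseline is None:
            prior = [values[j] for j in range(len(times)) if times[j] < onset]
            baseline = min(prior) if prior else values[list(times).index(onset)]
        resolution = onset + 90.0
        for j in range(len(times)):
            if times[j] > onset and values[j] < 1.25 * baseline:
                if times[j] < resolution:
                    resolution = times[j]
                break
        raw.append([onset, resolution])
    merged = []
    for interval in raw:
        if merged and interval[0] <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], interval[1])
        else:
            merged.append(interval)
    return [(a, b) for a, b in merged]


# ---------------------------------------------------------------- case finding

def oracle_incident(times, egfr, start, end, lookback_years=3.0, krt_time=None):
    """All-pairs search for the first qualifying index; returns
    (index_time, inclusion_egfr) or (None, reason)."""
    horizon = start - lookback_years * DAYS_PER_YEAR
    pts = [(t, e) for t, e in zip(times, egfr) if t >= horizon]
    best_j = None
    for j in range(len(pts)):
        for i in range(j):
            if 30 <= pts[i][1] < 60 and 30 <= pts[j][1] < 60 and pts[j][0] - pts[i][0] >= 90:
                if best_j is None or pts[j][0] < pts[best_j][0]:
                    best_j = j
    if best_j is None:
        return None, "no_qualifying_pair"
    t2, e2 = pts[best_j]
    if t2 < start:
        return None, "prevalent"
    if t2 > end:
        return None, "after_window"
    if krt_time is not None and krt_time < t2:
        return None, "prior_krt"
    return (t2, e2), "included"


def oracle_substage(times, egfr, index_time):
    for i in range(len(times)):
        for j in range(len(times)):
            if i == j:
                continue
            if (
                times[i] <= index_time
                and times[j] <= index_time
                and 30 <= egfr[i] < 45
                and 30 <= egfr[j] < 45
                and abs(times[j] - times[i]) >= 90
            ):
                return "G3b"
    return "G3a"


# ---------------------------------------------------------------- slopes & outcomes

def oracle_ols_slope(times, values):
    """Closed-form OLS slope/intercept, time in years."""
    t = [x / DAYS_PER_YEAR for x in times]
    n = len(t)
    tbar = sum(t) / n
    vbar = sum(values) / n
    num = sum((ti - tbar) * (vi - vbar) for ti, vi in zip(t, values))
    den = sum((ti - tbar) ** 2 for ti in t)
    slope = num / den
    return slope, vbar - slope * tbar


def oracle_stage(egfr):
    if egfr >= 90:
        return 0
    if egfr >= 60:
        return 1
    if egfr >= 45:
        return 2
    if egfr >= 30:
        return 3
    if egfr >= 15:
        return 4
    return 5


def oracle_category_drop(times, egfr, index_time, inclusion_egfr):
    for t, e in sorted(zip(times, egfr)):
        if t <= index_time:
            continue
        if e <= 0.75 * inclusion_egfr and oracle_stage(e) > oracle_stage(inclusion_egfr):
            return t
    return None


def oracle_kidney_failure(times, egfr, krt_time=None):
    pair = None
    for j in range(len(times)):
        for i in range(j):
            if egfr[i] < 15 and egfr[j] < 15 and times[j] - times[i] >= 90:
                if pair is None or times[j] < pair:
                    pair = times[j]
    options = [x for x in (pair, krt_time) if x is not None]
    return min(options) if options else None


def oracle_rapid(times, egfr, index_time, inclusion_egfr, require_confirmation):
    """Step-by-step transliteration of the rapid-progression criteria."""

    def window(i):
        return [j for j in range(len(times)) if times[i] - 365.0 < times[j] <= times[i]]

    def qualifies(i):
        if times[i] <= index_time:
            return False
        if egfr[i] > inclusion_egfr - 5.0:
            return False
        w = window(i)
        if len(w) < 3:
            return False
        first = min(times[j] for j in w)
        if times[i] - first < 90.0:
            return False
        slope, _ = oracle_ols_slope([times[j] for j in w], [egfr[j] for j in w])
        return slope <= -5.0

    event_times = []
    for i in range(len(times)):
        if not qualifies(i):
            continue
        if not require_confirmation:
            event_times.append(times[i])
            continue
        confirmations = [
            j
            for j in range(len(times))
            if 30.0 <= times[j] - times[i] <= 180.0 and (egfr[j] <= egfr[i] or qualifies(j))
        ]
        if confirmations:
            event_times.append(min(times[j] for j in confirmations))
    return min(event_times) if event_times else None


def oracle_outcome(index, event, death, emigration, admin_end):
    """Enumeration-style resolution of (time-since-index, code)."""
    censor = admin_end if emigration is None else min(emigration, admin_end)
    candidates = []
    if event is not None:
        candidates.append((event, 1, 0))  # events win ties
    if death is not None:
        candidates.append((death, 2, 1))
    candidates.append((censor, 0, 2))
    time, code, _ = min(candidates, key=lambda x: (x[0], x[2]))
    return max(time - index, 0.0), code


# ---------------------------------------------------------------- estimator

def oracle_aalen_johansen(times, codes):
    """Tabular risk-set walk; returns (event_times, {cause: cifs}, survivals)."""
    rows = sorted(zip(times, codes))
    event_times = sorted({t for t, c in rows if c != 0})
    surv = 1.0
    cif = {1: 0.0, 2: 0.0}
    out_t, out_cif, out_s = [], {1: [], 2: []}, []
    for et in event_times:
        n_risk = sum(1 for t, _ in rows if t >= et)
        d = {k: sum(1 for t, c in rows if t == et and c == k) for k in (1, 2)}
        for k in (1, 2):
            cif[k] += surv * d[k] / n_risk
        surv *= 1.0 - (d[1] + d[2]) / n_risk
        out_t.append(et)
        out_cif[1].append(cif[1])
        out_cif[2].append(cif[2])
        out_s.append(surv)
    return out_t, out_cif, out_s


def oracle_closed_form_cif(lam1, lam2, t_years):
    total = lam1 + lam2
    if total == 0:
        return 0.0
    return lam1 / total * (1.0 - math.exp(-total * t_years))
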