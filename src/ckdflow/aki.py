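"""KDIGO acute-kidney-injury episode detection on creatinine time series.

A measurement marks an AKI onset when plasma creatinine rises by
>=26.5 µmol/L relative to some earlier measurement taken within the preceding
48 h, or when it reaches >=1.5x the baseline, with baseline taken as the
minimum creatinine over the preceding 7 days. Measurements falling inside an
episode (onset through resolution, closed interval) are flagged and excluded
from all chronic phenotyping downstream.

Episode extent is a bounded exclusion rule: an episode resolves at the first
subsequent measurement below 1.25x the pre-onset baseline, capped at 90 days
after onset; overlapping episodes are merged.

Times are in days (floats allowed); 48 h == 2.0 days, with ties at exactly
48 h counting as within the window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ckdflow.errors import ContractViolationError

__all__ = [
    "AkiEpisode",
    "detect_aki_onsets",
    "build_episodes",
    "flag_excluded",
    "ABSOLUTE_RISE_UMOL_L",
    "RELATIVE_RISE_FACTOR",
    "ABSOLUTE_WINDOW_DAYS",
    "BASELINE_WINDOW_DAYS",
    "RECOVERY_FACTOR",
    "EPISODE_CAP_DAYS",
]

ABSOLUTE_RISE_UMOL_L = 26.5
RELATIVE_RISE_FACTOR = 1.5
ABSOLUTE_WINDOW_DAYS = 2.0
BASELINE_WINDOW_DAYS = 7.0
RECOVERY_FACTOR = 1.25
EPISODE_CAP_DAYS = 90.0


@dataclass(frozen=True)
class AkiEpisode:
    """One merged AKI episode for one person; interval is closed."""

    person_id: object
    onset_time: float
    resolution_time: float

    def __post_init__(self):
        if self.resolution_time < self.onset_time:
            raise ContractViolationError("episode resolution precedes onset")


def _check_sorted(times: np.ndarray) -> None:
    if np.any(np.diff(times) < 0):
        raise ContractViolationError("measurement series must be sorted by time")


def detect_aki_onsets(times: Sequence[float], creatinine: Sequence[float]) -> list:
    """Return the times of measurements that trigger a KDIGO AKI onset.

    ``times``/``creatinine`` form one person's sorted measurement series.
    The triggering (higher) measurement is the onset; the earlier comparison
    measurement is retained.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(creatinine, dtype=float)
    if t.shape != v.shape:
        raise ContractViolationError("times and creatinine must have equal length")
    _check_sorted(t)
    onsets = []
    for i in range(1, len(t)):
        ti, vi = t[i], v[i]
        recent = (t >= ti - ABSOLUTE_WINDOW_DAYS) & (t < ti)
        if np.any(recent) and vi - v[recent].min() >= ABSOLUTE_RISE_UMOL_L:
            onsets.append(ti)
            continue
        week = (t >= ti - BASELINE_WINDOW_DAYS) & (t < ti)
        if np.any(week) and vi >= RELATIVE_RISE_FACTOR * v[week].min():
            onsets.append(ti)
    return onsets


def build_episodes(
    times: Sequence[float],
    creatinine: Sequence[float],
    onsets: Sequence[float],
    person_id=None,
) -> list:
    """Turn onset times into merged :class:`AkiEpisode` intervals.

    Each episode resolves at the first measurement after onset whose
    creatinine is below ``RECOVERY_FACTOR`` times the pre-onset baseline
    (minimum over the 7 days before onset), or ``EPISODE_CAP_DAYS`` after
    onset, whichever comes first.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(creatinine, dtype=float)
    _check_sorted(t)
    onset_arr = np.sort(np.asarray(list(onsets), dtype=float))
    if onset_arr.size and not np.all(np.isin(onset_arr, t)):
        raise ContractViolationError("onsets must be a subset of measurement times")

    raw = []
    for onset in onset_arr:
        before = (t >= onset - BASELINE_WINDOW_DAYS) & (t < onset)
        if np.any(before):
            baseline = v[before].min()
        else:  # unreachable for detected onsets; defensive for manual lists
            baseline = v[t < onset].min() if np.any(t < onset) else v[t == onset][0]
        cap = onset + EPISODE_CAP_DAYS
        after = np.flatnonzero((t > onset) & (v < RECOVERY_FACTOR * baseline))
        if after.size and t[after[0]] <= cap:
            resolution = t[after[0]]
        else:
            resolution = cap
        raw.append((onset, resolution))

    merged = []
    for onset, resolution in raw:
        if merged and onset <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], resolution)
        else:
            merged.append([onset, resolution])
    return [AkiEpisode(person_id, a, b) for a, b in merged]


def flag_excluded(times: Sequence[float], episodes: Sequence[AkiEpisode]) -> np.ndarray:
    """Boolean mask: True where a measurement falls inside any episode."""
    t = np.asarray(times, dtype=float)
    mask = np.zeros(t.shape, dtype=bool)
    for ep in episodes:
        mask |= (t >= ep.onset_time) & (t <= ep.resolution_time)
    return mask


def detect_and_flag(times, creatinine, person_id=None):
    """Convenience: detect onsets, build episodes, return (mask, episodes)."""
    onsets = detect_aki_onsets(times, creatinine)
    episodes = build_episodes(times, creatinine, onsets, person_id=person_id)
    return flag_excluded(times, episodes), episodes
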