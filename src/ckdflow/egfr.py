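"""CKD-EPI creatinine equations and KDIGO staging.

All creatinine inputs are plasma creatinine in µmol/L; eGFR outputs are in
mL/min/1.73 m². Functions accept scalars or numpy arrays (broadcasting), and
sex as ``"female"``/``"male"`` scalars or arrays thereof.

The 2009 equation is implemented without the race coefficient (the source
registries carry no race variable); the 2021 equation is race-free by
construction. eGFR values are carried at full floating precision — no rounding
happens before any threshold comparison.
"""

from __future__ import annotations

from typing import Union

import numpy as np

from ckdflow.errors import InvalidInputError

__all__ = [
    "UMOL_PER_MGDL",
    "EQUATION_CONSTANTS",
    "egfr_ckdepi_2009",
    "egfr_ckdepi_2021",
    "gfr_stage",
    "gfr_stage_rank",
    "albuminuria_stage",
    "GFR_STAGE_ORDER",
]

ArrayLike = Union[float, np.ndarray]

#: conversion between µmol/L and mg/dL of creatinine
UMOL_PER_MGDL = 88.42

#: published coefficients, exported for transparency/config dumps
EQUATION_CONSTANTS = {
    "2009": {
        "scale": 141.0,
        "kappa": {"female": 0.7, "male": 0.9},
        "alpha": {"female": -0.329, "male": -0.411},
        "beta": -1.209,
        "age_base": 0.993,
        "female_factor": 1.018,
    },
    "2021": {
        "scale": 142.0,
        "kappa": {"female": 0.7, "male": 0.9},
        "alpha": {"female": -0.241, "male": -0.302},
        "beta": -1.200,
        "age_base": 0.9938,
        "female_factor": 1.012,
    },
}

#: severity order used for "drop in GFR category" comparisons
GFR_STAGE_ORDER = {"G1": 0, "G2": 1, "G3a": 2, "G3b": 3, "G4": 4, "G5": 5}


def _female_mask(sex: ArrayLike) -> np.ndarray:
    sex_arr = np.asarray(sex)
    valid = np.isin(sex_arr, ("female", "male"))
    if not np.all(valid):
        bad = np.unique(sex_arr[~valid]) if sex_arr.ndim else sex_arr
        raise InvalidInputError(f"sex must be 'female' or 'male', got {bad!r}")
    return sex_arr == "female"


def _ckdepi(creatinine: ArrayLike, age: ArrayLike, sex: ArrayLike, version: str) -> ArrayLike:
    c = EQUATION_CONSTANTS[version]
    creat = np.asarray(creatinine, dtype=float)
    age_arr = np.asarray(age, dtype=float)
    if np.any(creat <= 0) or not np.all(np.isfinite(creat)):
        raise InvalidInputError("creatinine must be positive and finite (µmol/L)")
    if np.any(age_arr < 18) or not np.all(np.isfinite(age_arr)):
        raise InvalidInputError("age must be finite and >= 18 years")
    female = _female_mask(sex)

    scr = creat / UMOL_PER_MGDL
    kappa = np.where(female, c["kappa"]["female"], c["kappa"]["male"])
    alpha = np.where(female, c["alpha"]["female"], c["alpha"]["male"])
    ratio = scr / kappa
    egfr = (
        c["scale"]
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** c["beta"]
        * c["age_base"] ** age_arr
        * np.where(female, c["female_factor"], 1.0)
    )
    if egfr.ndim == 0:
        return float(egfr)
    return egfr


def egfr_ckdepi_2009(creatinine: ArrayLike, age: ArrayLike, sex: ArrayLike) -> ArrayLike:
    """2009 CKD-EPI creatinine eGFR, race coefficient not applied.

    Parameters
    ----------
    creatinine : plasma creatinine in µmol/L (> 0).
    age : age in years (>= 18).
    sex : ``"female"`` or ``"male"``.
    """
    return _ckdepi(creatinine, age, sex, "2009")


def egfr_ckdepi_2021(creatinine: ArrayLike, age: ArrayLike, sex: ArrayLike) -> ArrayLike:
    """2021 race-free CKD-EPI creatinine eGFR."""
    return _ckdepi(creatinine, age, sex, "2021")


# stage boundaries, closed on the left on the eGFR scale: G3a = [45, 60) etc.
_STAGE_EDGES = np.array([15.0, 30.0, 45.0, 60.0, 90.0])
_STAGE_NAMES = np.array(["G5", "G4", "G3b", "G3a", "G2", "G1"])


def gfr_stage(egfr: ArrayLike):
    """Map eGFR to its KDIGO GFR category.

    Boundaries 90/60/45/30/15 partition the positive reals with half-open
    intervals closed on the left, so e.g. 45.0 -> G3a and 44.999 -> G3b.
    """
    arr = np.asarray(egfr, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise InvalidInputError("eGFR must be positive and finite")
    idx = np.searchsorted(_STAGE_EDGES, arr, side="right")
    out = _STAGE_NAMES[idx]
    if out.ndim == 0:
        return str(out)
    return out


def gfr_stage_rank(egfr: ArrayLike):
    """Severity rank of :func:`gfr_stage` (G1=0 ... G5=5); higher is worse."""
    arr = np.asarray(egfr, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise InvalidInputError("eGFR must be positive and finite")
    idx = np.searchsorted(_STAGE_EDGES, arr, side="right")
    rank = len(_STAGE_EDGES) - idx
    if np.ndim(egfr) == 0:
        return int(rank)
    return rank


def albuminuria_stage(uacr) -> str:
    """KDIGO albuminuria stage from uACR in mg/g.

    <30 -> A1, [30, 300] -> A2, >300 -> A3 (300 exactly is A2); ``None``/NaN
    -> ``"missing"``.
    """
    if uacr is None:
        return "missing"
    value = float(uacr)
    if np.isnan(value):
        return "missing"
    if value < 0:
        raise InvalidInputError(f"uACR must be non-negative, got {value}")
    if value < 30:
        return "A1"
    if value <= 300:
        return "A2"
    return "A3"
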