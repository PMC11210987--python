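"""Delimited-text readers and writers for the pipeline interchange tables.

The interchange format is plain CSV with explicit headers; times are numeric
days since a configurable epoch. Readers validate schemas, collect row-level
problems with line numbers instead of failing on the first bad value, and
deduplicate exact duplicates with a logged warning.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import List, Tuple

import numpy as np
import pandas as pd

from ckdflow.errors import SchemaError

log = logging.getLogger("ckdflow")

__all__ = [
    "read_measurements",
    "read_persons",
    "write_table",
    "MEASUREMENT_COLUMNS",
    "PERSON_COLUMNS",
    "CREATININE_PLAUSIBLE_RANGE",
]

MEASUREMENT_COLUMNS = ["person_id", "time", "creatinine_umol_l"]
PERSON_COLUMNS = [
    "person_id",
    "sex",
    "birth_time",
    "diabetes",
    "hypertension",
    "cvd",
    "uacr_mg_g",
    "death_time",
    "emigration_time",
    "krt_time",
    "first_admission_time",
]
CREATININE_PLAUSIBLE_RANGE = (10.0, 2000.0)


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_measurements(path) -> Tuple[pd.DataFrame, List[str]]:
    """Read a long-format creatinine table.

    Returns ``(table, row_errors)``. The table is sorted by person and time,
    exact duplicates removed, and rows with non-numeric or implausible
    creatinine (outside 10-2000 µmol/L) dropped; each dropped row is reported
    in ``row_errors`` with its 1-based file line number.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    df = pd.read_csv(path)
    _require_columns(df, MEASUREMENT_COLUMNS, path)
    if "setting" not in df.columns:
        df["setting"] = "outpatient"

    errors: List[str] = []
    lines = df.index.to_numpy() + 2  # header is line 1
    creat = pd.to_numeric(df["creatinine_umol_l"], errors="coerce")
    time = pd.to_numeric(df["time"], errors="coerce")
    bad_numeric = creat.isna() | time.isna()
    lo, hi = CREATININE_PLAUSIBLE_RANGE
    implausible = ~bad_numeric & ((creat < lo) | (creat > hi))
    for ln, row in zip(lines[bad_numeric], df.index[bad_numeric]):
        errors.append(f"line {ln}: non-numeric time or creatinine")
    for ln, val in zip(lines[implausible], creat[implausible]):
        errors.append(f"line {ln}: creatinine {val} µmol/L outside plausible range {lo}-{hi}")
    keep = ~(bad_numeric | implausible)
    df = df.loc[keep].copy()
    df["creatinine_umol_l"] = creat[keep]
    df["time"] = time[keep]

    before = len(df)
    df = df.drop_duplicates(subset=["person_id", "time", "creatinine_umol_l", "setting"])
    dropped = before - len(df)
    if dropped:
        log.warning("%s: removed %d duplicated measurement row(s)", path, dropped)
    if errors:
        log.warning("%s: %d malformed row(s) dropped", path, len(errors))
    df = df.sort_values(["person_id", "time"], kind="stable").reset_index(drop=True)
    return df, errors


def read_persons(path) -> pd.DataFrame:
    """Read the person table; validates schema and sex levels."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    df = pd.read_csv(path)
    _require_columns(df, PERSON_COLUMNS, path)
    bad_sex = ~df["sex"].isin(["female", "male"])
    if bad_sex.any():
        raise SchemaError(f"{path}: invalid sex value(s) {df['sex'][bad_sex].unique()!r}")
    if df["person_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicated person_id")
    return df.reset_index(drop=True)


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a DataFrame as headered CSV, creating parent directories."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
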