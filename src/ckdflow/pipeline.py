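"""End-to-end orchestration: AKI filter -> case finding -> outcomes -> risks.

``phenotype_cohort`` is the per-person driver used by both the CLI and the
tests; ``run_pipeline`` adds file IO, the attrition log and a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

import ckdflow
from ckdflow import aki, phenotyping as ph, risks
from ckdflow.egfr import egfr_ckdepi_2009, egfr_ckdepi_2021
from ckdflow.errors import ConfigError
from ckdflow.io import read_measurements, read_persons, write_table

log = logging.getLogger("ckdflow")

DAYS_PER_YEAR = 365.25

__all__ = ["PipelineConfig", "phenotype_cohort", "run_pipeline"]


@dataclass
class PipelineConfig:
    enrollment_start: float
    enrollment_end: float
    admin_end: float
    equation: str = "2009"  # or "2021"
    lookback_years: float = 3.0
    horizons: Sequence[float] = (365.0, 1095.0)
    min_age: float = 18.0

    def validate(self) -> None:
        if self.equation not in ("2009", "2021"):
            raise ConfigError("equation must be '2009' or '2021'")
        if any(h <= 0 for h in self.horizons):
            raise ConfigError("horizons must be positive")
        if not (self.enrollment_start <= self.enrollment_end <= self.admin_end):
            raise ConfigError("require enrollment_start <= enrollment_end <= admin_end")


def phenotype_cohort(
    measurements: pd.DataFrame,
    persons: pd.DataFrame,
    config: PipelineConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, int]]:
    """Run AKI filtering, case finding and outcome classification.

    Returns ``(cohort, outcomes, attrition)``. ``cohort`` has one row per
    included person (index_time, inclusion_egfr, substage, age_at_index,
    covariates, eGFR testing frequency in the prior year); ``outcomes`` has
    one row per person per outcome with days-since-index time and code
    0/1/2. ``attrition`` counts every person by disposition so the stages
    conserve: included + each exclusion category == persons seen.
    """
    config.validate()
    egfr_fn = egfr_ckdepi_2009 if config.equation == "2009" else egfr_ckdepi_2021
    attrition = {
        "persons_total": int(len(persons)),
        "no_measurements": 0,
        "no_adult_outpatient_measurements": 0,
        "no_qualifying_pair": 0,
        "prevalent": 0,
        "after_window": 0,
        "prior_krt": 0,
        "dead_or_emigrated_before_index": 0,
        "included": 0,
    }

    meas = measurements[measurements["setting"] == "outpatient"] if "setting" in measurements else measurements
    grouped = {pid: g for pid, g in meas.groupby("person_id", sort=False)}

    cohort_rows: List[dict] = []
    outcome_rows: List[dict] = []
    pmap = persons.set_index("person_id")

    def _opt(row, col):
        v = row[col]
        return None if pd.isna(v) else float(v)

    for pid, prow in pmap.iterrows():
        g = grouped.get(pid)
        if g is None or len(g) == 0:
            attrition["no_measurements"] += 1
            continue
        t = g["time"].to_numpy(dtype=float)
        creat = g["creatinine_umol_l"].to_numpy(dtype=float)
        order = np.argsort(t, kind="stable")
        t, creat = t[order], creat[order]

        age = (t - float(prow["birth_time"])) / DAYS_PER_YEAR
        adult = age >= config.min_age
        t, creat, age = t[adult], creat[adult], age[adult]
        if t.size == 0:
            attrition["no_adult_outpatient_measurements"] += 1
            continue

        excluded, _episodes = aki.detect_and_flag(t, creat, person_id=pid)
        tk, ck, agek = t[~excluded], creat[~excluded], age[~excluded]
        if tk.size == 0:
            attrition["no_adult_outpatient_measurements"] += 1
            continue
        egfr = np.asarray(egfr_fn(ck, agek, str(prow["sex"])), dtype=float).reshape(tk.shape)

        krt_time = _opt(prow, "krt_time")
        record, reason = ph.find_incident_ckd_g3(
            tk,
            egfr,
            config.enrollment_start,
            config.enrollment_end,
            lookback_years=config.lookback_years,
            krt_time=krt_time,
            person_id=pid,
            return_reason=True,
        )
        if record is None:
            attrition[reason] += 1
            continue

        death_time = _opt(prow, "death_time")
        emig_time = _opt(prow, "emigration_time")
        if (death_time is not None and death_time < record.index_time) or (
            emig_time is not None and emig_time < record.index_time
        ):
            # registry inconsistency: measurements after recorded death/emigration
            attrition["dead_or_emigrated_before_index"] += 1
            continue
        attrition["included"] += 1

        post = tk >= record.index_time
        events: Dict[str, Optional[float]] = {
            "rapid": ph.detect_rapid_progression(tk, egfr, record, require_confirmation=True),
            "potential_rapid": ph.detect_rapid_progression(tk, egfr, record, require_confirmation=False),
            "category_drop": ph.detect_category_drop(tk, egfr, record),
            "kidney_failure": ph.detect_kidney_failure(tk[post], egfr[post], krt_time=krt_time),
        }
        adm = _opt(prow, "first_admission_time")
        events["hospitalization"] = adm if adm is not None and adm > record.index_time else None

        for outcome, etime in events.items():
            rec = ph.resolve_outcome(
                pid, outcome, record.index_time, etime, death_time, emig_time, config.admin_end
            )
            outcome_rows.append(
                {"person_id": pid, "outcome": outcome, "time": rec.time, "code": rec.code}
            )

        prior_year = (tk > record.index_time - 365.0) & (tk <= record.index_time)
        cohort_rows.append(
            {
                "person_id": pid,
                "index_time": record.index_time,
                "inclusion_egfr": record.inclusion_egfr,
                "substage": record.substage,
                "age_at_index": (record.index_time - float(prow["birth_time"])) / DAYS_PER_YEAR,
                "sex": str(prow["sex"]),
                "diabetes": int(prow["diabetes"]),
                "hypertension": int(prow["hypertension"]),
                "cvd": int(prow["cvd"]),
                "uacr_mg_g": prow["uacr_mg_g"],
                "egfr_tests_prior_year": int(prior_year.sum()),
            }
        )

    cohort = pd.DataFrame(
        cohort_rows,
        columns=[
            "person_id",
            "index_time",
            "inclusion_egfr",
            "substage",
            "age_at_index",
            "sex",
            "diabetes",
            "hypertension",
            "cvd",
            "uacr_mg_g",
            "egfr_tests_prior_year",
        ],
    )
    outcomes = pd.DataFrame(outcome_rows, columns=["person_id", "outcome", "time", "code"])
    assert (
        attrition["included"]
        + attrition["no_measurements"]
        + attrition["no_adult_outpatient_measurements"]
        + attrition["no_qualifying_pair"]
        + attrition["prevalent"]
        + attrition["after_window"]
        + attrition["prior_krt"]
        + attrition["dead_or_emigrated_before_index"]
        == attrition["persons_total"]
    )
    return cohort, outcomes, attrition


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(
    measurements_path,
    persons_path,
    out_dir,
    config: PipelineConfig,
) -> Dict[str, Path]:
    """Execute the full pipeline from files and persist all artifacts.

    Writes cohort.csv, outcomes.csv, curves_<outcome>.csv, heatmap.csv,
    summary.csv, attrition.csv and manifest.json under ``out_dir``; returns
    the artifact paths. Any stage failure aborts with the stage named in the
    raised error; logs written so far persist.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: Dict[str, Path] = {}
    stage = "read"
    try:
        measurements, row_errors = read_measurements(measurements_path)
        persons = read_persons(persons_path)

        stage = "phenotype"
        cohort, outcomes, attrition = phenotype_cohort(measurements, persons, config)
        artifacts["cohort"] = write_table(cohort, out_dir / "cohort.csv")
        artifacts["outcomes"] = write_table(outcomes, out_dir / "outcomes.csv")
        attr_df = pd.DataFrame(sorted(attrition.items()), columns=["category", "n_persons"])
        artifacts["attrition"] = write_table(attr_df, out_dir / "attrition.csv")
        for cat, cnt in attrition.items():
            log.info("attrition: %s = %d", cat, cnt)

        stage = "estimate"
        for outcome in ph.OUTCOMES:
            sub = outcomes[outcomes["outcome"] == outcome]
            if len(sub) == 0:
                continue
            curve = risks.aalen_johansen(sub["time"], sub["code"], causes=(1,))[1]
            artifacts[f"curve_{outcome}"] = write_table(
                curve.to_frame(), out_dir / f"curve_{outcome}.csv"
            )

        stage = "heatmap"
        rapid = outcomes[outcomes["outcome"] == "rapid"]
        if len(rapid):
            heat = risks.heatmap_table(rapid, persons, horizons=tuple(config.horizons))
            artifacts["heatmap"] = write_table(heat, out_dir / "heatmap.csv")

        stage = "summary"
        if len(cohort):
            summary = risks.cohort_summary(persons, cohort)
            artifacts["summary"] = write_table(summary, out_dir / "summary.csv")

        stage = "manifest"
        manifest = {
            "package_version": ckdflow.__version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "config": asdict(config),
            "config_hash": _config_hash(config),
            "n_measurement_row_errors": len(row_errors),
            "attrition": attrition,
        }
        manifest["config"]["horizons"] = list(config.horizons)
        mpath = out_dir / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
        artifacts["manifest"] = mpath
    except Exception as exc:
        log.error("pipeline stage '%s' failed: %s", stage, exc)
        exc.args = (f"pipeline stage '{stage}' failed: {exc}",) + exc.args[1:] if exc.args else (
            f"pipeline stage '{stage}' failed",
        )
        raise
    return artifacts
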