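"""CSV and JSON input/output for patient records and results.

The canonical patient CSV has one row per patient with columns

    patient_id, cohort, t_intervention, t_end, discharged, age, sex

where times are durations from admission in days (``t_intervention`` blank
when the patient never received the intervention) and ``discharged`` is a
boolean/0-1 event indicator.  A date-mode reader converting admission /
intervention / discharge calendar dates into durations is provided for real
deployments.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .records import PatientRecord

PathLike = Union[str, Path]

REQUIRED_COLUMNS = [
    "patient_id",
    "cohort",
    "t_intervention",
    "t_end",
    "discharged",
    "age",
    "sex",
]

_TRUE = {"true", "1", "yes", "t", "y"}
_FALSE = {"false", "0", "no", "f", "n"}


def _parse_bool(value, row: int, errors: list[str]) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, float, np.integer, np.floating)) and not pd.isna(value):
        if float(value) in (0.0, 1.0):
            return bool(value)
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    errors.append(f"row {row}: cannot parse discharged value {value!r}")
    return False


def _parse_float(value, row: int, col: str, errors: list[str]) -> Optional[float]:
    if pd.isna(value) or (isinstance(value, str) and not value.strip()):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        errors.append(f"row {row}: non-numeric {col} value {value!r}")
        return None


def records_from_dataframe(df: pd.DataFrame) -> list[PatientRecord]:
    """Build validated records from a canonical-schema frame.

    All problems are collected and raised together in one
    :class:`ValidationError`, each message naming the offending row.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError([f"missing column(s): {', '.join(missing)}"])
    errors: list[str] = []
    records: list[PatientRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        ti = _parse_float(row.t_intervention, i, "t_intervention", errors)
        te = _parse_float(row.t_end, i, "t_end", errors)
        dis = _parse_bool(row.discharged, i, errors)
        age = _parse_float(row.age, i, "age", errors)
        sex = None if pd.isna(row.sex) else str(row.sex).strip().lower() or None
        if te is None:
            errors.append(f"row {i}: t_end is required")
            continue
        rec = PatientRecord(
            patient_id=str(row.patient_id),
            cohort=str(row.cohort).strip(),
            t_intervention=ti,
            t_end=te,
            discharged=dis,
            age=age,
            sex=sex,
        )
        rec_errors = rec.errors()
        if rec_errors:
            errors.extend(f"row {i}: {msg}" for msg in rec_errors)
        else:
            records.append(rec)
    if errors:
        raise ValidationError(errors)
    return records


def read_patients(path: PathLike) -> list[PatientRecord]:
    """Read and validate the canonical patient CSV."""
    df = pd.read_csv(
        path,
        dtype={"patient_id": str, "cohort": str, "sex": str},
        float_precision="round_trip",
    )
    return records_from_dataframe(df)


def read_patients_dates(
    path: PathLike,
    admission_col: str = "admission_date",
    intervention_col: str = "intervention_date",
    end_col: str = "end_date",
) -> list[PatientRecord]:
    """Date-mode reader: calendar dates to durations from admission (days)."""
    df = pd.read_csv(path, dtype={"patient_id": str, "cohort": str, "sex": str})
    for col in (admission_col, intervention_col, end_col):
        if col not in df.columns:
            raise ValidationError([f"missing column(s): {col}"])
        df[col] = pd.to_datetime(df[col], errors="coerce")
    adm = df[admission_col]
    out = df.copy()
    out["t_intervention"] = (df[intervention_col] - adm).dt.total_seconds() / 86400.0
    out["t_end"] = (df[end_col] - adm).dt.total_seconds() / 86400.0
    for col in ("age", "sex", "discharged"):
        if col not in out.columns:
            out[col] = np.nan
    return records_from_dataframe(out[REQUIRED_COLUMNS])


def records_to_dataframe(records: Sequence[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "cohort": [r.cohort for r in records],
            "t_intervention": [r.t_intervention for r in records],
            "t_end": [r.t_end for r in records],
            "discharged": [r.discharged for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
        }
    )


def write_patients(records: Sequence[PatientRecord], path: PathLike) -> None:
    # %.17g guarantees float round-tripping through the CSV
    records_to_dataframe(records).to_csv(path, index=False, float_format="%.17g")


def write_scenario_sidecar(scenario, path: PathLike) -> None:
    """Write the generating scenario as a JSON sidecar for provenance."""
    from .simulate import scenario_to_dict

    Path(path).write_text(json.dumps(scenario_to_dict(scenario), indent=2))


def write_json(obj: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))
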