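"""Cohort CSV round-trip.

Baseline tables are one row per subject (``subject_id`` index column);
follow-up tables are long, one row per subject-year.  Missing values are
written as empty fields and read back as NaN; all measurement columns are
numeric.  Unknown columns warn, malformed numerics raise with the offending
row and column named.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (CANDIDATE_COLUMNS, COMPONENT_COLUMNS, MEDICATION_FLAGS)

__all__ = ["write_cohort_csv", "read_cohort_csv", "COLUMN_DICTIONARY"]

# column -> short description; doubles as the known-column registry
COLUMN_DICTIONARY = {
    "subject_id": "integer subject identifier",
    "age": "years", "height": "cm", "weight": "kg", "bmi": "kg/m^2",
    "sbp": "systolic blood pressure, mmHg",
    "dbp": "diastolic blood pressure, mmHg",
    "tc": "serum total cholesterol, mg/dl",
    "tg": "serum triglycerides, mg/dl",
    "hdl": "serum HDL cholesterol, mg/dl",
    "glucose": "fasting plasma glucose, mg/dl",
    "bun": "blood urea nitrogen, mg/dl",
    "creatinine": "serum creatinine, mg/dl",
    "uric_acid": "serum uric acid, mg/dl",
    "ggtp": "gamma-glutamyltranspeptidase, IU/L",
    "got": "glutamic-oxaloacetic transaminase, IU/L",
    "gpt": "glutamic-pyruvic transaminase, IU/L",
    "hemoglobin": "g/dl", "hematocrit": "%",
    "rbc": "red blood cells, million cells/uL",
    "wbc": "white blood cells, cells/uL",
    "urine_urobilinogen": "flag 0/1", "urine_protein": "flag 0/1",
    "urine_sugar": "flag 0/1", "urine_occult_blood": "flag 0/1",
    "alcohol": "drinking habit flag 0/1 (>= once weekly)",
    "smoking": "smoking habit flag 0/1 (past or current)",
    "exercise": "exercise category 0-3 (none .. daily)",
    "med_antihypertensive": "medication flag 0/1",
    "med_lipid": "medication flag 0/1",
    "med_diabetic": "medication flag 0/1",
    "year": "follow-up year, 1-based",
    "label": "cohort label",
}

_LABEL_COLUMNS = {"label"}


def write_cohort_csv(frame: pd.DataFrame, path) -> None:
    """Write a baseline or follow-up table; NaN becomes an empty field."""
    path = Path(path)
    df = frame.copy()
    if df.index.name == "subject_id":
        df = df.reset_index()
    df.to_csv(path, index=False, na_rep="")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort table back, validating numerics column by column.

    Empty fields become NaN.  Unknown columns are kept but warned about;
    a non-numeric entry in a numeric column raises a ValueError naming the
    row and column.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        if col not in COLUMN_DICTIONARY:
            warnings.warn(f"unknown column {col!r} in {path.name}",
                          stacklevel=2)
        ser = raw[col].replace("", np.nan)
        if col in _LABEL_COLUMNS or col not in COLUMN_DICTIONARY:
            out[col] = ser
            continue
        num = pd.to_numeric(ser, errors="coerce")
        bad = num.isna() & ser.notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"malformed numeric in column {col!r}, row {row + 2} "
                f"of {path.name}: {ser[row]!r}")
        out[col] = num
    if "subject_id" in out.columns:
        out["subject_id"] = out["subject_id"].astype(int)
        if "year" not in out.columns:
            out = out.set_index("subject_id")
    if "year" in out.columns:
        out["year"] = out["year"].astype(int)
    return out
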