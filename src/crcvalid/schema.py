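"""Cohort table schema: canonical columns, units, and delimited-text I/O.

One row per participant.  Units are fixed at the schema level (BMI kg/m²,
waist cm, height cm, physical activity MET-h/day); model specs perform any
rescaling they need.  Dates are integer days since 1970-01-01 and follow-up
time in years is days/365.25.  Boolean columns are stored as 0/1; missing
values are empty fields (``aspirin_use`` is observed only in the
coronary-heart-disease subgroup and is missing elsewhere).
"""

from __future__ import annotations

import io
from pathlib import Path

import pandas as pd

from .errors import SchemaError

SCHEMA_VERSION = "crcvalid-cohort-v1"

DAYS_PER_YEAR = 365.25

#: column -> pandas dtype ("float" columns may contain missing values)
COHORT_COLUMNS: dict[str, str] = {
    "id": "int64",
    "age": "float64",
    "sex": "object",            # male / female
    "region": "object",
    "urban": "int64",
    "height_cm": "float64",
    "bmi": "float64",           # may be missing
    "waist_cm": "float64",
    "smoking_status": "object",  # never / ex_regular / current
    "alcohol_weekly": "int64",
    "alcohol_category": "object",
    "diabetes": "int64",
    "physical_activity": "float64",  # MET-h/day
    "sitting_time": "object",
    "red_meat": "object",
    "processed_meat": "object",
    "vegetable": "object",
    "dairy": "object",
    "egg": "object",
    "sugar_confectionery": "object",
    "defecation_frequency": "object",
    "education": "object",
    "marital_status": "object",
    "nsaid_use": "int64",
    "metabolic_syndrome": "int64",
    "chd_history": "int64",
    "aspirin_use": "float64",   # 0/1, missing outside the CHD subgroup
    "prior_intestinal_cancer": "int64",
    "entry_date": "int64",      # days since epoch
    "exit_date": "float64",     # filled by outcome simulation / follow-up data
    "exit_reason": "object",    # crc / death_other / ltfu / admin
    "icd10": "object",          # present iff exit_reason == crc
}

EXIT_REASONS = ("crc", "death_other", "ltfu", "admin")


def validate_cohort(df: pd.DataFrame, *, require_exit: bool = False) -> None:
    """Check a cohort frame against the schema; raise :class:`SchemaError`."""
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort is missing schema columns: {missing}")
    if len(df) == 0:
        raise SchemaError("cohort is empty")
    sexes = set(df["sex"].dropna().unique())
    if not sexes <= {"male", "female"}:
        raise SchemaError(f"unexpected sex values: {sorted(sexes - {'male', 'female'})}")
    ages = df["age"]
    if (ages < 30).any() or (ages > 79).any():
        raise SchemaError("ages outside the 30-79 recruitment range")
    if require_exit:
        reasons = set(df["exit_reason"].dropna().unique())
        if df["exit_reason"].isna().any() or not reasons <= set(EXIT_REASONS):
            raise SchemaError("exit_reason must be filled for every record")
        if (df["exit_date"] < df["entry_date"]).any():
            raise SchemaError("exit before entry")
        has_code = df["icd10"].notna() & (df["icd10"] != "")
        if not (has_code == (df["exit_reason"] == "crc")).all():
            raise SchemaError("icd10 must be present iff exit_reason == crc")


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort as CSV with a versioned header line."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"#{SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def read_cohort(path: str | Path, *, require_exit: bool = True) -> pd.DataFrame:
    """Read and validate a cohort CSV written by :func:`write_cohort`."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if first != f"#{SCHEMA_VERSION}":
            raise SchemaError(
                f"{path}: expected schema header '#{SCHEMA_VERSION}', got {first!r}"
            )
        df = pd.read_csv(io.StringIO(fh.read()), dtype={"icd10": "object",
                                                        "exit_reason": "object"})
    validate_cohort(df, require_exit=require_exit)
    return df


def time_years(df: pd.DataFrame) -> pd.Series:
    """Follow-up time in years from entry/exit dates."""
    return (df["exit_date"] - df["entry_date"]) / DAYS_PER_YEAR
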