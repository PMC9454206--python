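"""Shared fixtures: synthetic model specs, toy cohorts, brute-force oracles.

Engine correctness is established on small synthetic specs and cohorts
built here, with exhaustive-pair / closed-form oracles implemented
independently of the package code paths they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from crcvalid.registry import parse_model_spec
from crcvalid.schema import COHORT_COLUMNS


def brute_force_auc(scores, labels) -> float:
    """All case-control pairs, ties 0.5 — the Mann–Whitney definition."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    cases = scores[labels]
    ctrls = scores[~labels]
    total = 0.0
    for c in cases:
        for d in ctrls:
            total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(ctrls))


def brute_force_concordance(times, events, scores) -> float:
    """Exhaustive usable-pair enumeration for Harrell's C.

    Usable: the earlier time is an observed event and the comparator
    survives strictly longer; concordant when the event scores higher,
    ties 0.5.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    scores = np.asarray(scores, dtype=float)
    numer = 0.0
    pairs = 0
    n = len(times)
    for i in range(n):
        if not events[i]:
            continue
        for j in range(n):
            if times[j] > times[i]:
                pairs += 1
                if scores[i] > scores[j]:
                    numer += 1.0
                elif scores[i] == scores[j]:
                    numer += 0.5
    return numer / pairs


@pytest.fixture
def toy_logistic_spec():
    """Two-variable logistic spec with known contributions."""
    return parse_model_spec(
        {
            "name": "toy_logistic",
            "model_type": "logistic",
            "native_horizon_years": 10,
            "applicable_sex": "both",
            "intercept_or_baseline": -2.0,
            "variables": [
                {
                    "name": "age",
                    "source_column": "age",
                    "kind": "continuous",
                    "coefficient": 0.1,
                    "transform": {"scale": 1.0, "offset": -50.0},
                    "missing_policy": "exclude_record",
                },
                {
                    "name": "smoking",
                    "source_column": "smoking_status",
                    "kind": "categorical",
                    "levels": [
                        {"when": {"equals": "never"}, "contribution": 0.0,
                         "reference": True},
                        {"when": {"equals": "ex_regular"}, "contribution": 0.3},
                        {"when": {"equals": "current"}, "contribution": 0.6},
                    ],
                },
            ],
        }
    )


@pytest.fixture
def toy_points_spec():
    """Three-variable point score: levels 0-2, 0-1, 0-3 with a risk table."""
    return parse_model_spec(
        {
            "name": "toy_points",
            "model_type": "points",
            "native_horizon_years": 10,
            "applicable_sex": "both",
            "variables": [
                {
                    "name": "age",
                    "source_column": "age",
                    "kind": "categorical",
                    "levels": [
                        {"when": {"range": [None, 50]}, "contribution": 0,
                         "reference": True},
                        {"when": {"range": [50, 65]}, "contribution": 1},
                        {"when": {"range": [65, None]}, "contribution": 2},
                    ],
                },
                {
                    "name": "diabetes",
                    "source_column": "diabetes",
                    "kind": "binary",
                    "coefficient": 1,
                },
                {
                    "name": "smoking",
                    "source_column": "smoking_status",
                    "kind": "categorical",
                    "levels": [
                        {"when": {"equals": "never"}, "contribution": 0,
                         "reference": True},
                        {"when": {"equals": "ex_regular"}, "contribution": 1},
                        {"when": {"equals": "current"}, "contribution": 3},
                    ],
                },
            ],
            "risk_table": [
                {"min_points": 0, "max_points": 1, "risk": 0.002},
                {"min_points": 2, "max_points": 3, "risk": 0.005},
                {"min_points": 4, "max_points": 6, "risk": 0.012},
            ],
        }
    )


def make_cohort_rows(rows: list[dict]) -> pd.DataFrame:
    """Build a schema-complete cohort frame from sparse row dicts."""
    defaults = {
        "id": None, "age": 50.0, "sex": "male", "region": "urban_1",
        "urban": 1, "height_cm": 165.0, "bmi": 23.0, "waist_cm": 80.0,
        "smoking_status": "never", "alcohol_weekly": 0,
        "alcohol_category": "never", "diabetes": 0,
        "physical_activity": 21.0, "sitting_time": "low",
        "red_meat": "weekly", "processed_meat": "rarely",
        "vegetable": "daily", "dairy": "rarely", "egg": "weekly",
        "sugar_confectionery": "rarely", "defecation_frequency": "daily",
        "education": "primary", "marital_status": "married", "nsaid_use": 0,
        "metabolic_syndrome": 0, "chd_history": 0, "aspirin_use": np.nan,
        "prior_intestinal_cancer": 0, "entry_date": 13000,
        "exit_date": np.nan, "exit_reason": None, "icd10": None,
    }
    out = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec.update(row)
        if rec["id"] is None:
            rec["id"] = i
        out.append(rec)
    return pd.DataFrame(out, columns=list(COHORT_COLUMNS))


@pytest.fixture
def cohort_factory():
    return make_cohort_rows
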