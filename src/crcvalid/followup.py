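"""Follow-up construction: exclusions, outcome composites, event labels.

Participants contribute person-time from study entry to the earliest of CRC
diagnosis/death, death from other causes, loss to follow-up, or 10 years
(administrative censoring).  Outcome composites are defined by literal
ICD-10 ranges:

========== =====================
composite  ICD-10 codes
========== =====================
CRC        C18–C20
colon      C18 (any subsite)
rectal     C19–C20
right      C18.0–C18.3
left       C18.5–C18.7
========== =====================

C18.4 (transverse colon) and C18.8/C18.9 count toward colon and CRC but
neither sided subset.  For a site-specific composite, CRC events at other
sites are censored (not dropped) at their event time.  For binary ROC
labels, an event within 10 years is a case and everyone else — including
those censored early — is a control.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CrcValidError, SchemaError
from .schema import DAYS_PER_YEAR

OUTCOME_SETS = ("CRC", "colon", "rectal", "right_colon", "left_colon")

HORIZON_YEARS = 10.0

_CODE_RE = re.compile(r"^C(\d{2})(?:\.(\d))?$")


@dataclass(frozen=True)
class ExclusionLog:
    """Counts per exclusion rule, their overlap, and retention arithmetic."""

    prior_intestinal_cancer: int
    missing_bmi: int
    overlap: int
    n_before: int
    n_after: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": [
                    "prior_intestinal_cancer",
                    "missing_bmi",
                    "overlap_both_rules",
                    "n_before",
                    "n_after",
                ],
                "count": [
                    self.prior_intestinal_cancer,
                    self.missing_bmi,
                    self.overlap,
                    self.n_before,
                    self.n_after,
                ],
            }
        )


def apply_exclusions(records: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLog]:
    """Remove participants with prior intestinal cancer or missing BMI.

    A record failing both rules is removed once but logged under both, with
    the overlap reported explicitly so the retention arithmetic
    ``n_before − (prior + bmi − overlap) = n_after`` is always auditable.
    """
    prior = records["prior_intestinal_cancer"].astype(bool).to_numpy()
    bmi_missing = records["bmi"].isna().to_numpy()
    drop = prior | bmi_missing
    log = ExclusionLog(
        prior_intestinal_cancer=int(prior.sum()),
        missing_bmi=int(bmi_missing.sum()),
        overlap=int((prior & bmi_missing).sum()),
        n_before=len(records),
        n_after=int((~drop).sum()),
    )
    return records.loc[~drop].copy(), log


def _parse_code(code: str) -> tuple[int, int | None]:
    m = _CODE_RE.match(str(code).strip())
    if not m:
        raise CrcValidError(f"malformed ICD-10 code {code!r}")
    return int(m.group(1)), None if m.group(2) is None else int(m.group(2))


def classify_outcome(icd10: str | None, outcome_set: str) -> bool:
    """Whether an ICD-10 code belongs to an outcome composite (literal ranges)."""
    if outcome_set not in OUTCOME_SETS:
        raise CrcValidError(
            f"unknown outcome set {outcome_set!r}; expected one of {OUTCOME_SETS}"
        )
    if icd10 is None or (isinstance(icd10, float) and np.isnan(icd10)) or icd10 == "":
        return False
    major, minor = _parse_code(icd10)
    if outcome_set == "CRC":
        return 18 <= major <= 20
    if outcome_set == "colon":
        return major == 18
    if outcome_set == "rectal":
        return major in (19, 20)
    if major != 18 or minor is None:
        return False
    if outcome_set == "right_colon":
        return 0 <= minor <= 3
    return 5 <= minor <= 7  # left_colon


def build_followup(records: pd.DataFrame, outcome_set: str = "CRC") -> pd.DataFrame:
    """Per-participant follow-up time and event label for one composite.

    Returns a frame with columns ``id``, ``time_years`` (truncated at 10),
    ``event`` (boolean), ``event_class`` and ``outcome_set``.  CRC events at
    sites outside the composite are censored at their event time; any exit
    recorded beyond 10 years becomes administrative censoring at exactly
    10 years.
    """
    if records["exit_reason"].isna().any():
        raise SchemaError("exit fields must be populated before follow-up")
    t = (
        records["exit_date"].to_numpy(float) - records["entry_date"].to_numpy(float)
    ) / DAYS_PER_YEAR
    if (t < 0).any():
        raise CrcValidError("exit before entry")
    event_class = records["exit_reason"].to_numpy(object).copy()
    beyond = t > HORIZON_YEARS
    event_class[beyond] = "admin"
    time_years = np.minimum(t, HORIZON_YEARS)

    in_set = np.array(
        [
            classify_outcome(code, outcome_set)
            for code in records["icd10"].to_numpy(object)
        ]
    )
    event = (event_class == "crc") & in_set
    return pd.DataFrame(
        {
            "id": records["id"].to_numpy(),
            "time_years": time_years,
            "event": event,
            "event_class": event_class,
            "outcome_set": outcome_set,
        },
        index=records.index,
    )
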