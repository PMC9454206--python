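"""Calibration of absolute 10-year risk: expected vs observed by quantile
groups, calibration slope/intercept, and affine recalibration.

Participants are grouped by quantiles (deciles by default) of expected
risk.  Observed risk per group is the Kaplan–Meier complement at 10 years
by default — a crude event proportion is biased downward when censoring
occurs before the horizon — with a crude estimator available by switch.
The calibration line is an ordinary least-squares fit of observed on mean
expected risk over the group points; recalibration applies
``r' = slope·r + intercept``, clamping to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .errors import ConfigurationError, DegenerateInputError

OBSERVED_ESTIMATORS = ("km", "crude")


@dataclass(frozen=True)
class ObservedRisk:
    value: float
    #: set when the risk set empties before the horizon with no events —
    #: the point estimate is then 0 with essentially no information
    wide_uncertainty: bool = False


@dataclass
class CalibrationTable:
    model_name: str
    n_groups: int
    table: pd.DataFrame  # group, n, cases, expected, observed, recalibrated
    slope: float
    intercept: float
    estimator: str = "km"
    clamped_groups: list[int] = field(default_factory=list)


def quantile_groups(risks, n_groups: int = 10) -> np.ndarray:
    """Assign each record to a quantile group of expected risk.

    Groups are 0..n_groups−1 in increasing risk; tied risk values share the
    lower group.  In the untied case group sizes differ by at most one.
    """
    risks = np.asarray(risks, dtype=float)
    if np.isnan(risks).any():
        raise ConfigurationError("risks must be defined for every record")
    n = len(risks)
    n_distinct = len(np.unique(risks))
    if n_groups < 2:
        raise ConfigurationError("n_groups must be at least 2")
    if n_groups > n:
        raise ConfigurationError(
            f"cannot form {n_groups} groups from {n} usable record(s)"
        )
    if n_distinct == 1:
        raise ConfigurationError(
            "all risks are identical: a single effective group cannot "
            "support quantile calibration"
        )
    # with heavily tied risks (e.g. point scores) ties share the lower
    # group, so fewer than n_groups groups may be non-empty — callers fit
    # the calibration line over the non-empty group points
    order = np.argsort(risks, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    groups = ranks * n_groups // n
    # ties share the lower group
    sorted_risks = risks[order]
    sorted_groups = groups[order]
    for i in range(1, n):
        if sorted_risks[i] == sorted_risks[i - 1]:
            sorted_groups[i] = sorted_groups[i - 1]
    groups[order] = sorted_groups
    return groups


def observed_risk(
    times,
    events,
    horizon: float = 10.0,
    estimator: str = "km",
) -> ObservedRisk:
    """Observed cumulative risk in a group at the horizon.

    ``km``: Kaplan–Meier complement 1 − Ŝ(horizon); ``crude``: event
    proportion.  The two coincide when no one is censored before the
    horizon.
    """
    if estimator not in OBSERVED_ESTIMATORS:
        raise ConfigurationError(
            f"estimator must be one of {OBSERVED_ESTIMATORS}"
        )
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if len(times) == 0:
        raise DegenerateInputError("empty group")
    if estimator == "crude":
        return ObservedRisk(float(events.mean()))
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    surv = float(kmf.predict(horizon))
    exhausted = (times.max() < horizon) and not events.any()
    return ObservedRisk(1.0 - surv, wide_uncertainty=exhausted)


def calibration_line(expected, observed) -> tuple[float, float]:
    """OLS fit of observed on expected risk over group points → (slope, intercept)."""
    x = np.asarray(expected, dtype=float)
    y = np.asarray(observed, dtype=float)
    if len(x) < 2:
        raise DegenerateInputError("calibration line needs at least 2 groups")
    if np.ptp(x) == 0.0:
        raise DegenerateInputError(
            "expected risks have zero variance; slope undefined"
        )
    A = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(slope), float(intercept)


def recalibrate(
    risk_values, slope: float, intercept: float
) -> tuple[np.ndarray, np.ndarray]:
    """Affine recalibration ``r' = slope·r + intercept`` clamped to [0, 1].

    Returns ``(recalibrated, clamped_mask)`` so callers can log clamping.
    """
    r = np.asarray(risk_values, dtype=float)
    out = slope * r + intercept
    clamped = (out < 0.0) | (out > 1.0)
    return np.clip(out, 0.0, 1.0), clamped


def calibration_table(
    model_name: str,
    expected_risks,
    times,
    events,
    *,
    n_groups: int = 10,
    horizon: float = 10.0,
    estimator: str = "km",
) -> CalibrationTable:
    """Full per-model calibration: deciles, observed vs expected, slope,
    intercept, and recalibrated group risks."""
    expected_risks = np.asarray(expected_risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    groups = quantile_groups(expected_risks, n_groups)
    rows = []
    for g in range(n_groups):
        mask = groups == g
        if not mask.any():  # possible under heavy ties
            rows.append((g, 0, 0, float("nan"), float("nan"), False))
            continue
        obs = observed_risk(times[mask], events[mask], horizon, estimator)
        rows.append(
            (
                g,
                int(mask.sum()),
                int(events[mask].sum()),
                float(expected_risks[mask].mean()),
                obs.value,
                obs.wide_uncertainty,
            )
        )
    tab = pd.DataFrame(
        rows,
        columns=["group", "n", "cases", "expected", "observed",
                 "wide_uncertainty"],
    )
    usable = tab["n"] > 0
    slope, intercept = calibration_line(
        tab.loc[usable, "expected"], tab.loc[usable, "observed"]
    )
    recal, clamped = recalibrate(tab["expected"].to_numpy(), slope, intercept)
    tab["recalibrated"] = recal
    return CalibrationTable(
        model_name=model_name,
        n_groups=n_groups,
        table=tab,
        slope=slope,
        intercept=intercept,
        estimator=estimator,
        clamped_groups=tab.loc[clamped, "group"].tolist(),
    )
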