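"""Discrimination statistics: ROC/AUC with DeLong variance, paired DeLong
tests, an age-threshold comparator, Harrell's concordance for censored
time-to-event data, subgroup analyses, and top-fraction screening metrics.

The empirical AUC is the Mann–Whitney statistic — the probability that a
randomly chosen case scores above a randomly chosen control, with ties
credited 0.5.  Its variance and the covariance between two AUCs computed on
the same participants use DeLong's per-observation structural components,
evaluated via midranks so the cost is O(n log n) rather than quadratic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DegenerateInputError

SUBGROUP_SCHEMES = ("sex", "urbanicity", "age_group", "site")

AGE_CUTOFF_DEFAULT = 56.0


@dataclass(frozen=True)
class AUCResult:
    model_name: str
    subgroup: str
    auc: float
    variance: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int
    reason: str | None = None  # set when the stratum is undefined

    @property
    def defined(self) -> bool:
        return self.reason is None


@dataclass(frozen=True)
class TopKMetrics:
    model_name: str
    fraction: float
    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    n_flagged: int
    true_positives: int


@dataclass(frozen=True)
class ComparisonResult:
    model_a: str
    model_b: str
    auc_a: float
    auc_b: float
    auc_difference: float
    z: float
    p_two_sided: float


def _check_binary(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise DegenerateInputError(
            "AUC needs at least one case and one control"
        )
    return labels, ~labels


def delong_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components for one or more score vectors.

    ``scores`` has shape (k, n) or (n,).  Returns ``(aucs, v10, v01)``:
    per-model AUCs, case components (k, m) and control components (k, n−m).
    The AUC is the mean of either component set; the (co)variance matrix of
    the AUC vector is ``cov(v10)/m + cov(v01)/n_ctrl``.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if not np.isfinite(scores).all():
        raise DegenerateInputError("scores must be finite")
    is_case, is_ctrl = _check_binary(labels)
    pos = scores[:, is_case]
    neg = scores[:, is_ctrl]
    m, n_ctrl = pos.shape[1], neg.shape[1]
    v10 = np.empty((scores.shape[0], m))
    v01 = np.empty((scores.shape[0], n_ctrl))
    for i in range(scores.shape[0]):
        tx = stats.rankdata(pos[i], method="average")
        ty = stats.rankdata(neg[i], method="average")
        tz = stats.rankdata(np.concatenate([pos[i], neg[i]]), method="average")
        v10[i] = (tz[:m] - tx) / n_ctrl
        v01[i] = 1.0 - (tz[m:] - ty) / m
    aucs = v10.mean(axis=1)
    return aucs, v10, v01


def _auc_variance(v10: np.ndarray, v01: np.ndarray) -> np.ndarray:
    m, n_ctrl = v10.shape[1], v01.shape[1]
    s10 = np.atleast_2d(np.cov(v10)) if m > 1 else np.zeros((v10.shape[0],) * 2)
    s01 = np.atleast_2d(np.cov(v01)) if n_ctrl > 1 else np.zeros((v01.shape[0],) * 2)
    return s10 / m + s01 / n_ctrl


def empirical_auc(
    scores,
    labels,
    *,
    model_name: str = "",
    subgroup: str = "overall",
    ci_level: float = 0.95,
) -> AUCResult:
    """Mann–Whitney AUC with DeLong variance and a truncated Wald CI."""
    aucs, v10, v01 = delong_components(np.asarray(scores, dtype=float), labels)
    var = float(_auc_variance(v10, v01)[0, 0])
    var = max(var, 0.0)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    half = z * math.sqrt(var)
    return AUCResult(
        model_name=model_name,
        subgroup=subgroup,
        auc=float(aucs[0]),
        variance=var,
        ci_low=max(0.0, float(aucs[0]) - half),
        ci_high=min(1.0, float(aucs[0]) + half),
        n_cases=v10.shape[1],
        n_controls=v01.shape[1],
    )


def delong_paired_test(
    scores_a, scores_b, labels, *, model_a: str = "a", model_b: str = "b"
) -> ComparisonResult:
    """Paired DeLong test for two AUCs computed on identical participants.

    z = (AUC_a − AUC_b) / sqrt(var_a + var_b − 2·cov_ab), two-sided normal
    p-value.  Identical score vectors give z = 0, p = 1 by definition.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise DegenerateInputError("paired scores must cover identical participants")
    aucs, v10, v01 = delong_components(np.stack([a, b]), labels)
    cov = _auc_variance(v10, v01)
    var_diff = float(cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1])
    diff = float(aucs[0] - aucs[1])
    if np.array_equal(a, b) or (abs(diff) < 1e-15 and var_diff <= 0.0):
        z, p = 0.0, 1.0
    elif var_diff <= 0.0:
        raise DegenerateInputError(
            "zero variance of the AUC difference with unequal AUCs"
        )
    else:
        z = diff / math.sqrt(var_diff)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return ComparisonResult(
        model_a=model_a,
        model_b=model_b,
        auc_a=float(aucs[0]),
        auc_b=float(aucs[1]),
        auc_difference=diff,
        z=z,
        p_two_sided=p,
    )


def age_threshold_comparator(
    ages, labels, cutoff: float = AGE_CUTOFF_DEFAULT
) -> AUCResult:
    """AUC of the screening-age indicator ``age ≥ cutoff``.

    For a binary marker the Mann–Whitney AUC equals
    (sensitivity + specificity)/2 exactly.
    """
    ages = np.asarray(ages, dtype=float)
    scores = (ages >= cutoff).astype(float)
    return empirical_auc(
        scores, labels, model_name=f"age_ge_{cutoff:g}", subgroup="overall"
    )


def concordance_cox(times, events, scores) -> float:
    """Harrell's concordance index over usable pairs.

    A pair is usable when the earlier time is an observed event and the
    comparator survives strictly longer; concordant when the event's score
    is higher, with ties in score credited 0.5.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    scores = np.asarray(scores, dtype=float)
    if (times <= 0).any():
        raise DegenerateInputError("times must be positive")
    order = np.argsort(times, kind="stable")
    ts, es, ss = times[order], events[order], scores[order]
    n = len(ts)
    numer = 0.0
    pairs = 0
    for i in np.flatnonzero(es):
        j0 = np.searchsorted(ts, ts[i], side="right")
        if j0 >= n:
            continue
        later = ss[j0:]
        numer += (later < ss[i]).sum() + 0.5 * (later == ss[i]).sum()
        pairs += n - j0
    if pairs == 0:
        raise DegenerateInputError("no usable pairs for concordance")
    return float(numer / pairs)


def topk_metrics(
    scores, labels, fraction: float, *, ids=None, model_name: str = ""
) -> TopKMetrics:
    """Screening metrics for the top-``fraction`` of predicted risk.

    Flags the ⌈fraction·n⌉ highest scores, breaking ties deterministically
    by (score descending, id ascending), then reads sensitivity,
    specificity, PPV and NPV off the 2×2 table.
    """
    if not (0.0 < fraction < 1.0):
        raise ConfigurationError("fraction must lie in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    is_case, _ = _check_binary(labels)
    n = len(scores)
    ids = np.arange(n) if ids is None else np.asarray(ids)
    # np.lexsort sorts by the last key first: score desc, then id asc
    order = np.lexsort((ids, -scores))
    k = math.ceil(fraction * n)
    flagged_idx = order[:k]
    flagged = np.zeros(n, dtype=bool)
    flagged[flagged_idx] = True
    tp = int((flagged & is_case).sum())
    fp = int((flagged & ~is_case).sum())
    fn = int((~flagged & is_case).sum())
    tn = int((~flagged & ~is_case).sum())
    return TopKMetrics(
        model_name=model_name,
        fraction=fraction,
        threshold=float(scores[flagged_idx[-1]]),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        ppv=tp / (tp + fp) if (tp + fp) else float("nan"),
        npv=tn / (tn + fn) if (tn + fn) else float("nan"),
        n_flagged=k,
        true_positives=tp,
    )


def _strata(records: pd.DataFrame, grouping: str,
            age_cutoff: float) -> list[tuple[str, np.ndarray]]:
    if grouping == "sex":
        sex = records["sex"].to_numpy()
        return [("male", sex == "male"), ("female", sex == "female")]
    if grouping == "urbanicity":
        urban = records["urban"].to_numpy().astype(bool)
        return [("urban", urban), ("rural", ~urban)]
    if grouping == "age_group":
        old = records["age"].to_numpy(float) >= age_cutoff
        return [
            (f"age_lt_{age_cutoff:g}", ~old),
            (f"age_ge_{age_cutoff:g}", old),
        ]
    raise ConfigurationError(
        f"unknown grouping {grouping!r}; expected one of "
        f"{('sex', 'urbanicity', 'age_group')} (site strata are handled as "
        f"separate outcome sets)"
    )


def subgroup_discrimination(
    records: pd.DataFrame,
    scores,
    grouping: str,
    labels,
    *,
    model_name: str = "",
    age_cutoff: float = AGE_CUTOFF_DEFAULT,
) -> list[AUCResult]:
    """One AUC per stratum of a grouping scheme.

    Strata without at least one case and one control are reported as
    undefined with a reason rather than raising, so report tables stay
    complete.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    results: list[AUCResult] = []
    for name, mask in _strata(records, grouping, age_cutoff):
        sub = labels[mask]
        if mask.sum() == 0 or sub.all() or not sub.any():
            results.append(
                AUCResult(
                    model_name=model_name,
                    subgroup=name,
                    auc=float("nan"),
                    variance=float("nan"),
                    ci_low=float("nan"),
                    ci_high=float("nan"),
                    n_cases=int(sub.sum()),
                    n_controls=int((~sub).sum()) if mask.sum() else 0,
                    reason="stratum lacks a case and a control",
                )
            )
            continue
        results.append(
            empirical_auc(
                scores[mask], sub, model_name=model_name, subgroup=name
            )
        )
    return results
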