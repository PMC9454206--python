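"""Declarative risk-score engine.

A published colorectal-cancer risk model is represented as a
:class:`ModelSpec` — a declarative description of its type (logistic
regression, Cox proportional hazards, or an integer point score), its
variables with per-level contributions, and, where the source article
published one, a baseline risk (logistic intercept, Cox baseline survival,
or a points-to-risk lookup table).  The engine evaluates a spec against a
cohort table to obtain a linear predictor or point total per participant,
and converts scores to absolute risk over the model's native horizon.

Spec files are YAML, one per model, loaded by :func:`load_model_spec`; the
nine models shipped under ``crcvalid/registry/`` cover the published scores
validated here.  Because the original equations are not reproduced in this
repository, the shipped coefficient values are clearly-marked placeholders
(synthetic, epidemiologically plausible magnitudes) — the engine's
correctness is established on synthetic specs in the test suite and does
not depend on transcription.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    DomainError,
    EvaluationError,
    PointRangeError,
    SchemaError,
    SpecParseError,
    SpecValidationError,
)

MODEL_TYPES = ("logistic", "cox", "points")
VARIABLE_KINDS = ("continuous", "categorical", "binary")
SEXES = ("male", "female", "both")

_MISSING_POLICIES = ("reference_level", "exclude_record", "impute_value")


@dataclass(frozen=True)
class Level:
    """One category of a categorical variable.

    ``when`` is a condition on the source value: ``{"equals": v}``,
    ``{"in": [v, ...]}`` or ``{"range": [lo, hi]}`` (lo inclusive, hi
    exclusive; ``None`` for an open end).  ``contribution`` is a regression
    coefficient term or an integer point count.  Exactly one level per
    variable is the reference, with contribution 0.
    """

    when: Mapping[str, Any]
    contribution: float
    reference: bool = False

    def matches(self, values: np.ndarray) -> np.ndarray:
        if "equals" in self.when:
            return values == self.when["equals"]
        if "in" in self.when:
            return np.isin(values, list(self.when["in"]))
        if "range" in self.when:
            lo, hi = self.when["range"]
            v = values.astype(float)
            mask = np.ones(v.shape, dtype=bool)
            if lo is not None:
                mask &= v >= lo
            if hi is not None:
                mask &= v < hi
            return mask
        raise SpecParseError(f"unknown level condition {dict(self.when)!r}")


@dataclass(frozen=True)
class VariableDef:
    """A model variable and how it maps cohort columns to contributions."""

    name: str
    source_column: str
    kind: str
    coefficient: float = 0.0
    transform: Mapping[str, float] | None = None  # {'scale': a, 'offset': b}
    levels: tuple[Level, ...] = ()
    missing_policy: str = "reference_level"
    impute_value: Any = None

    def validate(self) -> None:
        if self.kind not in VARIABLE_KINDS:
            raise SpecValidationError(
                f"variable {self.name!r}: kind must be one of {VARIABLE_KINDS}, "
                f"got {self.kind!r}"
            )
        if self.missing_policy not in _MISSING_POLICIES:
            raise SpecValidationError(
                f"variable {self.name!r}: unknown missing_policy "
                f"{self.missing_policy!r}"
            )
        if self.missing_policy == "impute_value" and self.impute_value is None:
            raise SpecValidationError(
                f"variable {self.name!r}: impute_value policy requires a value"
            )
        if self.kind == "categorical":
            refs = [lv for lv in self.levels if lv.reference]
            if len(refs) != 1:
                raise SpecValidationError(
                    f"variable {self.name!r}: categorical variables need exactly "
                    f"one reference level, found {len(refs)}"
                )
            if refs[0].contribution != 0:
                raise SpecValidationError(
                    f"variable {self.name!r}: reference level must contribute 0"
                )
            self._check_mutually_exclusive()

    def _check_mutually_exclusive(self) -> None:
        # equals/in levels: no value may appear twice; range levels: no overlap
        seen: set[Any] = set()
        ranges: list[tuple[float, float]] = []
        for lv in self.levels:
            if "equals" in lv.when:
                vals: Iterable[Any] = [lv.when["equals"]]
            elif "in" in lv.when:
                vals = lv.when["in"]
            else:
                lo, hi = lv.when["range"]
                ranges.append(
                    (-math.inf if lo is None else lo, math.inf if hi is None else hi)
                )
                continue
            for v in vals:
                if v in seen:
                    raise SpecValidationError(
                        f"variable {self.name!r}: value {v!r} appears in two levels"
                    )
                seen.add(v)
        ranges.sort()
        for (lo1, hi1), (lo2, _hi2) in zip(ranges, ranges[1:]):
            if lo2 < hi1:
                raise SpecValidationError(
                    f"variable {self.name!r}: overlapping ranges "
                    f"[{lo1}, {hi1}) and starting at {lo2}"
                )


@dataclass(frozen=True)
class RiskStratum:
    """One row of a points-to-absolute-risk lookup table (inclusive bounds)."""

    min_points: float
    max_points: float
    risk: float


@dataclass(frozen=True)
class ModelSpec:
    name: str
    model_type: str
    variables: tuple[VariableDef, ...]
    native_horizon_years: float = 10.0
    applicable_sex: str = "both"
    intercept_or_baseline: float | None = None
    risk_table: tuple[RiskStratum, ...] = ()
    provenance: str = ""

    def validate(self) -> None:
        if self.model_type not in MODEL_TYPES:
            raise SpecValidationError(
                f"model {self.name!r}: model_type must be one of {MODEL_TYPES}"
            )
        if self.applicable_sex not in SEXES:
            raise SpecValidationError(
                f"model {self.name!r}: applicable_sex must be one of {SEXES}"
            )
        if not self.native_horizon_years > 0:
            raise SpecValidationError(
                f"model {self.name!r}: native_horizon_years must be positive"
            )
        if self.model_type == "cox" and self.intercept_or_baseline is not None:
            s0 = self.intercept_or_baseline
            if not (0.0 < s0 < 1.0):
                raise SpecValidationError(
                    f"model {self.name!r}: Cox baseline survival must lie in "
                    f"(0, 1), got {s0}"
                )
        if self.risk_table and self.model_type != "points":
            raise SpecValidationError(
                f"model {self.name!r}: risk_table is only valid for points models"
            )
        for var in self.variables:
            var.validate()
        if self.risk_table:
            self._validate_risk_table()

    def _validate_risk_table(self) -> None:
        strata = sorted(self.risk_table, key=lambda s: s.min_points)
        for s in strata:
            if not (0.0 <= s.risk <= 1.0):
                raise SpecValidationError(
                    f"model {self.name!r}: risk_table risk {s.risk} outside [0, 1]"
                )
            if s.max_points < s.min_points:
                raise SpecValidationError(
                    f"model {self.name!r}: risk_table stratum with "
                    f"max_points < min_points"
                )
        for a, b in zip(strata, strata[1:]):
            if b.min_points <= a.max_points:
                raise SpecValidationError(
                    f"model {self.name!r}: overlapping risk_table strata"
                )
        lo, hi = self.achievable_point_range()
        covered = all(
            any(s.min_points <= p <= s.max_points for s in strata)
            for p in range(int(lo), int(hi) + 1)
        )
        if not covered:
            raise SpecValidationError(
                f"model {self.name!r}: risk_table does not cover the achievable "
                f"point range [{lo}, {hi}]"
            )

    def achievable_point_range(self) -> tuple[float, float]:
        """Min and max point totals attainable under this spec."""
        lo = hi = 0.0
        for var in self.variables:
            if var.kind == "categorical":
                contribs = [lv.contribution for lv in var.levels]
            elif var.kind == "binary":
                contribs = [0.0, var.coefficient]
            else:  # continuous points variables are not used by shipped models
                contribs = [0.0]
            lo += min(contribs)
            hi += max(contribs)
        return lo, hi

    def drop_variable(self, name: str) -> "ModelSpec":
        """Return a copy of the spec without the named variable's term.

        Used by the aspirin sensitivity analysis, which removes the aspirin
        term from the two models containing it and re-evaluates on identical
        records.
        """
        kept = tuple(v for v in self.variables if v.name != name)
        if len(kept) == len(self.variables):
            raise SpecValidationError(
                f"model {self.name!r} has no variable named {name!r}"
            )
        return replace(self, variables=kept)

    @property
    def has_absolute_risk(self) -> bool:
        """Whether the model publishes absolute risks (five shipped models do)."""
        if self.model_type == "points":
            return bool(self.risk_table)
        return self.intercept_or_baseline is not None


@dataclass(frozen=True)
class ScoreResult:
    """Per-record outcome of evaluating one model."""

    model_name: str
    linear_predictor_or_points: float
    absolute_risk_10y: float | None
    excluded: bool = False
    exclusion_reason: str | None = None


# ---------------------------------------------------------------------------
# loading


def _parse_level(raw: Mapping[str, Any], varname: str) -> Level:
    if "when" not in raw or "contribution" not in raw:
        raise SpecParseError(
            f"variable {varname!r}: each level needs 'when' and 'contribution'"
        )
    return Level(
        when=dict(raw["when"]),
        contribution=float(raw["contribution"]),
        reference=bool(raw.get("reference", False)),
    )


def _parse_variable(raw: Mapping[str, Any]) -> VariableDef:
    for key in ("name", "source_column", "kind"):
        if key not in raw:
            raise SpecParseError(f"variable definition missing field {key!r}")
    policy = raw.get("missing_policy", "reference_level")
    impute = None
    if isinstance(policy, Mapping):
        if "impute_value" not in policy:
            raise SpecParseError(
                f"variable {raw['name']!r}: unknown missing_policy {policy!r}"
            )
        impute = policy["impute_value"]
        policy = "impute_value"
    levels = tuple(_parse_level(lv, raw["name"]) for lv in raw.get("levels", ()))
    return VariableDef(
        name=str(raw["name"]),
        source_column=str(raw["source_column"]),
        kind=str(raw["kind"]),
        coefficient=float(raw.get("coefficient", 0.0)),
        transform=dict(raw["transform"]) if raw.get("transform") else None,
        levels=levels,
        missing_policy=policy,
        impute_value=impute,
    )


def parse_model_spec(raw: Mapping[str, Any]) -> ModelSpec:
    """Build and validate a :class:`ModelSpec` from a parsed mapping."""
    for key in ("name", "model_type", "variables"):
        if key not in raw:
            raise SpecParseError(f"model spec missing field {key!r}")
    table = tuple(
        RiskStratum(
            min_points=float(s["min_points"]),
            max_points=float(s["max_points"]),
            risk=float(s["risk"]),
        )
        for s in raw.get("risk_table") or ()
    )
    ib = raw.get("intercept_or_baseline")
    spec = ModelSpec(
        name=str(raw["name"]),
        model_type=str(raw["model_type"]),
        variables=tuple(_parse_variable(v) for v in raw["variables"]),
        native_horizon_years=float(raw.get("native_horizon_years", 10.0)),
        applicable_sex=str(raw.get("applicable_sex", "both")),
        intercept_or_baseline=None if ib is None else float(ib),
        risk_table=table,
        provenance=str(raw.get("provenance", "")),
    )
    spec.validate()
    return spec


def load_model_spec(path: str | Path) -> ModelSpec:
    """Load one model-spec YAML file, validating all structural invariants."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise SpecParseError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise SpecParseError(f"{path}: expected a mapping at top level")
    try:
        return parse_model_spec(raw)
    except (SpecParseError, SpecValidationError) as exc:
        raise type(exc)(f"{path}: {exc}") from exc


def load_registry(directory: str | Path | None = None) -> dict[str, ModelSpec]:
    """Load every ``*.yaml`` spec in a directory (default: shipped registry)."""
    if directory is None:
        directory = resources.files("crcvalid") / "registry"
    directory = Path(str(directory))
    specs: dict[str, ModelSpec] = {}
    for path in sorted(directory.glob("*.yaml")):
        spec = load_model_spec(path)
        if spec.name in specs:
            raise SpecValidationError(f"duplicate model name {spec.name!r}")
        specs[spec.name] = spec
    return specs


# ---------------------------------------------------------------------------
# evaluation


def _is_missing(values: np.ndarray) -> np.ndarray:
    if values.dtype.kind in "fc":
        return np.isnan(values)
    if values.dtype.kind == "O":
        return pd.isna(values) | (values == "")
    return np.zeros(values.shape, dtype=bool)


def _variable_contributions(
    var: VariableDef, column: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Contribution of one variable for every record.

    Returns ``(contribution, exclude_mask)``; excluded records carry a
    contribution of 0 and are flagged by the caller.
    """
    n = column.shape[0]
    missing = _is_missing(column)
    exclude = np.zeros(n, dtype=bool)
    values = column.copy()
    if var.missing_policy == "impute_value":
        values = np.where(missing, var.impute_value, values)
        missing = np.zeros(n, dtype=bool)
    elif var.missing_policy == "exclude_record":
        exclude = missing

    contrib = np.zeros(n, dtype=float)
    usable = ~missing & ~exclude
    if var.kind == "continuous":
        x = pd.to_numeric(pd.Series(values), errors="coerce").to_numpy(float)
        bad = usable & np.isnan(x)
        if bad.any():
            raise EvaluationError(
                f"variable {var.name!r}: non-numeric value in column "
                f"{var.source_column!r}"
            )
        scale = offset = None
        if var.transform:
            scale = float(var.transform.get("scale", 1.0))
            offset = float(var.transform.get("offset", 0.0))
            x = scale * x + offset
        contrib[usable] = var.coefficient * x[usable]
    elif var.kind == "binary":
        x = pd.to_numeric(pd.Series(values), errors="coerce").to_numpy(float)
        if (usable & np.isnan(x)).any():
            raise EvaluationError(
                f"variable {var.name!r}: non-numeric value in binary column "
                f"{var.source_column!r}"
            )
        contrib[usable] = var.coefficient * (x[usable] != 0)
    else:  # categorical
        matched = np.zeros(n, dtype=bool)
        for lv in var.levels:
            with np.errstate(invalid="ignore"):
                mask = usable & ~matched & lv.matches(values)
            contrib[mask] = lv.contribution
            matched |= mask
        unmatched = usable & ~matched
        if unmatched.any():
            offending = pd.unique(pd.Series(values[unmatched]))[:5]
            raise EvaluationError(
                f"variable {var.name!r}: values {list(offending)!r} match no "
                f"declared level of column {var.source_column!r}"
            )
    # reference_level policy: missing contributes 0, which is already the case
    return contrib, exclude


def evaluate_cohort(
    spec: ModelSpec,
    cohort: pd.DataFrame,
    *,
    enforce_sex: bool = True,
    drop_variables: Sequence[str] = (),
) -> pd.DataFrame:
    """Vectorised evaluation of one model over a cohort table.

    Returns a frame indexed like ``cohort`` with columns ``score`` (linear
    predictor incl. intercept for logistic models, or point total),
    ``risk_native``, ``risk_10y``, ``excluded`` and ``exclusion_reason``.
    Missing inputs are handled per each variable's declared policy; records
    whose sex falls outside ``applicable_sex`` are flagged excluded when
    ``enforce_sex`` (the pipeline relaxes this, evaluating sex-restricted
    models in both sexes as the validation design requires).
    """
    variables = [v for v in spec.variables if v.name not in set(drop_variables)]
    for var in variables:
        if var.source_column not in cohort.columns:
            raise SchemaError(
                f"model {spec.name!r}: column {var.source_column!r} absent "
                f"from cohort schema"
            )
    n = len(cohort)
    score = np.zeros(n, dtype=float)
    if spec.model_type == "logistic" and spec.intercept_or_baseline is not None:
        score += spec.intercept_or_baseline
    excluded = np.zeros(n, dtype=bool)
    reason = np.full(n, None, dtype=object)

    for var in variables:
        contrib, excl = _variable_contributions(
            var, cohort[var.source_column].to_numpy()
        )
        newly = excl & ~excluded
        reason[newly] = f"missing {var.name}"
        excluded |= excl
        score += np.where(excl, 0.0, contrib)

    if enforce_sex and spec.applicable_sex in ("male", "female"):
        if "sex" not in cohort.columns:
            raise SchemaError("cohort schema lacks a 'sex' column")
        off = (cohort["sex"].to_numpy() != spec.applicable_sex) & ~excluded
        reason[off] = f"sex outside applicable_sex={spec.applicable_sex}"
        excluded |= off

    score[excluded] = np.nan
    risk_native = risk_vector_from_scores(spec, score)
    if risk_native is None:
        risk_10y = np.full(n, np.nan)
        risk_native_arr = np.full(n, np.nan)
    else:
        risk_native_arr = risk_native
        risk_10y = convert_horizon(
            risk_native_arr, spec.native_horizon_years, 10.0
        )
    return pd.DataFrame(
        {
            "score": score,
            "risk_native": risk_native_arr,
            "risk_10y": risk_10y,
            "excluded": excluded,
            "exclusion_reason": reason,
        },
        index=cohort.index,
    )


def evaluate(spec: ModelSpec, record: Mapping[str, Any]) -> ScoreResult:
    """Evaluate one model on a single participant record."""
    df = pd.DataFrame([dict(record)])
    out = evaluate_cohort(spec, df).iloc[0]
    risk = out["risk_10y"]
    return ScoreResult(
        model_name=spec.name,
        linear_predictor_or_points=float(out["score"]),
        absolute_risk_10y=None if pd.isna(risk) else float(risk),
        excluded=bool(out["excluded"]),
        exclusion_reason=out["exclusion_reason"],
    )


def risk_vector_from_scores(
    spec: ModelSpec, scores: np.ndarray
) -> np.ndarray | None:
    """Absolute risk at the native horizon for an array of scores.

    Returns ``None`` when the model publishes no absolute risk (points model
    without a risk table, or regression model without intercept/baseline —
    chen, betes, aleksandrova and ma_cox in the shipped registry).
    """
    if not spec.has_absolute_risk:
        return None
    scores = np.asarray(scores, dtype=float)
    with np.errstate(over="ignore"):
        if spec.model_type == "logistic":
            return 1.0 / (1.0 + np.exp(-scores))
        if spec.model_type == "cox":
            s0 = spec.intercept_or_baseline
            return 1.0 - np.power(s0, np.exp(scores))
    # points lookup
    out = np.full(scores.shape, np.nan)
    unresolved = ~np.isnan(scores)
    for stratum in spec.risk_table:
        mask = (
            unresolved
            & (scores >= stratum.min_points)
            & (scores <= stratum.max_points)
        )
        out[mask] = stratum.risk
        unresolved &= ~mask
    if unresolved.any():
        bad = np.unique(scores[unresolved])[:5]
        raise PointRangeError(
            f"model {spec.name!r}: point totals {bad.tolist()} outside "
            f"risk_table coverage"
        )
    return out


def risk_from_score(spec: ModelSpec, score: float) -> float | None:
    """Absolute risk at the model's native horizon for a single score.

    logistic → inverse logit of the score; cox → ``1 − S0**exp(score)``;
    points → risk-table lookup (``None`` when the model publishes no table).
    """
    risks = risk_vector_from_scores(spec, np.asarray([score], dtype=float))
    if risks is None:
        return None
    return float(risks[0])


def convert_horizon(
    risk: float | np.ndarray, from_years: float, to_years: float
) -> float | np.ndarray:
    """Rescale a cumulative risk between horizons assuming constant hazard.

    Under an exponential event-time distribution a cumulative risk ``r`` over
    ``t1`` years corresponds to hazard ``−ln(1−r)/t1``, hence the risk over
    ``t2`` years is ``1 − (1−r)**(t2/t1)``.  Used to convert the driver
    model's native 20-year risk to the 10-year scale of the analysis.
    """
    if from_years <= 0 or to_years <= 0:
        raise DomainError("horizons must be positive")
    r = np.asarray(risk, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (r < 0) | (r > 1)
    if bad.any():
        raise DomainError("risk must lie in [0, 1]")
    out = 1.0 - np.power(1.0 - r, to_years / from_years)
    if np.isscalar(risk) or np.ndim(risk) == 0:
        return float(out)
    return out
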