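"""End-to-end validation pipeline.

Given a cohort table and a model registry, the pipeline applies the
exclusion rules, scores every model on every participant, and computes:
overall and subgroup discrimination for each outcome composite, paired
DeLong contrasts against the age-threshold comparator, top-fraction
screening metrics, calibration and recalibration for the models that
publish absolute risks, plus two sensitivity analyses (Cox C-statistic,
and removal of the aspirin term from the models that contain it).

Sex-restricted models are evaluated in both sexes — the validation design
assesses every model separately in males and females even when it was
developed in males only — so ``applicable_sex`` gates a warning at this
level, not an exclusion.  A model whose required column is absent from the
cohort is reported as undefined with a reason; other models are unaffected.
All outputs are deterministic given (cohort, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import CalibrationTable, calibration_table
from .discrimination import (
    AGE_CUTOFF_DEFAULT,
    concordance_cox,
    delong_paired_test,
    empirical_auc,
    subgroup_discrimination,
    topk_metrics,
)
from .errors import ConfigurationError, SchemaError
from .followup import OUTCOME_SETS, apply_exclusions, build_followup
from .registry import ModelSpec, evaluate_cohort, load_registry
from .schema import read_cohort

logger = logging.getLogger("crcvalid.pipeline")

ASPIRIN_POLICIES = ("impute_nonuse", "drop_term")
_FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    cohort_path: str | None = None
    registry_dir: str | None = None  # None -> shipped registry
    outcome_sets: tuple[str, ...] = OUTCOME_SETS
    subgroups: tuple[str, ...] = ("sex", "urbanicity", "age_group")
    top_fractions: tuple[float, ...] = (0.10, 0.25)
    calibration_groups: int = 10
    age_cutoff: float = AGE_CUTOFF_DEFAULT
    aspirin_policy: str = "impute_nonuse"
    observed_estimator: str = "km"
    seed: int = 0
    output_dir: str | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        for f in self.top_fractions:
            if not (0.0 < f < 1.0):
                raise ConfigurationError(f"top fraction {f} outside (0, 1)")
        if not (30.0 <= self.age_cutoff <= 79.0):
            raise ConfigurationError("age cutoff must lie within [30, 79]")
        if self.aspirin_policy not in ASPIRIN_POLICIES:
            raise ConfigurationError(
                f"aspirin_policy must be one of {ASPIRIN_POLICIES}"
            )
        unknown = set(self.outcome_sets) - set(OUTCOME_SETS)
        if unknown:
            raise ConfigurationError(f"unknown outcome sets {sorted(unknown)}")
        if self.calibration_groups < 2:
            raise ConfigurationError("calibration_groups must be >= 2")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ValidationReport:
    auc_overall: pd.DataFrame
    auc_subgroups: pd.DataFrame
    delong_vs_age: pd.DataFrame
    topk: pd.DataFrame
    calibration: dict[str, CalibrationTable]
    cstat: pd.DataFrame
    sensitivity_aspirin: pd.DataFrame
    exclusion_log: pd.DataFrame
    provenance: dict


def _aspirin_drops(spec: ModelSpec, policy: str) -> tuple[str, ...]:
    if policy != "drop_term":
        return ()
    has = any(v.name == "aspirin" for v in spec.variables)
    return ("aspirin",) if has else ()


def _score_models(
    specs: dict[str, ModelSpec], cohort: pd.DataFrame, policy: str
) -> tuple[dict[str, pd.DataFrame], dict[str, str]]:
    """Evaluate every model; return per-model score frames and failures."""
    scored: dict[str, pd.DataFrame] = {}
    failed: dict[str, str] = {}
    for name, spec in specs.items():
        if spec.applicable_sex != "both":
            logger.warning(
                "model %s was developed in %s participants only; evaluating "
                "in both sexes per the validation design",
                name, spec.applicable_sex,
            )
        try:
            scored[name] = evaluate_cohort(
                spec,
                cohort,
                enforce_sex=False,
                drop_variables=_aspirin_drops(spec, policy),
            )
        except SchemaError as exc:
            failed[name] = str(exc)
            logger.warning("model %s undefined: %s", name, exc)
    return scored, failed


def _undefined_auc_row(model: str, outcome: str, scheme: str, stratum: str,
                       reason: str) -> dict:
    return {
        "model": model, "outcome_set": outcome, "scheme": scheme,
        "stratum": stratum, "auc": np.nan, "variance": np.nan,
        "ci_low": np.nan, "ci_high": np.nan, "n_cases": 0, "n_controls": 0,
        "reason": reason,
    }


def run_validation(
    config: RunConfig, cohort: pd.DataFrame | None = None
) -> ValidationReport:
    """Run the full external-validation analysis; see module docstring."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    if cohort is None:
        if config.cohort_path is None:
            raise ConfigurationError("either a cohort frame or cohort_path is required")
        cohort = read_cohort(config.cohort_path)
    n_loaded = len(cohort)
    cohort, excl_log = apply_exclusions(cohort)
    logger.info(
        "loaded %d records; %d retained after exclusions", n_loaded, len(cohort)
    )
    cohort = cohort.reset_index(drop=True)

    specs = load_registry(config.registry_dir)
    scored, failed = _score_models(specs, cohort, config.aspirin_policy)
    model_names = sorted(specs)

    followups = {
        s: build_followup(cohort, s) for s in config.outcome_sets
    }
    labels = {s: fu["event"].to_numpy() for s, fu in followups.items()}
    age_scores = (
        cohort["age"].to_numpy(float) >= config.age_cutoff
    ).astype(float)
    ids = cohort["id"].to_numpy()

    # ---- overall + subgroup discrimination --------------------------------
    overall_rows, subgroup_rows, delong_rows = [], [], []
    for outcome in config.outcome_sets:
        y = labels[outcome]
        for model in model_names:
            if model in failed:
                overall_rows.append(
                    _undefined_auc_row(model, outcome, "overall", "overall",
                                       failed[model])
                )
                for scheme in config.subgroups:
                    for _, stratum in _scheme_strata(cohort, scheme,
                                                     config.age_cutoff):
                        subgroup_rows.append(
                            _undefined_auc_row(model, outcome, scheme,
                                               stratum, failed[model])
                        )
                delong_rows.append(
                    {"model": model, "outcome_set": outcome,
                     "auc_model": np.nan, "auc_age": np.nan,
                     "auc_difference": np.nan, "z": np.nan,
                     "p_two_sided": np.nan, "p_bonferroni": np.nan,
                     "reason": failed[model]}
                )
                continue
            frame = scored[model]
            usable = ~frame["excluded"].to_numpy()
            s = frame["score"].to_numpy()
            res = empirical_auc(s[usable], y[usable], model_name=model)
            overall_rows.append(
                {"model": model, "outcome_set": outcome, "scheme": "overall",
                 "stratum": "overall", "auc": res.auc,
                 "variance": res.variance, "ci_low": res.ci_low,
                 "ci_high": res.ci_high, "n_cases": res.n_cases,
                 "n_controls": res.n_controls, "reason": None}
            )
            for scheme in config.subgroups:
                for r in subgroup_discrimination(
                    cohort[usable], s[usable], scheme, y[usable],
                    model_name=model, age_cutoff=config.age_cutoff,
                ):
                    subgroup_rows.append(
                        {"model": model, "outcome_set": outcome,
                         "scheme": scheme, "stratum": r.subgroup,
                         "auc": r.auc, "variance": r.variance,
                         "ci_low": r.ci_low, "ci_high": r.ci_high,
                         "n_cases": r.n_cases, "n_controls": r.n_controls,
                         "reason": r.reason}
                    )
            cmp = delong_paired_test(
                s[usable], age_scores[usable], y[usable],
                model_a=model, model_b="age_threshold",
            )
            delong_rows.append(
                {"model": model, "outcome_set": outcome,
                 "auc_model": cmp.auc_a, "auc_age": cmp.auc_b,
                 "auc_difference": cmp.auc_difference, "z": cmp.z,
                 "p_two_sided": cmp.p_two_sided,
                 "p_bonferroni": min(1.0, cmp.p_two_sided * len(model_names)),
                 "reason": None}
            )

    # ---- top-fraction screening metrics (primary outcome, overall) --------
    primary = config.outcome_sets[0]
    y = labels[primary]
    topk_rows = []
    for model in model_names:
        for frac in config.top_fractions:
            if model in failed:
                topk_rows.append(
                    {"model": model, "fraction": frac, "threshold": np.nan,
                     "sensitivity": np.nan, "specificity": np.nan,
                     "ppv": np.nan, "npv": np.nan, "n_flagged": 0,
                     "reason": failed[model]}
                )
                continue
            frame = scored[model]
            usable = ~frame["excluded"].to_numpy()
            m = topk_metrics(
                frame["score"].to_numpy()[usable], y[usable], frac,
                ids=ids[usable], model_name=model,
            )
            topk_rows.append(
                {"model": model, "fraction": frac, "threshold": m.threshold,
                 "sensitivity": m.sensitivity, "specificity": m.specificity,
                 "ppv": m.ppv, "npv": m.npv, "n_flagged": m.n_flagged,
                 "reason": None}
            )

    # ---- calibration (absolute-risk models only, primary outcome) ---------
    fu = followups[primary]
    calibration: dict[str, CalibrationTable] = {}
    for model in model_names:
        if model in failed or not specs[model].has_absolute_risk:
            continue
        frame = scored[model]
        usable = (~frame["excluded"] & frame["risk_10y"].notna()).to_numpy()
        calibration[model] = calibration_table(
            model,
            frame["risk_10y"].to_numpy()[usable],
            fu["time_years"].to_numpy()[usable],
            fu["event"].to_numpy()[usable],
            n_groups=config.calibration_groups,
            estimator=config.observed_estimator,
        )

    # ---- Cox C-statistic sensitivity analysis -----------------------------
    cstat_rows = []
    times = fu["time_years"].to_numpy()
    events = fu["event"].to_numpy()
    for model in model_names + ["age_threshold"]:
        if model in failed:
            cstat_rows.append({"model": model, "c_index": np.nan,
                               "reason": failed[model]})
            continue
        if model == "age_threshold":
            s, usable = age_scores, np.ones(len(cohort), dtype=bool)
        else:
            frame = scored[model]
            usable = ~frame["excluded"].to_numpy()
            s = frame["score"].to_numpy()
        cstat_rows.append(
            {"model": model,
             "c_index": concordance_cox(times[usable], events[usable],
                                        s[usable]),
             "reason": None}
        )

    # ---- aspirin sensitivity analysis -------------------------------------
    aspirin_rows = aspirin_sensitivity(
        config, cohort=cohort, specs=specs, labels=y,
    )

    provenance = {
        "package_version": __version__,
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_loaded": int(n_loaded),
        "n_analysed": int(len(cohort)),
        "models": model_names,
        "models_undefined": sorted(failed),
    }
    return ValidationReport(
        auc_overall=pd.DataFrame(overall_rows),
        auc_subgroups=pd.DataFrame(subgroup_rows),
        delong_vs_age=pd.DataFrame(delong_rows),
        topk=pd.DataFrame(topk_rows),
        calibration=calibration,
        cstat=pd.DataFrame(cstat_rows),
        sensitivity_aspirin=aspirin_rows,
        exclusion_log=excl_log.to_frame(),
        provenance=provenance,
    )


def _scheme_strata(cohort, scheme, age_cutoff):
    if scheme == "sex":
        return [(scheme, "male"), (scheme, "female")]
    if scheme == "urbanicity":
        return [(scheme, "urban"), (scheme, "rural")]
    if scheme == "age_group":
        return [(scheme, f"age_lt_{age_cutoff:g}"),
                (scheme, f"age_ge_{age_cutoff:g}")]
    raise ConfigurationError(f"unknown subgroup scheme {scheme!r}")


def aspirin_sensitivity(
    config: RunConfig,
    cohort: pd.DataFrame,
    specs: dict[str, ModelSpec] | None = None,
    labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """AUC of the aspirin-containing models with and without the aspirin
    term, on identical records, with a paired DeLong contrast.

    The aspirin variable is observed only in the coronary-heart-disease
    subgroup; the default evaluation imputes non-use elsewhere, and this
    analysis quantifies how much the partially-observed term contributes.
    """
    if specs is None:
        specs = load_registry(config.registry_dir)
    if labels is None:
        cohort, _ = apply_exclusions(cohort)
        cohort = cohort.reset_index(drop=True)
        labels = build_followup(cohort, config.outcome_sets[0])["event"].to_numpy()
    rows = []
    for name in sorted(specs):
        spec = specs[name]
        if not any(v.name == "aspirin" for v in spec.variables):
            continue
        try:
            with_asp = evaluate_cohort(spec, cohort, enforce_sex=False)
            without = evaluate_cohort(
                spec, cohort, enforce_sex=False, drop_variables=("aspirin",)
            )
        except SchemaError as exc:
            rows.append({"model": name, "auc_with": np.nan,
                         "auc_without": np.nan, "auc_difference": np.nan,
                         "z": np.nan, "p_two_sided": np.nan,
                         "reason": str(exc)})
            continue
        usable = (~with_asp["excluded"] & ~without["excluded"]).to_numpy()
        cmp = delong_paired_test(
            with_asp["score"].to_numpy()[usable],
            without["score"].to_numpy()[usable],
            labels[usable],
            model_a=f"{name}_with_aspirin",
            model_b=f"{name}_without_aspirin",
        )
        rows.append(
            {"model": name, "auc_with": cmp.auc_a, "auc_without": cmp.auc_b,
             "auc_difference": cmp.auc_difference, "z": cmp.z,
             "p_two_sided": cmp.p_two_sided, "reason": None}
        )
    return pd.DataFrame(
        rows,
        columns=["model", "auc_with", "auc_without", "auc_difference", "z",
                 "p_two_sided", "reason"],
    )


def write_report(report: ValidationReport, output_dir: str | Path) -> None:
    """Emit the report as delimited tables plus a run manifest.

    Byte-identical across runs with the same inputs: fixed float format,
    sorted rows where construction order is not already deterministic, and
    a manifest with no timestamps.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {
        "auc_overall": report.auc_overall,
        "auc_subgroups": report.auc_subgroups,
        "delong_vs_age": report.delong_vs_age,
        "topk": report.topk,
        "cstat": report.cstat,
        "sensitivity_aspirin": report.sensitivity_aspirin,
        "exclusions": report.exclusion_log,
    }
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False, float_format=_FLOAT_FMT)
    for model, cal in sorted(report.calibration.items()):
        tab = cal.table.copy()
        tab.insert(0, "model", model)
        tab.to_csv(outdir / f"calibration_{model}.csv", index=False,
                   float_format=_FLOAT_FMT)
    manifest = dict(report.provenance)
    manifest["tables"] = {k: int(len(v)) for k, v in tables.items()}
    manifest["calibration_models"] = sorted(report.calibration)
    manifest["calibration_slopes"] = {
        m: round(c.slope, 10) for m, c in sorted(report.calibration.items())
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
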