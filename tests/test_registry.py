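"""Risk-score engine: spec loading, validation, evaluation, risk mapping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crcvalid.errors import (
    DomainError,
    PointRangeError,
    SchemaError,
    SpecValidationError,
)
from crcvalid.registry import (
    convert_horizon,
    evaluate,
    evaluate_cohort,
    load_registry,
    parse_model_spec,
    risk_from_score,
)
from conftest import make_cohort_rows


class TestLoading:
    def test_shipped_registry_has_nine_distinct_models(self):
        specs = load_registry()
        assert len(specs) == 9
        assert sorted(specs) == [
            "aleksandrova", "betes", "chen", "driver", "guo", "hong",
            "imperiale", "ma_cox", "ma_point",
        ]

    def test_five_shipped_models_publish_absolute_risk(self):
        specs = load_registry()
        with_risk = sorted(n for n, s in specs.items() if s.has_absolute_risk)
        assert with_risk == ["driver", "guo", "hong", "imperiale", "ma_point"]

    def test_cox_baseline_survival_outside_unit_interval_rejected(self):
        raw = {
            "name": "bad", "model_type": "cox",
            "intercept_or_baseline": 1.2,
            "variables": [{"name": "age", "source_column": "age",
                           "kind": "continuous", "coefficient": 0.1}],
        }
        with pytest.raises(SpecValidationError, match="baseline survival"):
            parse_model_spec(raw)

    def test_categorical_without_reference_level_rejected(self):
        raw = {
            "name": "bad", "model_type": "logistic",
            "intercept_or_baseline": 0.0,
            "variables": [{
                "name": "smoking", "source_column": "smoking_status",
                "kind": "categorical",
                "levels": [
                    {"when": {"equals": "never"}, "contribution": 0.1},
                    {"when": {"equals": "current"}, "contribution": 0.5},
                ],
            }],
        }
        with pytest.raises(SpecValidationError, match="reference"):
            parse_model_spec(raw)

    def test_overlapping_risk_table_strata_rejected(self, toy_points_spec):
        raw = {
            "name": "bad", "model_type": "points",
            "variables": [{"name": "diabetes", "source_column": "diabetes",
                           "kind": "binary", "coefficient": 1}],
            "risk_table": [
                {"min_points": 0, "max_points": 1, "risk": 0.01},
                {"min_points": 1, "max_points": 2, "risk": 0.02},
            ],
        }
        with pytest.raises(SpecValidationError, match="overlapping"):
            parse_model_spec(raw)

    def test_shipped_points_models_cover_achievable_range(self):
        # every achievable integer point total maps into a risk stratum
        specs = load_registry()
        for name in ("ma_point", "guo"):
            spec = specs[name]
            lo, hi = spec.achievable_point_range()
            for total in range(int(lo), int(hi) + 1):
                assert risk_from_score(spec, float(total)) is not None


class TestEvaluate:
    def test_all_reference_levels_yields_intercept(self, toy_logistic_spec):
        rec = make_cohort_rows(
            [{"age": 50.0, "smoking_status": "never"}]
        ).iloc[0]
        res = evaluate(toy_logistic_spec, rec)
        assert res.linear_predictor_or_points == pytest.approx(-2.0)
        assert not res.excluded

    def test_points_sum_matches_hand_total(self, toy_points_spec):
        # age 55 -> 1... choose levels scoring 2, 0, 3 -> total 5
        rec = make_cohort_rows(
            [{"age": 70.0, "diabetes": 0, "smoking_status": "current"}]
        ).iloc[0]
        res = evaluate(toy_points_spec, rec)
        assert res.linear_predictor_or_points == pytest.approx(5.0)
        assert res.absolute_risk_10y == pytest.approx(0.012)

    def test_male_only_model_excludes_female_record(self):
        guo = load_registry()["guo"]
        rec = make_cohort_rows([{"sex": "female"}]).iloc[0]
        res = evaluate(guo, rec)
        assert res.excluded
        assert "sex" in res.exclusion_reason

    def test_pipeline_relaxation_scores_female_records(self):
        guo = load_registry()["guo"]
        df = make_cohort_rows([{"sex": "female"}])
        out = evaluate_cohort(guo, df, enforce_sex=False)
        assert not out["excluded"].iloc[0]
        assert np.isfinite(out["score"].iloc[0])

    def test_missing_input_policies(self, toy_logistic_spec):
        df = make_cohort_rows([{"age": np.nan}])
        out = evaluate_cohort(toy_logistic_spec, df)  # age: exclude_record
        assert out["excluded"].iloc[0]
        assert "missing age" in out["exclusion_reason"].iloc[0]
        # reference_level policy: missing smoking contributes 0
        df2 = make_cohort_rows([{"smoking_status": None}])
        out2 = evaluate_cohort(toy_logistic_spec, df2)
        assert out2["score"].iloc[0] == pytest.approx(-2.0)

    def test_absent_source_column_raises_schema_error(self, toy_logistic_spec):
        df = make_cohort_rows([{}]).drop(columns=["smoking_status"])
        with pytest.raises(SchemaError, match="smoking_status"):
            evaluate_cohort(toy_logistic_spec, df)

    def test_evaluation_invariant_to_variable_order(self, toy_logistic_spec):
        import dataclasses

        df = make_cohort_rows(
            [{"age": a, "smoking_status": s}
             for a in (35.0, 50.0, 71.0)
             for s in ("never", "ex_regular", "current")]
        )
        reversed_spec = dataclasses.replace(
            toy_logistic_spec, variables=toy_logistic_spec.variables[::-1]
        )
        a = evaluate_cohort(toy_logistic_spec, df)["score"]
        b = evaluate_cohort(reversed_spec, df)["score"]
        assert np.allclose(a, b)

    def test_drop_variable_removes_exactly_that_term(self):
        hong = load_registry()["hong"]
        df = make_cohort_rows(
            [{"chd_history": 1, "aspirin_use": 1.0},
             {"chd_history": 1, "aspirin_use": 0.0}]
        )
        full = evaluate_cohort(hong, df)["score"]
        dropped = evaluate_cohort(hong, df, drop_variables=("aspirin",))["score"]
        # aspirin user loses its -0.25 contribution; non-user unchanged
        assert dropped.iloc[0] - full.iloc[0] == pytest.approx(0.25)
        assert dropped.iloc[1] == pytest.approx(full.iloc[1])


class TestRiskFromScore:
    def test_logistic_inverse_link_at_zero(self, toy_logistic_spec):
        assert risk_from_score(toy_logistic_spec, 0.0) == pytest.approx(0.5)

    def test_cox_baseline_and_closed_form(self):
        spec = parse_model_spec({
            "name": "cox", "model_type": "cox",
            "intercept_or_baseline": 0.99,
            "variables": [{"name": "x", "source_column": "age",
                           "kind": "continuous", "coefficient": 1.0}],
        })
        assert risk_from_score(spec, 0.0) == pytest.approx(0.01)
        assert risk_from_score(spec, math.log(2)) == pytest.approx(
            1 - 0.99**2, abs=1e-12
        )

    def test_points_outside_table_coverage_raises(self, toy_points_spec):
        with pytest.raises(PointRangeError):
            risk_from_score(toy_points_spec, 99.0)

    def test_no_risk_table_gives_undefined_risk(self):
        ma_cox = load_registry()["ma_cox"]
        assert risk_from_score(ma_cox, 1.0) is None

    @pytest.mark.parametrize("model_type", ["logistic", "cox"])
    def test_risk_strictly_increasing_in_score(self, model_type):
        spec = parse_model_spec({
            "name": "m", "model_type": model_type,
            "intercept_or_baseline": 0.99 if model_type == "cox" else 0.0,
            "variables": [{"name": "x", "source_column": "age",
                           "kind": "continuous", "coefficient": 1.0}],
        })
        # grid kept away from float saturation of the risk near 0 and 1
        grid = np.linspace(-4, 4, 101)
        risks = [risk_from_score(spec, s) for s in grid]
        assert all(b > a for a, b in zip(risks, risks[1:]))


class TestConvertHorizon:
    def test_boundaries_and_identity(self):
        assert convert_horizon(0.0, 20, 10) == 0.0
        assert convert_horizon(0.37, 10, 10) == pytest.approx(0.37, abs=1e-15)

    def test_twenty_to_ten_year_closed_form(self):
        # hazard algebra cross-check: h = -ln(0.8)/20, r10 = 1 - e^{-10h}
        h = -math.log(0.8) / 20.0
        assert convert_horizon(0.2, 20, 10) == pytest.approx(
            1 - math.exp(-10 * h), abs=1e-15
        )
        assert convert_horizon(0.2, 20, 10) == pytest.approx(
            1 - 0.8**0.5, abs=1e-15
        )

    def test_rejects_out_of_range_risk(self):
        with pytest.raises(DomainError):
            convert_horizon(1.2, 20, 10)
        with pytest.raises(DomainError):
            convert_horizon(0.5, -1, 10)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=0.999999))
    def test_round_trip_identity(self, r):
        assert convert_horizon(
            convert_horizon(r, 20, 10), 10, 20
        ) == pytest.approx(r, abs=1e-12)
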