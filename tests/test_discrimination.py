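"""AUC, DeLong, concordance, top-fraction metrics, subgroup analyses.

Checked against independent oracles: exhaustive pair enumeration for AUC
and concordance, the (sens+spec)/2 closed form for binary markers, a
paired-bootstrap p-value for the DeLong test, and scikit-learn /
lifelines as external cross-checks.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crcvalid.discrimination import (
    age_threshold_comparator,
    concordance_cox,
    delong_paired_test,
    empirical_auc,
    subgroup_discrimination,
    topk_metrics,
)
from crcvalid.errors import ConfigurationError, DegenerateInputError
from conftest import brute_force_auc, brute_force_concordance, make_cohort_rows


class TestEmpiricalAUC:
    def test_perfect_separation(self):
        r = empirical_auc([1, 2, 3, 4], [0, 0, 1, 1])
        assert r.auc == 1.0

    def test_constant_scores_are_uninformative(self):
        r = empirical_auc([5, 5, 5, 5], [0, 1, 0, 1])
        assert r.auc == 0.5

    def test_tied_scores_get_half_credit(self):
        # pairs: (2,1)=1, (2,2)=0.5, (3,1)=1, (3,2)=1 -> 3.5/4
        r = empirical_auc([1, 2, 2, 3], [0, 1, 0, 1])
        assert r.auc == pytest.approx(0.875, abs=1e-15)

    def test_single_class_labels_rejected(self):
        with pytest.raises(DegenerateInputError):
            empirical_auc([1, 2, 3], [1, 1, 1])

    def test_matches_exhaustive_pair_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = rng.integers(4, 51)
            scores = rng.integers(0, 8, n).astype(float)  # many ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            r = empirical_auc(scores, labels)
            assert r.auc == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )
            assert r.variance >= 0.0
            assert r.ci_low <= r.auc <= r.ci_high

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        scores = rng.normal(size=500)
        labels = rng.integers(0, 2, 500)
        assert empirical_auc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_symmetry_and_monotone_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        scores = rng.integers(0, 10, n).astype(float)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            return
        a = empirical_auc(scores, labels).auc
        assert a + empirical_auc(-scores, labels).auc == pytest.approx(
            1.0, abs=1e-12
        )
        # strictly increasing transform leaves the AUC unchanged
        assert empirical_auc(np.exp(scores / 3), labels).auc == pytest.approx(
            a, abs=1e-12
        )


class TestDeLong:
    def test_identical_scores_give_null_result(self):
        s = np.arange(20.0)
        y = np.tile([0, 1], 10)
        r = delong_paired_test(s, s, y)
        assert r.z == 0.0
        assert r.p_two_sided == 1.0

    def test_small_instance_agrees_with_bootstrap_oracle(self):
        rng = np.random.default_rng(42)
        n = 30
        y = np.array([1] * 12 + [0] * 18)
        a = rng.normal(size=n) + 0.9 * y
        b = rng.normal(size=n) + 0.3 * y
        r = delong_paired_test(a, b, y)
        # paired bootstrap over participants, 10,000 resamples
        boots = []
        for _ in range(10_000):
            idx = rng.integers(0, n, n)
            yy = y[idx]
            if yy.min() == yy.max():
                continue
            boots.append(
                empirical_auc(a[idx], yy).auc - empirical_auc(b[idx], yy).auc
            )
        boots = np.asarray(boots)
        observed = r.auc_difference
        # normal-approximation bootstrap p using the resampling SE
        z_boot = observed / boots.std(ddof=1)
        from scipy.stats import norm

        p_boot = 2 * norm.sf(abs(z_boot))
        assert r.p_two_sided == pytest.approx(p_boot, abs=0.05)

    def test_detects_a_clearly_better_marker(self):
        rng = np.random.default_rng(3)
        n = 2000
        y = (rng.random(n) < 0.3).astype(int)
        good = rng.normal(size=n) + 1.2 * y
        noise = rng.normal(size=n)
        r = delong_paired_test(good, noise, y)
        assert r.auc_difference > 0
        assert r.p_two_sided < 1e-6


class TestAgeComparator:
    def test_perfectly_separating_threshold(self):
        ages = [60, 70, 40, 45]
        labels = [1, 1, 0, 0]
        assert age_threshold_comparator(ages, labels).auc == 1.0

    def test_closed_form_for_binary_marker(self):
        # 10 cases (8 aged >=56), 90 controls (30 aged >=56)
        ages = np.concatenate(
            [np.full(8, 60.0), np.full(2, 40.0),
             np.full(30, 60.0), np.full(60, 40.0)]
        )
        labels = np.concatenate([np.ones(10), np.zeros(90)])
        r = age_threshold_comparator(ages, labels)
        sens, spec = 0.8, 60 / 90
        assert r.auc == pytest.approx((sens + spec) / 2, abs=1e-12)
        # and the pair-enumeration oracle agrees
        assert r.auc == pytest.approx(
            brute_force_auc((ages >= 56).astype(float), labels), abs=1e-12
        )

    def test_random_binary_markers_match_identity(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            n = int(rng.integers(10, 80))
            ages = rng.uniform(30, 79, n)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            ind = ages >= 56
            if ind.all() or not ind.any():
                continue
            cases = labels == 1
            sens = ind[cases].mean()
            spec = (~ind[~cases]).mean()
            r = age_threshold_comparator(ages, labels)
            assert r.auc == pytest.approx((sens + spec) / 2, abs=1e-12)


class TestConcordance:
    def test_perfect_ranking_no_censoring(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        scores = np.array([4.0, 3.0, 2.0, 1.0])  # higher score, earlier event
        assert concordance_cox(times, [1, 1, 1, 1], scores) == 1.0

    def test_six_record_toy_with_censoring_matches_enumeration(self):
        times = np.array([2.0, 3.0, 3.0, 5.0, 7.0, 9.0])
        events = np.array([1, 1, 0, 1, 0, 0])
        scores = np.array([3.0, 2.0, 2.0, 1.0, 2.0, 0.0])
        assert concordance_cox(times, events, scores) == pytest.approx(
            brute_force_concordance(times, events, scores), abs=1e-15
        )

    def test_matches_enumeration_on_random_censored_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(5, 120))
            times = rng.exponential(5.0, n).round(1) + 0.1  # ties likely
            events = rng.integers(0, 2, n)
            scores = rng.integers(0, 6, n).astype(float)
            if events.sum() == 0:
                continue
            try:
                c = concordance_cox(times, events, scores)
            except DegenerateInputError:
                continue
            assert c == pytest.approx(
                brute_force_concordance(times, events, scores), abs=1e-12
            )

    def test_agrees_with_lifelines_on_untied_times(self):
        from lifelines.utils import concordance_index

        rng = np.random.default_rng(6)
        times = rng.exponential(5.0, 300)  # continuous: no ties
        events = rng.integers(0, 2, 300)
        scores = rng.normal(size=300)
        assert concordance_cox(times, events, scores) == pytest.approx(
            concordance_index(times, -scores, events), abs=1e-12
        )

    def test_no_usable_pairs_rejected(self):
        with pytest.raises(DegenerateInputError):
            concordance_cox([1.0, 2.0], [0, 0], [1.0, 2.0])


class TestTopK:
    def test_all_cases_in_top_fraction(self):
        scores = np.array([9.0, 8.0, 1.0, 2.0, 3.0, 1.5, 0.5, 0.1, 0.2, 0.3])
        labels = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        m = topk_metrics(scores, labels, 0.2)
        assert m.sensitivity == 1.0
        assert m.ppv == 1.0
        assert m.npv == 1.0
        assert m.n_flagged == 2

    def test_two_by_two_table_arithmetic(self):
        # n=100, 10 cases, fraction 0.10, exactly 3 cases flagged
        scores = np.zeros(100)
        labels = np.zeros(100, dtype=int)
        labels[:10] = 1
        scores[:3] = 10.0          # 3 flagged cases
        scores[10:17] = 9.0        # 7 flagged controls
        scores[3:10] = 1.0         # unflagged cases
        m = topk_metrics(scores, labels, 0.10)
        assert m.sensitivity == pytest.approx(0.30)
        assert m.specificity == pytest.approx(83 / 90)
        assert m.ppv == pytest.approx(0.30)
        assert m.npv == pytest.approx(83 / 90)

    def test_flagged_count_is_ceiling_and_ties_break_by_id(self):
        rng = np.random.default_rng(7)
        for _ in range(100)[:100]:
            n = int(rng.integers(5, 200))
            frac = float(rng.uniform(0.05, 0.6))
            scores = rng.integers(0, 4, n).astype(float)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            m = topk_metrics(scores, labels, frac)
            assert m.n_flagged == int(np.ceil(frac * n))
            # 2x2 identities: PPV*flagged = TP, sens*cases = TP
            assert m.ppv * m.n_flagged == pytest.approx(m.true_positives)
            assert m.sensitivity * labels.sum() == pytest.approx(
                m.true_positives
            )

    def test_fraction_bounds(self):
        with pytest.raises(ConfigurationError):
            topk_metrics([1.0, 2.0], [0, 1], 1.5)


class TestSubgroups:
    def test_sex_grouping_returns_two_strata(self):
        df = make_cohort_rows(
            [{"sex": "male"} for _ in range(5)]
            + [{"sex": "female"} for _ in range(5)]
        )
        scores = np.arange(10.0)
        labels = np.tile([0, 1], 5)
        results = subgroup_discrimination(df, scores, "sex", labels)
        assert [r.subgroup for r in results] == ["male", "female"]
        assert all(r.defined for r in results)

    def test_empty_stratum_reported_undefined_with_reason(self):
        df = make_cohort_rows([{"sex": "male"} for _ in range(6)])
        scores = np.arange(6.0)
        labels = np.array([0, 1, 0, 1, 0, 1])
        results = subgroup_discrimination(df, scores, "sex", labels)
        female = [r for r in results if r.subgroup == "female"][0]
        assert not female.defined
        assert "lacks" in female.reason

    def test_unknown_grouping_rejected(self):
        df = make_cohort_rows([{}])
        with pytest.raises(ConfigurationError):
            subgroup_discrimination(df, [1.0], "province", [1])

    def test_null_simulation_auc_near_half_in_each_stratum(self):
        rng = np.random.default_rng(8)
        n = 20_000
        df = make_cohort_rows([{} for _ in range(200)])  # template only
        import pandas as pd

        df = pd.concat([df] * 100, ignore_index=True)
        df["sex"] = np.where(rng.random(n) < 0.5, "male", "female")
        df["age"] = rng.uniform(30, 79, n)
        scores = rng.normal(size=n)
        labels = rng.random(n) < 0.02
        for r in subgroup_discrimination(df, scores, "sex", labels):
            assert abs(r.auc - 0.5) < 3 * np.sqrt(r.variance)
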