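"""Scale banding, reduction-rate efficacy, outcome tables, group tests."""

import numpy as np
import pytest
from scipy import stats

from fawfs.clinical_stats import (
    COMPLIANCE_CATEGORIES,
    EFFICACY_CATEGORIES,
    aggregate_outcomes,
    chi_square_2x2,
    classify_efficacy,
    classify_severity,
    cohort_outcome_analysis,
    hamd_reduction_rate,
    two_sample_t,
)
from fawfs.synthetic_data import CohortSpec, make_clinical_cohort

# Published two-arm outcome counts (27 patients per arm): efficacy
# categories cured/markedly/effective/ineffective and compliance
# categories complete/basic/non.
EFFICACY_COUNTS = {
    "intervention": {"cured": 12, "markedly_effective": 8, "effective": 5, "ineffective": 2},
    "control": {"cured": 4, "markedly_effective": 5, "effective": 7, "ineffective": 11},
}
COMPLIANCE_COUNTS = {
    "intervention": {"complete": 15, "basic": 9, "non": 3},
    "control": {"complete": 4, "basic": 7, "non": 16},
}


class TestSeverity:
    @pytest.mark.parametrize(
        "instrument,score,expected",
        [
            ("SAS", 45, "none"),
            ("SAS", 55, "mild_anxiety"),
            ("SAS", 65, "moderate_anxiety"),
            ("SAS", 70, "severe_anxiety"),
            ("SDS", 72, "severe_depression"),
            ("SDS", 50, "mild_depression"),
            ("HAMD", 5, "none"),
            ("HAMD", 8, "mild"),
            ("HAMD", 20, "mild"),
            ("HAMD", 21, "mild_to_moderate"),
            ("HAMD", 34, "mild_to_moderate"),
            ("HAMD", 36, "severe"),
        ],
    )
    def test_bands(self, instrument, score, expected):
        assert classify_severity(instrument, score) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            classify_severity("SAS", -1)
        with pytest.raises(ValueError):
            classify_severity("XYZ", 10)


class TestReductionRate:
    @pytest.mark.parametrize(
        "pre,post,expected", [(32, 6, 81.25), (30, 30, 0.0), (30, 12, 60.0)]
    )
    def test_arithmetic(self, pre, post, expected):
        assert hamd_reduction_rate(pre, post) == pytest.approx(expected)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            hamd_reduction_rate(0, 0)


class TestEfficacy:
    @pytest.mark.parametrize(
        "rate,expected",
        [
            (81.25, "cured"),
            (75.0, "markedly_effective"),
            (60.0, "markedly_effective"),
            (50.0, "effective"),
            (30.0, "effective"),
            (25.0, "ineffective"),
            (14.3, "ineffective"),
        ],
    )
    def test_bands(self, rate, expected):
        assert classify_efficacy(rate) == expected

    def test_composition_monotone_in_post_score(self):
        # lower post score never yields a worse category (0 = cured is best)
        badness = {c: i for i, c in enumerate(EFFICACY_CATEGORIES)}
        ranks = [
            badness[classify_efficacy(hamd_reduction_rate(30, post))]
            for post in range(30, -1, -1)
        ]
        assert ranks == sorted(ranks, reverse=True)


class TestAggregateOutcomes:
    def test_published_efficacy_percentages(self):
        table = aggregate_outcomes(EFFICACY_COUNTS)
        iv, ct = table.loc["intervention"], table.loc["control"]
        assert iv["total_effective"] == 25 and iv["total_effective_pct"] == 92.59
        assert ct["total_effective"] == 16 and ct["total_effective_pct"] == 59.26
        assert iv["cured_pct"] == 44.44
        assert iv["markedly_effective_pct"] == 29.63
        assert iv["effective_pct"] == 18.52
        assert iv["ineffective_pct"] == 7.41
        assert ct["cured_pct"] == 14.81
        assert ct["markedly_effective_pct"] == 18.52
        assert ct["effective_pct"] == 25.93
        assert ct["ineffective_pct"] == 40.74

    def test_published_compliance_percentages(self):
        table = aggregate_outcomes(COMPLIANCE_COUNTS, category_set=COMPLIANCE_CATEGORIES)
        iv, ct = table.loc["intervention"], table.loc["control"]
        assert iv["total_compliant"] == 24 and iv["total_compliant_pct"] == 88.89
        assert ct["total_compliant"] == 11 and ct["total_compliant_pct"] == 40.74
        assert iv["complete_pct"] == 55.56 and iv["basic_pct"] == 33.33
        assert iv["non_pct"] == 11.11
        assert ct["complete_pct"] == 14.81 and ct["basic_pct"] == 25.93
        assert ct["non_pct"] == 59.26

    def test_percentages_sum_to_hundred(self):
        for counts, cats in [
            (EFFICACY_COUNTS, EFFICACY_CATEGORIES),
            (COMPLIANCE_COUNTS, COMPLIANCE_CATEGORIES),
        ]:
            table = aggregate_outcomes(counts, category_set=cats)
            sums = sum(table[f"{c}_pct"] for c in cats)
            assert (np.abs(sums - 100.0) <= 0.02).all()

    def test_single_category_and_per_patient_input(self):
        cats = ["cured"] * 10
        groups = ["g"] * 10
        table = aggregate_outcomes(cats, groups)
        assert table.loc["g", "cured_pct"] == 100.00
        assert table.loc["g", "ineffective_pct"] == 0.00

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            aggregate_outcomes(["miracle"], ["g"])


class TestChiSquare:
    def test_homogeneous_rows_zero(self):
        stat, p = chi_square_2x2([[10, 5], [10, 5]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_expected_count_oracle(self):
        obs = np.array([[25, 2], [16, 11]], dtype=float)
        row = obs.sum(1, keepdims=True)
        col = obs.sum(0, keepdims=True)
        exp = row * col / obs.sum()
        expected_stat = ((obs - exp) ** 2 / exp).sum()
        stat, p = chi_square_2x2(obs)
        assert stat == pytest.approx(expected_stat, rel=1e-12)
        ref_stat, ref_p, _, _ = stats.chi2_contingency(obs, correction=False)
        assert stat == pytest.approx(ref_stat, rel=1e-12)
        assert p == pytest.approx(ref_p, rel=1e-9)

    def test_doubling_counts_doubles_statistic(self):
        obs = [[12, 8], [5, 15]]
        s1, _ = chi_square_2x2(obs)
        s2, _ = chi_square_2x2(2 * np.asarray(obs))
        assert s2 == pytest.approx(2 * s1)

    def test_invariant_under_row_and_column_swap(self):
        obs = np.array([[25, 2], [16, 11]])
        s, _ = chi_square_2x2(obs)
        assert chi_square_2x2(obs[::-1])[0] == pytest.approx(s)
        assert chi_square_2x2(obs[:, ::-1])[0] == pytest.approx(s)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [3, 4]])


class TestTwoSampleT:
    def test_identical_groups(self):
        t, p = two_sample_t([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_separated_groups(self):
        t, p = two_sample_t([1, 2, 3], [11, 12, 13])
        assert abs(t) > 5
        assert p < 0.01

    def test_matches_welch_formula_oracle(self):
        rng = np.random.default_rng(27)
        a = rng.normal(40, 4, size=27)
        b = rng.normal(38, 5, size=27)
        va, vb = a.var(ddof=1) / 27, b.var(ddof=1) / 27
        t_ref = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 26 + vb**2 / 26)
        p_ref = 2 * stats.t.sf(abs(t_ref), df)
        t, p = two_sample_t(a, b)
        assert t == pytest.approx(t_ref, rel=1e-9)
        assert p == pytest.approx(p_ref, rel=1e-9)


def test_cohort_analysis_detects_planted_effect():
    cohort = make_clinical_cohort(
        CohortSpec(n_per_group=27, intervention_effect=8.0, seed=12)
    )
    results = cohort_outcome_analysis(cohort)
    tests = results["tests"].set_index("comparison")
    welch = tests[tests["test"] == "welch_t"].iloc[0]
    assert welch["p_value"] < 0.05
    table = results["HAMD_efficacy"]
    assert set(table.index) == {"control", "intervention"}
    assert (
        table.loc["intervention", "total_effective_pct"]
        >= table.loc["control", "total_effective_pct"]
    )
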