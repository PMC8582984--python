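"""Risk scores, quartile grouping, bimodality and the descriptive tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import perceptrisk as pr
from perceptrisk.scoring import (assign_quartiles, chi_square_test,
                                 contingency_table, detect_bimodality,
                                 frequency_profile, risk_histogram, risk_score)


class TestRiskScore:
    def test_row_sums(self):
        m = np.array([[0, 0, 0], [1, 1, -1], [-1, -1, -1]])
        assert risk_score(m).tolist() == [0, 1, -3]

    def test_score_conservation_and_bounds(self, small_survey):
        matrix = pr.encode_risk_matrix(small_survey.responses)
        scores = risk_score(matrix)
        assert scores.sum() == matrix.values.sum()
        assert scores.min() >= -matrix.m and scores.max() <= matrix.m


class TestQuartiles:
    def test_documented_percentile_rule_on_1_to_8(self):
        assert assign_quartiles(np.arange(1, 9)).tolist() == [1, 1, 2, 2, 3, 3, 4, 4]

    def test_ties_share_a_label(self):
        scores = np.array([0, 0, 0, 0, 0, 0, 1, 2])
        labels = assign_quartiles(scores)
        assert len(set(labels[scores == 0])) == 1

    def test_monotone_in_score(self, small_survey):
        scores = risk_score(pr.encode_risk_matrix(small_survey.responses))
        labels = assign_quartiles(scores)
        order = np.argsort(scores, kind="stable")
        assert (np.diff(labels[order]) >= 0).all()

    def test_constant_scores_warn_single_group(self):
        with pytest.warns(UserWarning, match="identical"):
            labels = assign_quartiles(np.zeros(10))
        assert set(labels) == {1}

    def test_too_few_respondents_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            assign_quartiles(np.array([1, 2, 3]))


class TestHistogram:
    def test_empty_scores(self):
        assert len(risk_histogram(np.array([]))) == 0

    def test_unit_width_counts(self):
        hist = risk_histogram(np.array([0, 0, 1]), 1)
        assert hist["count"].tolist() == [2, 1]
        assert hist["bin_left"].tolist() == [0, 1]

    def test_counts_sum_to_n(self, small_survey):
        scores = risk_score(pr.encode_risk_matrix(small_survey.responses))
        for width in (1, 2, 5):
            assert risk_histogram(scores, width)["count"].sum() == len(scores)


class TestBimodality:
    def test_two_separated_normals_flagged(self):
        rng = np.random.default_rng(0)
        scores = np.concatenate([rng.normal(-20, 5, 250), rng.normal(20, 5, 250)])
        assert detect_bimodality(scores).is_bimodal

    def test_single_normal_rarely_flagged(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            if detect_bimodality(rng.normal(0, 10, 500)).is_bimodal:
                hits += 1
        assert hits <= 1  # >= 95% specificity under the null

    def test_constant_scores_false_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert not detect_bimodality(np.zeros(100)).is_bimodal

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="n >= 50"):
            detect_bimodality(np.arange(10))


class TestContingencyAndChiSquare:
    # Printed gender x quartile counts from the modelled study's Table 1:
    # these serve as fixed input data for the arithmetic/inference checks.
    TABLE1 = [[1395, 1422, 1015, 976], [1785, 1992, 1932, 2132]]

    def test_single_respondent(self):
        ct = contingency_table(["female"], [1])
        assert ct.counts.iloc[0, 0] == 1
        assert ct.with_margins.loc["Total", "Total"] == 1

    def test_conservation_on_random_labels(self):
        rng = np.random.default_rng(3)
        rows = rng.choice(["a", "b", "c"], 100)
        cols = rng.choice([1, 2, 3, 4], 100)
        ct = contingency_table(rows, cols)
        assert ct.with_margins.loc["Total", "Total"] == 100
        assert (ct.with_margins.drop("Total").drop(columns="Total").sum().sum()
                == 100)
        assert np.isclose(ct.percent_of_total.loc["Total", "Total"], 100.0)

    def test_proportional_table_gives_zero_statistic(self):
        res = chi_square_test([[10, 20], [30, 60]])
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res["p_value"] == pytest.approx(1.0)

    def test_statistic_matches_direct_summation(self):
        obs = np.array([[10.0, 20.0], [20.0, 10.0]])
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        by_hand = ((obs - expected) ** 2 / expected).sum()
        res = chi_square_test(obs)
        assert res["statistic"] == pytest.approx(by_hand, abs=1e-9)
        assert res["df"] == 1

    @given(st.lists(st.integers(1, 50), min_size=4, max_size=4))
    @settings(max_examples=50, deadline=None)
    def test_chi_square_oracle_on_random_2x2(self, cells):
        obs = np.array(cells, dtype=float).reshape(2, 2)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        by_hand = ((obs - expected) ** 2 / expected).sum()
        assert chi_square_test(obs)["statistic"] == pytest.approx(by_hand, abs=1e-9)

    def test_printed_gender_quartile_table_significant(self):
        res = chi_square_test(self.TABLE1)
        assert res["df"] == 3
        assert res["p_value"] < 0.01

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="zero marginal"):
            chi_square_test([[0, 0], [1, 2]])


class TestFrequencyProfile:
    def test_single_group_all_true(self):
        groups = pd.DataFrame({"g": ["x"] * 5})
        flags = pd.DataFrame({"worry": [True] * 5})
        prof = frequency_profile(groups, flags)
        assert prof.loc[0, "percent"] == 100.0

    def test_counts_partition_population(self, small_survey):
        scores = risk_score(pr.encode_risk_matrix(small_survey.responses))
        quartiles = assign_quartiles(scores)
        groups = pd.DataFrame({"quartile": quartiles})
        flags = small_survey.responses.flags("emotion")
        prof = frequency_profile(groups, flags)
        for flag in flags.columns:
            assert prof.loc[prof["flag"] == flag, "count"].sum() == flags[flag].sum()

    def test_emotion_prevalence_monotone_in_quartile(self, small_survey):
        """Flags generated with positive slope on the trait rise from QR1 to QR4."""
        scores = risk_score(pr.encode_risk_matrix(small_survey.responses))
        quartiles = assign_quartiles(scores)
        groups = pd.DataFrame({"quartile": quartiles})
        prof = frequency_profile(groups, small_survey.responses.flags("emotion"))
        alert = prof[prof["flag"] == "alertness"].set_index("quartile")["percent"]
        assert alert.loc[4] > alert.loc[1]
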