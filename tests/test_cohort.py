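"""Recruitment flow, summaries and closed-form estimators."""

import numpy as np
import pandas as pd
import pytest

from lepmel.cohort import (
    apply_exclusions,
    chi_square_independence,
    kruskal_wallis,
    national_coverage,
    population_incidence,
    required_sample_size,
    round_half_up,
    summarize_groups,
)
from lepmel.errors import DomainError, InputError
from lepmel.simulate import generate_referral_table


class TestExclusionFlow:
    def test_printed_stage_counts_telescope_to_enrollment(self, reference):
        raw = generate_referral_table(reference, seed=3)
        enrolled, ledger = apply_exclusions(raw, reference)
        assert ledger.referred == 1935
        assert ledger.excluded_age_consent == 109
        assert ledger.assessed == 1826
        assert (ledger.assessed_without, ledger.assessed_excess) == (472, 1354)
        assert (ledger.excluded_without, ledger.excluded_excess) == (211, 107)
        assert (ledger.enrolled_without, ledger.enrolled_excess) == (261, 1247)
        assert len(enrolled) == 1508

    def test_empty_input_all_zero(self, reference):
        raw = pd.DataFrame(
            columns=["id", "sex", "age_years", "weight_kg", "height_m", "flags"]
        )
        enrolled, ledger = apply_exclusions(raw, reference)
        assert len(enrolled) == 0 and ledger.referred == 0

    def test_underage_participant_dropped_at_stage_one(self, reference):
        raw = pd.DataFrame(
            {
                "id": ["X1"], "sex": ["F"], "age_years": [1.5],
                "weight_kg": [12.0], "height_m": [0.8], "flags": [""],
            }
        )
        enrolled, ledger = apply_exclusions(raw, reference)
        assert len(enrolled) == 0
        assert ledger.reasons["X1"] == "age_out_of_range"

    @pytest.mark.parametrize("seed", range(5))
    def test_ledger_telescopes_under_random_flags(self, reference, seed):
        rng = np.random.default_rng(seed)
        n = 200
        tokens = ["", "no_consent", "metabolic_other", "iugr",
                  "hypopituitarism", "syndromic", "iugr;syndromic"]
        raw = generate_referral_table(
            reference, n_referred=n, n_age_consent=0, n_without=n // 2,
            n_excess=n - n // 2, n_excluded_without=0, n_excluded_excess=0,
            seed=seed,
        )
        raw["flags"] = rng.choice(tokens, size=n)
        raw.loc[rng.random(n) < 0.1, "age_years"] = 1.0
        _, ledger = apply_exclusions(raw, reference)  # validate() runs inside
        assert ledger.referred == n


class TestGroupSummary:
    def test_exact_carrier_percentages(self, exact_cohort, exact_matrix):
        cohort, _ = exact_cohort
        summary = summarize_groups(cohort, exact_matrix)
        all_col = summary[summary["column"] == "all"].set_index("stratum")
        assert all_col.loc["DCV", "n"] == 21 and all_col.loc["DCV", "pct"] == 1.4
        assert all_col.loc["VUS", "n"] == 62 and all_col.loc["VUS", "pct"] == 4.1

    def test_stratum_percentages_sum_to_total(self, exact_cohort, exact_matrix):
        cohort, _ = exact_cohort
        summary = summarize_groups(cohort, exact_matrix)
        all_col = summary[summary["column"] == "all"].set_index("stratum")
        parts = all_col.loc[["DCV", "VUS", "No variant"], "n"].sum()
        assert parts == all_col.loc["Total", "n"]
        pct_sum = all_col.loc[["DCV", "VUS", "No variant"], "pct"].sum()
        assert pct_sum == pytest.approx(100.0, abs=0.2)  # one-decimal rounding

    def test_single_participant_stratum_has_zero_iqr(self, exact_cohort, exact_matrix):
        cohort, _ = exact_cohort
        one = cohort.iloc[:1]
        summary = summarize_groups(one, exact_matrix)
        row = summary[(summary["stratum"] == "Total") & (summary["column"] == "all")]
        assert row["age_iqr"].iloc[0] == 0.0


class TestRankTests:
    def test_identical_observations_give_zero_h(self):
        assert kruskal_wallis([[5, 5, 5], [5, 5]]) == (0.0, 1.0)

    def test_two_group_rank_sum_value(self):
        # ranks 1..6, R1=6, R2=15 -> H = 12/42 * (12+75) - 21 = 27/7
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(27 / 7, abs=1e-12)
        assert 0 < p < 1

    def test_group_order_irrelevant(self):
        a = kruskal_wallis([[1.2, 3.4], [5.6, 7.8], [2.2, 9.9]])
        b = kruskal_wallis([[2.2, 9.9], [1.2, 3.4], [5.6, 7.8]])
        assert a == b

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            kruskal_wallis([[1, 2], []])

    def test_uniform_table_has_zero_statistic(self):
        stat, p = chi_square_independence([[10, 10], [10, 10]])
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_pearson_statistic_value(self):
        # expected 15 in every cell -> chi2 = 4 * 25/15 = 20/3
        stat, _ = chi_square_independence([[20, 10], [10, 20]])
        assert stat == pytest.approx(20 / 3, abs=1e-12)

    def test_transpose_invariance(self):
        t = [[5, 9, 2], [7, 3, 8]]
        assert chi_square_independence(t)[0] == pytest.approx(
            chi_square_independence(np.transpose(t))[0]
        )

    def test_zero_margin_rejected(self):
        with pytest.raises(InputError):
            chi_square_independence([[0, 0], [5, 3]])


class TestSampleSize:
    def test_survey_conditions_give_1067(self):
        assert required_sample_size(0.95, 0.03, 0.5) == 1067

    def test_shrinks_with_vanishing_variance(self):
        assert required_sample_size(0.95, 0.03, 1e-6) < 5

    def test_quadruples_when_margin_halves(self):
        z = 1.959963984540054
        exact = lambda e: z**2 * 0.25 / e**2  # noqa: E731
        assert exact(0.015) == pytest.approx(4 * exact(0.03))
        assert required_sample_size(0.95, 0.015, 0.5) in (4268, 4269)

    def test_monotone_in_margin_and_maximal_at_half(self):
        margins = [0.01, 0.02, 0.05, 0.1]
        sizes = [required_sample_size(0.95, m, 0.5) for m in margins]
        assert sizes == sorted(sizes, reverse=True)
        assert required_sample_size(0.95, 0.03, 0.5) >= required_sample_size(0.95, 0.03, 0.3)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            required_sample_size(0.95, 0.0, 0.5)


class TestCoverageAndIncidence:
    def test_estimated_obese_truncates(self):
        estimated, coverage = national_coverage(1079, 293897, 0.06)
        assert estimated == 17633
        assert round_half_up(100 * coverage, 1) == 6.1

    def test_zero_cohort_zero_coverage(self):
        assert national_coverage(0, 293897, 0.06)[1] == 0.0

    def test_incidence_point_estimate(self):
        rate, (lo, hi) = population_incidence(21, 1247, 0, 261, 0.06)
        assert rate == pytest.approx((21 / 1247) * 0.06, rel=1e-12)
        assert 0 <= lo <= rate <= hi

    def test_zero_carriers_zero_rate(self):
        rate, (lo, _) = population_incidence(0, 100, 0, 100, 0.06)
        assert rate == 0.0 and lo == 0.0

    def test_prevalence_one_limit_reduces_to_obese_fraction(self):
        rate, _ = population_incidence(30, 300, 5, 100, 1 - 1e-12)
        assert rate == pytest.approx(0.1, rel=1e-9)

    def test_carriers_exceeding_group_rejected(self):
        with pytest.raises(InputError):
            population_incidence(10, 5, 0, 10, 0.06)
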