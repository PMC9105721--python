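"""Fisher exact test, class rebalancing, classification rule and FDR."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from lepmel.association import (
    ContingencyTable2x2,
    PDistributionSummary,
    bh_fdr,
    classify_gene_association,
    fisher_exact,
    rebalance_sample,
    resampled_association,
)
from lepmel.errors import DomainError, InputError


def exact_fisher_p(a, b, c, d):
    """Independent oracle: exact minimum-likelihood two-sided p by integer
    enumeration of all tables with the observed margins."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    weights = [math.comb(c1, k) * math.comb(n - c1, r1 - k) for k in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    total = sum(weights)
    return Fraction(sum(w for w in weights if w <= w_obs), total)


class TestFisher:
    def test_enumerated_example(self):
        p, oratio = fisher_exact(ContingencyTable2x2(3, 1, 1, 3))
        assert p == pytest.approx(34 / 70, abs=1e-12)
        assert oratio == pytest.approx(9.0)

    def test_zero_margin_degenerates(self):
        p, oratio = fisher_exact(ContingencyTable2x2(0, 10, 0, 10))
        assert p == 1.0 and math.isnan(oratio)

    def test_row_and_column_swap_symmetry(self):
        p1, _ = fisher_exact(ContingencyTable2x2(7, 2, 3, 8))
        p2, _ = fisher_exact(ContingencyTable2x2(8, 3, 2, 7))
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_haldane_anscombe_odds_ratio_on_zero_cell(self):
        _, oratio = fisher_exact(ContingencyTable2x2(0, 5, 3, 2))
        assert oratio == pytest.approx((0.5 * 2.5) / (5.5 * 3.5))

    def test_negative_count_rejected(self):
        with pytest.raises(InputError):
            ContingencyTable2x2(-1, 2, 3, 4)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exact_enumeration_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 12, size=4)
            t = ContingencyTable2x2(int(a), int(b), int(c), int(d))
            if a + c == 0 or b + d == 0 or a + b == 0 or c + d == 0:
                continue
            p, _ = fisher_exact(t)
            assert p == pytest.approx(float(exact_fisher_p(a, b, c, d)), abs=1e-10)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, size=4))
            if a + c == 0 or b + d == 0 or a + b == 0 or c + d == 0:
                continue
            p, oratio = fisher_exact(ContingencyTable2x2(a, b, c, d))
            res = stats.fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(res.pvalue, rel=1e-9, abs=1e-12)
            if min(a, b, c, d) > 0:
                assert oratio == pytest.approx(res.statistic)


class TestRebalancing:
    def test_study_sized_groups_split_50_50(self):
        g = np.repeat([True, False], [1247, 261])
        idx = rebalance_sample(g, seed=0)
        assert len(idx) == 1508
        assert g[idx].sum() == 754  # undersampled majority
        assert (~g[idx]).sum() == 754  # oversampled minority

    def test_minority_drawn_with_replacement(self):
        g = np.repeat([True, False], [1247, 261])
        idx = rebalance_sample(g, seed=1)
        minority_draws = idx[~g[idx]]
        assert len(np.unique(minority_draws)) < len(minority_draws)

    def test_majority_drawn_without_replacement(self):
        g = np.repeat([True, False], [1247, 261])
        idx = rebalance_sample(g, seed=2)
        majority_draws = idx[g[idx]]
        assert len(np.unique(majority_draws)) == len(majority_draws)

    def test_balanced_input_stays_balanced(self):
        g = np.repeat([True, False], [100, 100])
        idx = rebalance_sample(g, seed=3)
        assert g[idx].sum() == 100

    def test_same_seed_same_multiset(self):
        g = np.repeat([True, False], [300, 80])
        a = rebalance_sample(g, seed=5)
        b = rebalance_sample(g, seed=5)
        assert np.array_equal(a, b)

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            rebalance_sample(np.ones(10, dtype=bool), seed=0)

    def test_carrier_rate_averages_the_two_class_rates(self):
        # minority rate 0.2, majority rate 0.05 -> resampled rate ~ 0.125
        rng = np.random.default_rng(0)
        g = np.repeat([True, False], [1000, 250])
        carrier = np.where(g, rng.random(1250) < 0.05, rng.random(1250) < 0.2)
        rates = []
        for seed in range(300):
            idx = rebalance_sample(g, seed=seed)
            rates.append(carrier[idx].mean())
        assert np.mean(rates) == pytest.approx(0.125, abs=0.02)


class TestResampledAssociation:
    def test_single_iteration_equals_single_draw(self):
        rng = np.random.default_rng(1)
        g = np.repeat([True, False], [120, 40])
        carrier = rng.random(160) < 0.1
        s = resampled_association(carrier, None, g, n_iter=1, seed=9)
        assert s.median_p == s.iqr_p[0] == s.iqr_p[1]

    def test_null_usually_has_high_median_p(self):
        # the rebalanced test is anti-conservative (duplicated minority
        # observations), so the null median p dips below 0.05 in a minority
        # of cohorts; require the clear majority to stay above
        g = np.repeat([True, False], [1247, 261])
        master = np.random.SeedSequence(7)
        high = 0
        for stream in master.spawn(20):
            rng = np.random.default_rng(stream)
            carrier = rng.random(1508) < 0.04  # equal rate in both classes
            s = resampled_association(carrier, None, g, n_iter=99, seed=stream.spawn(1)[0])
            high += s.median_p > 0.05
        assert high >= 15

    def test_planted_enrichment_is_detected(self):
        rng = np.random.default_rng(3)
        g = np.repeat([True, False], [1247, 261])
        carrier = np.where(g, rng.random(1508) < 0.10, False)  # 10% vs 0%
        s = resampled_association(carrier, None, g, n_iter=199, seed=17)
        assert s.median_p < 0.05
        assert s.or_median > 1

    def test_zero_carriers_degenerate(self):
        g = np.repeat([True, False], [30, 30])
        with pytest.warns(UserWarning, match="no carriers"):
            s = resampled_association(np.zeros(60, bool), None, g, n_iter=9, seed=0)
        assert s.median_p == 1.0 and math.isnan(s.or_median)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        g = np.repeat([True, False], [200, 60])
        carrier = rng.random(260) < 0.1
        a = resampled_association(carrier, None, g, n_iter=49, seed=11)
        b = resampled_association(carrier, None, g, n_iter=49, seed=11)
        assert a == b


def summary(median, q1, q3, n_iter=9999):
    return PDistributionSummary(
        n_iter=n_iter, median_p=median, iqr_p=(q1, q3), or_median=2.0, or_ci=(1.0, 4.0)
    )


class TestClassificationRule:
    @pytest.mark.parametrize(
        "median,q1,q3,n_variants,expected",
        [
            (0.0107, 0.0014, 0.0553, 23, "associated"),
            (0.026, 0.007, 0.0622, 10, "associated"),
            (0.031, 0.011, 0.118, 14, "associated"),
            (0.2, 0.04, 0.3, 12, "partially_associated"),
            (0.2, 0.06, 0.3, 12, "not_associated"),
            (0.0107, 0.0014, 0.0553, 4, "not_applicable"),
            (0.9, 0.8, 0.95, 2, "not_applicable"),
        ],
    )
    def test_median_iqr_rule(self, median, q1, q3, n_variants, expected):
        assert classify_gene_association(summary(median, q1, q3), n_variants) == expected


class TestBHFdr:
    def test_step_up_hand_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3]) == [0.3]

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_adjusted_at_least_raw_and_order_preserved(self):
        rng = np.random.default_rng(0)
        p = rng.random(20)
        adj = np.array(bh_fdr(p))
        assert np.all(adj >= p - 1e-15)
        # input order preserved: adjusting a permutation permutes the output
        perm = rng.permutation(20)
        adj_perm = np.array(bh_fdr(p[perm]))
        assert adj_perm == pytest.approx(adj[perm])

    def test_fully_tied_adjusted_vector_is_a_fixed_point(self):
        # a flat adjusted vector re-adjusts to itself (p * n/n at every rank)
        assert bh_fdr([0.04] * 4) == pytest.approx([0.04] * 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            bh_fdr([0.5, 1.5])
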