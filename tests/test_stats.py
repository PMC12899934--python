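import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from dietsim.stats import (adequacy_prevalence, bonferroni_alpha,
                           bootstrap_summary, chi_square_independence,
                           draw_truncated_normal, one_way_anova,
                           pairwise_posthoc, prevalence_se,
                           tradeoff_regression)


class TestPrevalence:
    def test_all_adequate(self):
        assert adequacy_prevalence([10, 20, 30], 5.0) == 100.0

    def test_half_adequate(self):
        assert adequacy_prevalence([8, 9, 10, 11], 10.0) == 50.0

    def test_per_person_thresholds(self):
        assert adequacy_prevalence([10, 10], [8.0, 12.0]) == 50.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            adequacy_prevalence([], 1.0)

    @given(st.lists(st.floats(0.1, 100), min_size=1, max_size=50),
           st.floats(0.5, 50), st.floats(0.5, 50))
    @settings(max_examples=50, deadline=None)
    def test_monotone_nonincreasing_in_threshold(self, values, t1, t2):
        lo, hi = sorted([t1, t2])
        assert adequacy_prevalence(values, lo) >= adequacy_prevalence(values, hi)

    @given(st.lists(st.floats(0.1, 100), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_order_invariance(self, values):
        assert adequacy_prevalence(values, 10.0) == \
            adequacy_prevalence(values[::-1], 10.0)

    def test_binomial_se(self):
        assert prevalence_se(50.0, 100) == pytest.approx(5.0)


class TestChiSquare:
    def test_uniform_table_gives_zero(self):
        r = chi_square_independence([[50, 50], [50, 50]])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        r = chi_square_independence([[30, 10], [10, 30]])
        assert r.statistic == pytest.approx(20.0)
        assert r.df == 1

    def test_df_formula(self):
        r = chi_square_independence([[5, 5], [5, 5], [5, 5]])
        assert r.df == 2

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_independence([[0, 0], [5, 5]])

    def test_agrees_with_reference_implementation(self, rng):
        for _ in range(100):
            shape = rng.integers(2, 5, size=2)
            table = rng.integers(1, 50, size=shape)
            mine = chi_square_independence(table)
            ref = sps.chi2_contingency(table, correction=False)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-8)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-8)


class TestBootstrap:
    def test_constant_vector_degenerate(self):
        b = bootstrap_summary([5.0] * 20, B=200, seed=0)
        assert b.se == 0.0
        assert b.ci_low == b.ci_high == 5.0

    def test_se_matches_clt_for_normal_data(self):
        rng = np.random.default_rng(10)
        sigma = 7.0
        x = rng.normal(100, sigma, 1500)
        b = bootstrap_summary(x, B=1000, seed=1)
        assert b.se == pytest.approx(sigma / np.sqrt(1500), rel=0.10)

    def test_deterministic_given_seed(self, rng):
        x = rng.normal(size=200)
        assert bootstrap_summary(x, seed=3) == bootstrap_summary(x, seed=3)

    def test_percentile_interval_brackets_mean(self, rng):
        x = rng.normal(size=300)
        b = bootstrap_summary(x, B=1000, seed=4)
        assert b.ci_low <= b.point_mean <= b.ci_high

    def test_small_B_warns_and_nonpositive_rejected(self, rng, caplog):
        x = rng.normal(size=50)
        with caplog.at_level("WARNING"):
            bootstrap_summary(x, B=50, seed=0)
        assert any("unstable" in r.message for r in caplog.records)
        with pytest.raises(ValueError):
            bootstrap_summary(x, B=0)

    def test_truncated_draws_nonnegative(self, rng):
        x = draw_truncated_normal(rng, loc=1.0, scale=2.0, size=1000)
        assert (x >= 0).all()


class TestTradeoff:
    def test_exact_proportional_relation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r = tradeoff_regression(x, 2 * x)
        assert r.slope == pytest.approx(2.0)
        assert r.elasticity == pytest.approx(1.0)
        assert r.r2 == pytest.approx(1.0)

    def test_flat_response_zero_elasticity(self):
        r = tradeoff_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert r.slope == pytest.approx(0.0)
        assert r.elasticity == pytest.approx(0.0)

    def test_elasticity_at_sample_means(self):
        # slope 0.5 at mean emissions 3.88 and mean cost 11.34
        assert 0.5 * 3.88 / 11.34 == pytest.approx(0.171, abs=5e-4)
        x = np.array([2.88, 3.88, 4.88])
        y = 0.5 * x + (11.34 - 0.5 * 3.88)
        r = tradeoff_regression(x, y)
        assert r.elasticity == pytest.approx(0.171, abs=5e-4)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            tradeoff_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestAnova:
    def test_equal_means_give_zero_f(self):
        r = one_way_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert r.statistic == pytest.approx(0.0)

    def test_hand_computed_example(self):
        r = one_way_anova([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        assert r.statistic == pytest.approx(13.5)
        assert r.df == (1, 4)

    def test_four_groups_df(self, rng):
        groups = [rng.normal(size=10) for _ in range(4)]
        assert one_way_anova(groups).df[0] == 3

    def test_zero_within_variance_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 1.0], [2.0, 2.0]])

    def test_agrees_with_reference_implementation(self, rng):
        for _ in range(100):
            k = int(rng.integers(2, 6))
            groups = [rng.normal(rng.normal(), 1, size=int(rng.integers(3, 20)))
                      for _ in range(k)]
            mine = one_way_anova(groups)
            ref = sps.f_oneway(*groups)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-8)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-8)


class TestBonferroni:
    def test_four_groups(self):
        adjusted, m = bonferroni_alpha(0.05, 4)
        assert m == 6
        assert adjusted == pytest.approx(0.05 / 6)
        assert round(adjusted, 4) == 0.0083

    def test_two_groups_unchanged(self):
        assert bonferroni_alpha(0.05, 2) == (0.05, 1)

    def test_three_groups(self):
        adjusted, m = bonferroni_alpha(0.01, 3)
        assert m == 3
        assert adjusted == pytest.approx(0.003333, abs=1e-6)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.0, 4)
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 1)


class TestPosthoc:
    def test_welch_bonferroni_detects_shifted_group(self, rng):
        groups = [rng.normal(0, 1, 60), rng.normal(0, 1, 60), rng.normal(3, 1, 60)]
        res = pairwise_posthoc(groups, labels=list("abc"))
        assert len(res) == 3
        flagged = {r["pair"] for r in res if r["significant"]}
        assert ("a", "c") in flagged and ("b", "c") in flagged

    def test_tukey_variant(self, rng):
        groups = [rng.normal(0, 1, 40), rng.normal(4, 1, 40)]
        res = pairwise_posthoc(groups, method="tukey")
        assert res[0]["method"] == "tukey_hsd"
        assert res[0]["significant"]
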