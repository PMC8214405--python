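import numpy as np
import pytest
from scipy import stats

from oracles import fisher_brute, rank_sum_brute, signed_rank_brute
from ppiresilience.evostats import (
    binomial_tail,
    fisher_exact_2x2,
    ols_slope,
    paired_resilience_test,
    pearson_correlation,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank_exact,
)


class TestOlsSlope:
    def test_exact_line(self):
        est = ols_slope([(0, 1.0), (1, 0.9), (2, 0.8)])
        assert est.slope == pytest.approx(-0.1)
        assert est.intercept == pytest.approx(1.0)

    def test_constant_series(self):
        est = ols_slope([(0, 0.5), (1, 0.5), (2, 0.5)])
        assert est.slope == pytest.approx(0.0)

    def test_closed_form_on_clone_scatter(self):
        rng = np.random.default_rng(8)
        gens = np.repeat(np.arange(0, 55_000, 5_000), 2)  # 11 timepoints x 2 clones
        values = 1.0 - 2e-6 * gens + rng.normal(0, 0.01, gens.size)
        est = ols_slope(list(zip(gens, values)))
        xm, ym = gens.mean(), values.mean()
        expected = ((gens - xm) * (values - ym)).sum() / ((gens - xm) ** 2).sum()
        assert est.slope == pytest.approx(expected, rel=1e-12)
        assert est.n_points == 22

    def test_identical_generations_error(self):
        with pytest.raises(ValueError, match="identical"):
            ols_slope([(5, 1.0), (5, 0.9)])

    def test_single_point_error(self):
        with pytest.raises(ValueError):
            ols_slope([(0, 1.0)])


class TestSignedRankExact:
    def test_twelve_positive_differences(self):
        res = wilcoxon_signed_rank_exact([1.0] * 0 + list(range(1, 13)), "greater")
        assert res.p_value == pytest.approx(1 / 4096)
        assert float(f"{res.p_value:.2g}") == 0.00024

    def test_single_positive_difference(self):
        res = wilcoxon_signed_rank_exact([2.5], "greater")
        assert res.p_value == pytest.approx(0.5)

    def test_three_differences(self):
        res = wilcoxon_signed_rank_exact([1, 2, 3], "greater")
        assert res.p_value == pytest.approx(1 / 8)

    def test_zeros_dropped(self):
        with_zero = wilcoxon_signed_rank_exact([0.0, 1, 2, 3], "greater")
        without = wilcoxon_signed_rank_exact([1, 2, 3], "greater")
        assert with_zero.p_value == without.p_value
        assert with_zero.n == 3

    def test_all_zero_error(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank_exact([0.0, 0.0])

    def test_matches_scipy_exact_no_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(3, 13))
            d = rng.normal(size=n)
            ours = wilcoxon_signed_rank_exact(d, "two_sided")
            ref = stats.wilcoxon(d, alternative="two-sided", mode="exact")
            assert ours.p_value == pytest.approx(ref.pvalue)

    @pytest.mark.parametrize("alternative", ["greater", "less", "two_sided"])
    def test_brute_force_oracle_with_ties(self, alternative):
        rng = np.random.default_rng(17)
        for _ in range(40):
            n = int(rng.integers(2, 11))
            # half-integer magnitudes force ties in |d|
            d = rng.choice([-3, -2, -1.5, -1, 1, 1.5, 2, 3], size=n)
            ours = wilcoxon_signed_rank_exact(d, alternative)
            oracle = signed_rank_brute(d, alternative)
            assert ours.p_value == pytest.approx(oracle, abs=1e-12)


class TestPairedResilienceTest:
    def test_all_twelve_positive_gives_headline_p(self):
        evolved = {f"p{i}": -1e-6 * i for i in range(1, 13)}
        null = {f"p{i}": -1e-6 * i - 1e-5 for i in range(1, 13)}
        res = paired_resilience_test(evolved, null, scheme="uniform_all", alternative="greater")
        assert float(f"{res.p_value:.2g}") == 0.00024
        assert res.n == 12

    def test_replicate_iterables_are_averaged(self):
        evolved = {"p1": 0.0, "p2": 0.1, "p3": 0.2}
        null = {"p1": [-0.2, -0.4], "p2": [0.0, -0.1], "p3": [0.1, 0.0]}
        res = paired_resilience_test(evolved, null, alternative="greater")
        direct = wilcoxon_signed_rank_exact([0.3, 0.15, 0.15], "greater")
        assert res.p_value == direct.p_value

    def test_identical_series_error(self):
        evolved = {"p1": 0.1, "p2": 0.2}
        with pytest.raises(ValueError, match="zero"):
            paired_resilience_test(evolved, dict(evolved))

    def test_mismatched_population_sets(self):
        with pytest.raises(ValueError, match="differ"):
            paired_resilience_test({"p1": 0.1}, {"p2": 0.1})

    def test_shift_invariance(self):
        rng = np.random.default_rng(5)
        evolved = {f"p{i}": float(rng.normal()) for i in range(12)}
        null = {f"p{i}": float(rng.normal()) for i in range(12)}
        base = paired_resilience_test(evolved, null, alternative="greater")
        shifted = paired_resilience_test(
            {k: v + 5.0 for k, v in evolved.items()},
            {k: v + 5.0 for k, v in null.items()},
            alternative="greater",
        )
        assert base.p_value == shifted.p_value

    def test_type_i_error_on_synthetic_null(self):
        # differences symmetric around 0 -> rejection rate ~ alpha
        rng = np.random.default_rng(123)
        n_sims, alpha = 500, 0.05
        rejections = 0
        for _ in range(n_sims):
            evolved = {f"p{i}": float(x) for i, x in enumerate(rng.normal(size=12))}
            null = {f"p{i}": float(x) for i, x in enumerate(rng.normal(size=12))}
            res = paired_resilience_test(evolved, null, alternative="greater")
            rejections += res.p_value <= alpha
        lo, hi = stats.binom.interval(0.999, n_sims, alpha)
        assert lo <= rejections <= hi


class TestRankSum:
    def test_small_sample_exact(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4], alternative="less")
        assert res.p_value == pytest.approx(1 / 6)
        assert res.method == "exact_enumeration"

    def test_identical_samples_two_sided(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], alternative="two_sided")
        assert res.p_value == pytest.approx(1.0)

    def test_large_sample_flags_normal_approximation(self):
        rng = np.random.default_rng(1)
        res = wilcoxon_rank_sum(rng.normal(size=30), rng.normal(size=30))
        assert res.method == "normal_approximation"

    def test_small_tied_samples_stay_exact(self):
        res = wilcoxon_rank_sum([1, 1, 2], [2, 3, 3])
        assert res.method == "exact_enumeration"

    def test_empty_sample_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize("alternative", ["greater", "less", "two_sided"])
    def test_brute_force_oracle(self, alternative):
        rng = np.random.default_rng(29)
        for _ in range(25):
            n1 = int(rng.integers(2, 8))
            n2 = int(rng.integers(2, 8))
            pooled = rng.permutation(np.arange(1, n1 + n2 + 1, dtype=float))
            x, y = pooled[:n1], pooled[n1:]
            ours = wilcoxon_rank_sum(x, y, alternative)
            oracle = rank_sum_brute(x, y, alternative)
            assert ours.p_value == pytest.approx(oracle, abs=1e-12)


class TestBinomialTail:
    def test_printed_count_deficit(self):
        # 44 essential-gene hits of 941, null 499,180/3,962,143
        res = binomial_tail(44, 941, 499_180 / 3_962_143, alternative="less")
        assert res.p_value < 1e-15

    def test_degenerate_p0_one(self):
        res = binomial_tail(5, 5, 1.0, alternative="less")
        assert res.p_value == pytest.approx(1.0)

    def test_two_trials(self):
        res = binomial_tail(0, 2, 0.5, alternative="less")
        assert res.p_value == pytest.approx(0.25)

    def test_invalid_ranges(self):
        with pytest.raises(ValueError):
            binomial_tail(5, 2, 0.5)
        with pytest.raises(ValueError):
            binomial_tail(1, 2, 1.5)


class TestFisherExact:
    def test_printed_essential_parallelism_table(self):
        res = fisher_exact_2x2([[23, 518], [34, 3537]], alternative="greater")
        assert res.p_value < 1e-6

    def test_diagonal_table(self):
        res = fisher_exact_2x2([[2, 0], [0, 2]], alternative="greater")
        assert res.p_value == pytest.approx(1 / 6)

    def test_zero_margin(self):
        res = fisher_exact_2x2([[0, 0], [3, 4]], alternative="two_sided")
        assert res.p_value == pytest.approx(1.0)

    def test_negative_counts(self):
        with pytest.raises(ValueError, match="negative"):
            fisher_exact_2x2([[1, -1], [0, 2]])

    @pytest.mark.parametrize("alternative", ["greater", "less"])
    def test_brute_force_oracle_one_sided(self, alternative):
        rng = np.random.default_rng(31)
        for _ in range(40):
            table = rng.integers(0, 8, size=(2, 2))
            ours = fisher_exact_2x2(table, alternative)
            oracle = fisher_brute(table.tolist(), alternative)
            assert ours.p_value == pytest.approx(oracle, rel=1e-9)

    def test_brute_force_oracle_two_sided(self):
        rng = np.random.default_rng(37)
        for _ in range(40):
            table = rng.integers(0, 8, size=(2, 2))
            ours = fisher_exact_2x2(table, "two_sided")
            oracle = fisher_brute(table.tolist(), "two_sided")
            assert ours.p_value == pytest.approx(oracle, rel=1e-6)


class TestPearson:
    def test_perfect_negative(self):
        x = np.arange(10.0)
        res = pearson_correlation(x, -x)
        assert res.statistic == pytest.approx(-1.0)

    def test_independent_series_small_r(self):
        rng = np.random.default_rng(2)
        res = pearson_correlation(rng.normal(size=1000), rng.normal(size=1000))
        assert abs(res.statistic) < 0.1

    def test_near_perfect_linearity(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0, 1, 50)
        res = pearson_correlation(x, 2 * x + rng.normal(0, 1e-3, 50))
        assert res.statistic > 0.99

    def test_zero_variance_error(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPValueBounds:
    def test_one_sided_le_two_sided(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            d = rng.normal(size=8)
            one = min(
                wilcoxon_signed_rank_exact(d, "greater").p_value,
                wilcoxon_signed_rank_exact(d, "less").p_value,
            )
            two = wilcoxon_signed_rank_exact(d, "two_sided").p_value
            assert one <= two + 1e-12
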