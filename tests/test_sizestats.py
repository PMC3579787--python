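import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import brute_moments, nct_cdf_by_integration, oracle_power_n
from nemameter.sizestats import (
    PowerSpec,
    achieved_power,
    balanced_subsample_ttest,
    compare_slopes,
    excess_kurtosis,
    power_sample_size,
    sample_skewness,
    shape_table,
    size_table,
)


class TestMoments:
    def test_symmetric_sample_has_zero_skewness(self):
        assert sample_skewness([1, 2, 3]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_skewness(self):
        # {0,0,0,1}: m2 = 0.1875, m3 = 0.09375 -> g1 = 2/sqrt(3)
        assert sample_skewness([0, 0, 0, 1]) == pytest.approx(1.1547005, abs=1e-6)

    def test_skewness_negates_under_reflection(self, rng):
        xs = rng.gamma(2.0, size=50)
        assert sample_skewness(-xs) == pytest.approx(-sample_skewness(xs))

    def test_three_point_kurtosis(self):
        # {1,2,3}: m2 = 2/3, m4 = 2/3 -> g2 = -1.5
        assert excess_kurtosis([1, 2, 3]) == pytest.approx(-1.5, abs=1e-12)

    def test_kurtosis_affine_invariant(self, rng):
        xs = rng.normal(size=40)
        assert excess_kurtosis(3.2 * xs - 7) == pytest.approx(
            excess_kurtosis(xs), rel=1e-9)

    def test_normal_sample_kurtosis_near_zero(self):
        xs = np.random.default_rng(123).normal(size=100_000)
        se = np.sqrt(24 / len(xs))
        assert abs(excess_kurtosis(xs)) <= 3 * se

    def test_matches_brute_force_moments(self, rng):
        for _ in range(20):
            xs = rng.lognormal(size=int(rng.integers(5, 200)))
            _, _, _, g1, g2 = brute_moments(xs)
            assert sample_skewness(xs) == pytest.approx(g1, rel=1e-12)
            assert excess_kurtosis(xs) == pytest.approx(g2, rel=1e-12)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            sample_skewness([1, 1, 1])
        with pytest.raises(ValueError):
            sample_skewness([1, 2])


class TestBalancedSubsampleTtest:
    def test_identical_groups_capped_at_one(self):
        xs = np.arange(20.0)
        p = balanced_subsample_ttest([xs], [xs], n_iter=10,
                                     n_comparisons=5, seed=0)
        assert p == 1.0

    def test_strong_separation_is_significant(self):
        rng = np.random.default_rng(42)
        a = rng.normal(0, 1, 50)
        b = rng.normal(5, 1, 50)
        p = balanced_subsample_ttest([a], [b], n_iter=100, seed=1)
        assert p < 1e-6

    def test_reduces_to_plain_t_test_when_balanced(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 30)
        p = balanced_subsample_ttest([a], [b], n_iter=1, n_comparisons=1,
                                     seed=0)
        assert p == pytest.approx(stats.ttest_ind(a, b).pvalue, rel=1e-12)

    def test_subsamples_larger_group(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 200)
        b = rng.normal(0, 1, 20)
        p = balanced_subsample_ttest([a], [b], n_iter=50, seed=9)
        assert 0 <= p <= 1

    def test_seeded_runs_bit_reproducible(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 80), rng.normal(0.3, 1, 33)
        p1 = balanced_subsample_ttest([a], [b], n_iter=200, seed=17)
        p2 = balanced_subsample_ttest([a], [b], n_iter=200, seed=17)
        assert p1 == p2

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            balanced_subsample_ttest([[1.0]], [[1.0, 2.0]], seed=0)


class TestCompareSlopes:
    def test_same_data_gives_p_one(self, rng):
        x = np.linspace(0, 10, 20)
        y = 2 * x + rng.normal(0, 0.5, 20)
        cmp = compare_slopes(x, y, x, y)
        assert cmp.t_stat == pytest.approx(0.0, abs=1e-12)
        assert cmp.p == pytest.approx(1.0)

    def test_noiseless_distinct_slopes(self):
        x = np.linspace(0, 10, 10)
        cmp = compare_slopes(x, 1.0 * x, x, 2.0 * x + 1)
        assert cmp.se_diff == 0.0
        assert cmp.p == 0.0

    def test_degrees_of_freedom(self, rng):
        x1, x2 = rng.normal(size=12), rng.normal(size=9)
        cmp = compare_slopes(x1, rng.normal(size=12), x2, rng.normal(size=9))
        assert cmp.df == 12 + 9 - 4

    def test_calibration_under_equal_slopes(self):
        # equal true slopes: p should be uniform, rejections at alpha=0.05
        # should land near 5%
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            x1, x2 = rng.uniform(0, 10, 25), rng.uniform(0, 10, 25)
            y1 = 1.5 * x1 + rng.normal(0, 1, 25)
            y2 = 1.5 * x2 + rng.normal(0, 1, 25)
            if compare_slopes(x1, y1, x2, y2).p < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            compare_slopes([1, 1, 1], [1, 2, 3], [1, 2, 3], [1, 2, 3])


class TestPowerAnalysis:
    def test_unit_effect_sample_size_vs_oracle(self):
        res = power_sample_size(PowerSpec(alpha=0.05, beta=0.2,
                                          delta=1.0, sigma=1.0))
        assert res.n_real == pytest.approx(16.71, abs=0.05)
        assert res.n_real == pytest.approx(
            oracle_power_n(0.05, 0.2, 1.0), rel=1e-3)

    def test_double_effect_sample_size_vs_oracle(self):
        res = power_sample_size(PowerSpec(alpha=0.05, beta=0.2,
                                          delta=2.0, sigma=1.0))
        assert res.n_real == pytest.approx(5.1, abs=0.05)
        assert res.n_real == pytest.approx(
            oracle_power_n(0.05, 0.2, 2.0), rel=1e-3)

    def test_nct_cdf_against_integration(self):
        assert stats.nct.cdf(2.0, 10, 1.5) == pytest.approx(
            nct_cdf_by_integration(2.0, 10, 1.5), abs=1e-8)

    def test_monotone_in_effect_and_alpha(self):
        n1 = power_sample_size(PowerSpec(delta=0.10, sigma=0.21)).n_real
        n2 = power_sample_size(PowerSpec(delta=0.15, sigma=0.21)).n_real
        n3 = power_sample_size(PowerSpec(alpha=0.05, delta=0.15,
                                         sigma=0.21)).n_real
        assert n1 > n2 > n3

    def test_achieved_power_at_ceiling(self):
        spec = PowerSpec(alpha=0.01, beta=0.2, delta=0.15, sigma=0.21)
        res = power_sample_size(spec)
        assert achieved_power(res.n, spec) >= 1 - spec.beta

    def test_normal_approximation_for_large_n(self):
        spec = PowerSpec(alpha=0.01, beta=0.2, delta=0.10, sigma=0.21)
        res = power_sample_size(spec)
        z = stats.norm.ppf
        approx = 2 * (z(1 - spec.alpha / 2) + z(1 - spec.beta)) ** 2 \
            / (spec.delta / spec.sigma) ** 2
        assert res.n_real > 50
        assert res.n_real == pytest.approx(approx, rel=0.05)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec(alpha=0.0)
        with pytest.raises(ValueError):
            PowerSpec(delta=-1.0)


def synthetic_population(rng, strain, mean_scale, n=40, reps=2):
    rows = []
    for rep in range(reps):
        for t in (0, 48):
            growth = 1.0 + 30.0 * t / 48.0
            length = rng.normal(205 * mean_scale * growth ** 0.5, 8, n)
            width = 0.081 * length * mean_scale + rng.normal(0, 1.5, n)
            rows.append(pd.DataFrame({
                "strain": strain, "replicate": rep, "time": t,
                "length_um": length, "mid_width_um": width,
                "volume_pl": np.pi * (width / 2) ** 2 * length / 1000.0}))
    return pd.concat(rows, ignore_index=True)


@pytest.fixture(scope="module")
def population():
    rng = np.random.default_rng(99)
    return pd.concat([synthetic_population(rng, "N2", 1.0),
                      synthetic_population(rng, "dpy-like", 0.8)],
                     ignore_index=True)


class TestTables:
    def test_size_table_shape_and_significance(self, population):
        table = size_table(population, "N2", n_iter=50, seed=0)
        assert set(table["strain"]) == {"dpy-like"}
        assert len(table) == 2  # two time points
        # a 20% shorter strain at n=80/group must come out significant
        assert (table["length_um_p"] < 0.01).all()
        assert table["volume_skewness"].notna().all()

    def test_shape_table_detects_slope_difference(self, population):
        table = shape_table(population, "N2")
        row = table[table["strain"] == "dpy-like"].iloc[0]
        n2 = table[table["strain"] == "N2"].iloc[0]
        # the mutant's width-on-length slope was generated shallower
        assert row["slope"] < n2["slope"]
        assert 0 <= row["p"] <= 1
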