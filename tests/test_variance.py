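from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from lifespans import (
    HazardCurve,
    SurvivalDataset,
    chow_test,
    km_estimate,
    log_cumulative_hazard,
    normalized_chow_test,
    partial_slopes,
    partial_slopes_ranksum_test,
    ranksum_on_slopes,
    reconstruct_death_times,
    shapiro_wilk_test,
    survival_time_f_test,
)

from conftest import gaussian_pair, random_dataset


def curve(ds):
    return log_cumulative_hazard(km_estimate(ds))


class TestReconstruction:
    def test_uncensored_passthrough(self, uncensored_ds):
        t, w, warns = reconstruct_death_times(uncensored_ds)
        assert list(t) == [18, 20, 22]
        assert list(w) == [1, 1, 1]
        assert not warns

    def test_censored_mass_moves_to_later_deaths(self):
        ds = SurvivalDataset.from_records("x", [(1, 1, 1), (2, 1, 0)])
        t, w, warns = reconstruct_death_times(ds)
        assert list(t) == [1, 2]
        assert w[0] == pytest.approx(1.0)
        assert w[1] == pytest.approx(2.0)
        assert not warns

    def test_censored_after_last_death_truncated_with_warning(self):
        ds = SurvivalDataset.from_records("x", [(1, 1, 0), (2, 0, 1)])
        t, w, warns = reconstruct_death_times(ds)
        assert list(t) == [1]
        assert w[0] == pytest.approx(1.0)
        assert len(warns) == 1

    def test_total_weight_bounded_by_cohort_size(self):
        rng = np.random.default_rng(307)
        for _ in range(100):
            ds = random_dataset(rng, n_max=20)
            _, w, _ = reconstruct_death_times(ds)
            assert w.sum() <= ds.n_total + 1e-9
            assert w.sum() >= ds.n_deaths - 1e-9

    def test_all_censored_is_error(self):
        ds = SurvivalDataset.from_records("x", [(5, 0, 4)])
        with pytest.raises(ValueError):
            reconstruct_death_times(ds)


class TestSurvivalTimeF:
    def test_identical_groups(self, uncensored_ds):
        res = survival_time_f_test(uncensored_ds, uncensored_ds)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_example(self, uncensored_ds):
        other = SurvivalDataset.from_records("o", [(16, 1, 0), (20, 1, 0), (24, 1, 0)])
        res = survival_time_f_test(uncensored_ds, other)
        assert res.statistic == pytest.approx(0.25)  # 4 / 16
        assert res.p_value == pytest.approx(0.4)  # F(2,2): 2 * 0.25/1.25
        assert res.df == (2, 2)

    def test_reciprocal_symmetry(self):
        rng = np.random.default_rng(311)
        for _ in range(50):
            ds1 = random_dataset(rng, n_max=20)
            ds2 = random_dataset(rng, n_max=20)
            try:
                r12 = survival_time_f_test(ds1, ds2)
                r21 = survival_time_f_test(ds2, ds1)
            except ValueError:
                continue
            if np.isfinite(r12.statistic) and r12.statistic > 0:
                assert r12.statistic * r21.statistic == pytest.approx(1.0, rel=1e-9)
            assert r12.p_value == pytest.approx(r21.p_value, rel=1e-9, abs=1e-12)

    def test_normality_gate_warns_on_exponential_lifespans(self):
        rng = np.random.default_rng(313)
        t = np.ceil(rng.exponential(10, 80))
        ds = SurvivalDataset.from_subjects("exp", t, np.ones(80, dtype=int))
        res = survival_time_f_test(ds, ds)
        assert any("not applicable" in w for w in res.warnings)

    def test_power_and_level_on_gaussian_cohorts(self):
        """SD 2 vs 4 is rejected nearly always; equal SDs near the 5% level."""
        rej_alt = rej_null = 0
        for r in range(200):
            a, b = gaussian_pair(120_000 + r, n=100, sd1=2.0, sd2=4.0)
            rej_alt += survival_time_f_test(a, b).p_value < 0.05
            c, d = gaussian_pair(121_000 + r, n=100, mean1=20.0, mean2=30.0)
            rej_null += survival_time_f_test(c, d).p_value < 0.05
        assert rej_alt / 200 >= 0.95
        assert 0.02 <= rej_null / 200 <= 0.10


class TestShapiroWilk:
    def test_three_point_linear_sample(self):
        res = shapiro_wilk_test([1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            shapiro_wilk_test([1.0, 2.0])

    def test_rejects_exponential_sample(self):
        rng = np.random.default_rng(317)
        res = shapiro_wilk_test(rng.exponential(1.0, 50))
        assert res.p_value < 0.01

    def test_level_on_normal_samples(self):
        ok = 0
        for seed in range(200):
            rng = np.random.default_rng(130_000 + seed)
            if shapiro_wilk_test(rng.normal(0, 1, 50)).p_value > 0.01:
                ok += 1
        assert ok >= 190


class TestPartialSlopes:
    def test_linear_curve(self):
        h = HazardCurve(np.array([1.0, 2, 3]), np.array([0.0, 1, 2]))
        assert np.allclose(partial_slopes(h), [1, 1])

    def test_half_slope(self):
        h = HazardCurve(np.array([0.0, 2]), np.array([0.0, 1]))
        assert np.allclose(partial_slopes(h), [0.5])

    def test_vertical_shift_invariance(self):
        rng = np.random.default_rng(331)
        t = np.sort(rng.uniform(0, 10, 8))
        y = np.cumsum(rng.exponential(1, 8))
        assert np.allclose(
            partial_slopes(HazardCurve(t, y)), partial_slopes(HazardCurve(t, y + 3.7))
        )

    def test_duplicate_times_error(self):
        with pytest.raises(ValueError):
            partial_slopes(HazardCurve(np.array([1.0, 1.0]), np.array([0.0, 1.0])))


class TestRanksum:
    def test_identical_sets(self):
        res = ranksum_on_slopes([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_extreme_separation_exact(self):
        res = ranksum_on_slopes([1, 2, 3], [4, 5, 6])
        assert res.extras["exact"]
        assert res.p_value == pytest.approx(0.1)  # 2 * 2/C(6,3)... = 2/20*... = 0.1

    def test_exact_matches_enumeration(self):
        """Exact rank-sum p equals brute-force enumeration of assignments."""
        rng = np.random.default_rng(337)
        for _ in range(20):
            x = rng.normal(size=4)
            y = rng.normal(size=5)
            res = ranksum_on_slopes(x, y)
            pooled = np.concatenate([x, y])
            u_obs = res.extras["U"]
            mu = 4 * 5 / 2
            count = 0
            combos = list(combinations(range(9), 4))
            for idx in combos:
                mask = np.zeros(9, bool)
                mask[list(idx)] = True
                ranks = stats.rankdata(pooled)
                u = ranks[mask].sum() - 4 * (4 + 1) / 2
                if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
                    count += 1
            assert res.p_value == pytest.approx(count / len(combos), abs=1e-9)

    def test_exact_close_to_normal_approximation(self):
        """For balanced sets of size 10 the exact and approximate p agree."""
        rng = np.random.default_rng(341)
        for _ in range(10):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            p_exact = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            p_approx = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
            assert p_approx == pytest.approx(p_exact, abs=0.02)

    def test_six_point_minimum_enforced(self):
        a = SurvivalDataset.from_records("a", [(t, 2, 0) for t in (1, 2, 3, 4)])
        b = SurvivalDataset.from_records("b", [(t, 2, 0) for t in (1, 2, 3, 4, 5, 6, 7)])
        with pytest.raises(ValueError, match="six"):
            partial_slopes_ranksum_test(a, b)

    def test_low_power_warning_for_few_points(self):
        a = SurvivalDataset.from_records("a", [(t, 3, 0) for t in range(1, 9)])
        b = SurvivalDataset.from_records("b", [(t, 3, 0) for t in range(1, 9)])
        res = partial_slopes_ranksum_test(a, b)
        assert any("low" in w for w in res.warnings)

    def test_detects_spread_difference_on_cohorts(self):
        rej_alt = rej_null = 0
        for r in range(200):
            a, b = gaussian_pair(140_000 + r, n=150, sd1=2.0, sd2=4.0)
            try:
                rej_alt += partial_slopes_ranksum_test(a, b).p_value < 0.05
            except ValueError:
                pass
            c, d = gaussian_pair(141_000 + r, n=150, sd1=4.0, sd2=4.0)
            try:
                rej_null += partial_slopes_ranksum_test(c, d).p_value < 0.05
            except ValueError:
                pass
        assert rej_alt / 200 > rej_null / 200


class TestNormalizedChow:
    def test_identical_curves(self):
        h = HazardCurve(np.arange(1.0, 9), np.cumsum(np.full(8, 0.4)) + np.sin(np.arange(8)) * 0.05)
        res = normalized_chow_test(h, h)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_vertical_shift_invariance_vs_plain_chow(self):
        rng = np.random.default_rng(347)
        t = np.sort(rng.uniform(0, 10, 8))
        y = np.cumsum(rng.exponential(0.5, 8))
        h1 = HazardCurve(t, y)
        h2 = HazardCurve(t, y + 2.0)
        res = normalized_chow_test(h1, h2)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)
        # the un-normalized Chow test does see the shift
        plain = chow_test(h1, h2, k=3)
        assert plain.statistic > 10

    def test_independent_shifts_of_either_curve(self):
        rng = np.random.default_rng(349)
        t1, t2 = np.sort(rng.uniform(0, 10, 7)), np.sort(rng.uniform(0, 10, 9))
        y1, y2 = np.cumsum(rng.exponential(1, 7)), np.cumsum(rng.exponential(1, 9))
        base = normalized_chow_test(HazardCurve(t1, y1), HazardCurve(t2, y2))
        shifted = normalized_chow_test(
            HazardCurve(t1, y1 - 5.0), HazardCurve(t2, y2 + 11.0)
        )
        assert shifted.statistic == pytest.approx(base.statistic, rel=1e-9)

    def test_slope_difference_detected(self):
        rng = np.random.default_rng(353)
        t = np.linspace(1, 10, 10)
        h1 = HazardCurve(t, 1.0 * t + rng.normal(0, 0.01, 10))
        h2 = HazardCurve(t, 3.0 * t + rng.normal(0, 0.01, 10))
        res = normalized_chow_test(h1, h2)
        assert res.statistic > 0
        assert res.p_value < 0.05

    def test_degenerate_df_error(self):
        h = HazardCurve(np.array([1.0, 2.0]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="smaller k"):
            normalized_chow_test(h, h, k=3)
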