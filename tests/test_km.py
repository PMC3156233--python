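import numpy as np
import pytest
from lifelines import KaplanMeierFitter

from lifespans import (
    LifespanWarning,
    SurvivalDataset,
    km_estimate,
    log_cumulative_hazard,
    summary_stats,
)
from lifespans.simulate import SimulationSpec, simulate_lifespans

from conftest import random_dataset


def brute_force_km(ds):
    """Hand product-limit: walk the records keeping explicit risk counts."""
    at_risk = ds.n_total
    s = 1.0
    var_sum = 0.0
    out = []
    for t, d, c in zip(ds.times, ds.deaths, ds.censored):
        if d > 0:
            s *= 1.0 - d / at_risk
            if at_risk > d:
                var_sum += d / (at_risk * (at_risk - d))
            out.append((t, s, s**2 * var_sum, at_risk, d))
        at_risk -= d + c
    return out


class TestKMEstimate:
    def test_hand_example(self, simple_ds):
        km = km_estimate(simple_ds)
        assert np.allclose(km.survival, [0.75, 0.5])
        assert list(km.event_times) == [10, 20]
        assert list(km.at_risk) == [4, 3]

    def test_complete_mortality(self):
        ds = SurvivalDataset.from_records("c", [(1, 1, 0), (2, 1, 0)])
        km = km_estimate(ds)
        assert np.allclose(km.survival, [0.5, 0.0])

    def test_no_deaths_warns_and_survival_is_one(self):
        ds = SurvivalDataset.from_records("n", [(10, 0, 5)])
        with pytest.warns(LifespanWarning, match="no deaths"):
            km = km_estimate(ds)
        assert km.event_times.size == 0
        assert km.survival_at(100.0) == 1.0

    def test_censoring_convention_censored_at_t_leave_after_deaths(self):
        # the subject censored at 10 is at risk for the death at 10
        ds = SurvivalDataset.from_records("x", [(10, 1, 1), (20, 1, 0)])
        km = km_estimate(ds)
        assert np.allclose(km.survival, [2 / 3, 0.0])

    def test_matches_brute_force_and_lifelines_on_random_data(self):
        rng = np.random.default_rng(42)
        kmf = KaplanMeierFitter()
        for _ in range(200):
            ds = random_dataset(rng)
            km = km_estimate(ds)
            oracle = brute_force_km(ds)
            assert len(oracle) == km.event_times.size
            for j, (t, s, gw, n, d) in enumerate(oracle):
                assert km.event_times[j] == t
                assert km.survival[j] == pytest.approx(s, abs=1e-12)
                assert km.greenwood_var[j] == pytest.approx(gw, abs=1e-12)
                assert km.at_risk[j] == n and km.deaths[j] == d
            times, status = ds.to_subjects()
            kmf.fit(times, status)
            ll = kmf.survival_function_at_times(km.event_times).to_numpy()
            assert np.allclose(km.survival, ll, atol=1e-10)

    def test_no_censoring_survival_is_one_minus_ecdf(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            ds = random_dataset(rng, censoring=False)
            km = km_estimate(ds)
            times, _ = ds.to_subjects()
            for t, s in zip(km.event_times, km.survival):
                assert s == pytest.approx(1.0 - np.mean(times <= t), abs=1e-12)

    def test_survival_left_limit(self, simple_ds):
        km = km_estimate(simple_ds)
        assert km.survival_at(10.0, side="left") == 1.0
        assert km.survival_at(10.0, side="right") == 0.75
        assert km.survival_at(15.0, side="left") == 0.75


class TestSummaryStats:
    def test_restricted_mean_hand_example(self, simple_ds):
        st = summary_stats(km_estimate(simple_ds), simple_ds)
        # 10*1 + 10*0.75 + 10*0.5
        assert st.restricted_mean == pytest.approx(22.5)
        assert st.median == 20
        assert st.ci95[0] == pytest.approx(st.restricted_mean - 1.96 * st.restricted_mean_se)

    def test_uncensored_restricted_mean_is_sample_mean(self, uncensored_ds):
        st = summary_stats(km_estimate(uncensored_ds), uncensored_ds)
        assert st.restricted_mean == pytest.approx(20.0, abs=1e-12)

    def test_uncensored_mean_matches_on_random_data(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            ds = random_dataset(rng, censoring=False)
            st = summary_stats(km_estimate(ds), ds)
            times, _ = ds.to_subjects()
            assert st.restricted_mean == pytest.approx(times.mean(), rel=1e-12)

    def test_last_subject_censored_makes_100pct_undefined(self):
        ds = SurvivalDataset.from_records("d", [(10, 3, 0), (20, 0, 1)])
        st = summary_stats(km_estimate(ds), ds)
        assert st.percentile_ages[100] is None
        assert st.percentile_ages[25] == 10

    def test_percentiles_nondecreasing(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            ds = random_dataset(rng, n_max=20)
            st = summary_stats(km_estimate(ds), ds)
            defined = [v for v in st.percentile_ages.values() if v is not None]
            assert all(x <= y for x, y in zip(defined, defined[1:]))

    def test_restricted_mean_against_lifelines(self):
        from lifelines.utils import restricted_mean_survival_time

        rng = np.random.default_rng(17)
        for _ in range(20):
            ds = random_dataset(rng, n_max=20)
            km = km_estimate(ds)
            tau = float(ds.times[-1])
            st = summary_stats(km, ds, tau=tau)
            times, status = ds.to_subjects()
            kmf = KaplanMeierFitter().fit(times, status)
            rmst = restricted_mean_survival_time(kmf, t=tau)
            assert st.restricted_mean == pytest.approx(rmst, rel=1e-9)

    def test_restricted_mean_se_matches_reference_values(self, simple_ds):
        # expected values computed with R survival::survfit on the same data
        st = summary_stats(km_estimate(simple_ds), simple_ds)
        assert st.restricted_mean_se == pytest.approx(4.145781, abs=1e-6)
        ds = SurvivalDataset.from_subjects(
            "ref",
            np.array([3, 5, 5, 7, 9, 9, 9, 12, 14, 14, 2, 6, 10], dtype=float),
            np.array([1, 1, 1, 1, 1, 1, 0, 1, 1, 0, 0, 1, 1]),
        )
        st = summary_stats(km_estimate(ds), ds)
        assert st.restricted_mean == pytest.approx(8.875, abs=1e-9)
        assert st.restricted_mean_se == pytest.approx(1.05161912201, abs=1e-8)


class TestLogCumulativeHazard:
    def test_closed_form_point(self):
        ds = SurvivalDataset.from_records("h", [(20, 1, 0), (30, 1, 0)])
        h = log_cumulative_hazard(km_estimate(ds))
        assert h.times[0] == 20
        assert h.y[0] == pytest.approx(np.log(np.log(2)), abs=1e-12)

    def test_all_survival_one_is_error(self):
        ds = SurvivalDataset.from_records("n", [(10, 0, 5)])
        with pytest.warns(LifespanWarning):
            km = km_estimate(ds)
        with pytest.raises(ValueError, match="hazard curve"):
            log_cumulative_hazard(km)

    def test_monotone_nondecreasing_on_random_data(self):
        rng = np.random.default_rng(23)
        checked = 0
        for _ in range(1000):
            ds = random_dataset(rng, n_max=25)
            km = km_estimate(ds)
            usable = (km.survival > 0) & (km.survival < 1)
            if usable.sum() < 2:
                continue
            for estimator in ("km", "nelson-aalen"):
                h = log_cumulative_hazard(km, estimator=estimator)
                assert np.all(np.diff(h.y) >= -1e-12)
            checked += 1
        assert checked > 500

    def test_exponential_slope_vs_log_time_is_one(self):
        spec = SimulationSpec("exponential", {"rate": 0.1}, n=5000, round_to_days=False)
        ds = simulate_lifespans(spec, seed=3)
        h = log_cumulative_hazard(km_estimate(ds))
        slope = np.polyfit(np.log(h.times), h.y, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_nelson_aalen_option_differs_but_tracks(self, simple_ds):
        km = km_estimate(simple_ds)
        h_km = log_cumulative_hazard(km, estimator="km")
        h_na = log_cumulative_hazard(km, estimator="nelson-aalen")
        assert h_na.y[0] == pytest.approx(np.log(0.25))
        assert not np.allclose(h_km.y, h_na.y)
        assert np.allclose(h_km.y, h_na.y, atol=0.3)
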