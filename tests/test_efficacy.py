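"""Tumor volume, doubling time, humane endpoints, Kaplan-Meier, log-rank."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alphachain import efficacy
from alphachain.efficacy import (
    EndpointRules,
    apply_humane_endpoints,
    build_survival_table,
    ellipsoid_volume,
    fit_doubling_time,
    km_curve,
    logrank_test,
)
from alphachain.synthetic import EfficacyTruth, GroupTruth, simulate_efficacy_cohort
from alphachain.units import LN2


class TestEllipsoidVolume:
    def test_unit_sphere(self):
        assert ellipsoid_volume(1, 1, 1) == pytest.approx(4 * math.pi / 3)

    def test_known_product(self):
        assert ellipsoid_volume(3, 4, 5) == pytest.approx(4 * math.pi / 3 * 60)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(a=st.floats(0.1, 20), b=st.floats(0.1, 20), c=st.floats(0.1, 20))
    def test_linearity_in_each_radius(self, a, b, c):
        assert ellipsoid_volume(2 * a, b, c) == pytest.approx(
            2 * ellipsoid_volume(a, b, c), rel=1e-12)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            ellipsoid_volume(0, 1, 1)


def exp_series(td=30.0, v0=50.0, days=None):
    days = days if days is not None else np.arange(0, 60, 3.5)
    v = v0 * 2 ** (days / td)
    return pd.DataFrame({"day": days, "volume_mm3": v})


class TestDoublingTime:
    def test_noiseless_exponential_exact(self):
        fit = fit_doubling_time(exp_series(td=30.0), animal_id="a")
        assert fit.doubling_time == pytest.approx(30.0, rel=1e-12)
        assert fit.included
        assert fit.r_squared == pytest.approx(1.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(td=st.floats(5.0, 120.0),
           grid=st.lists(st.floats(0, 100), min_size=3, max_size=12,
                         unique_by=lambda x: round(x, 3)))
    def test_exact_on_any_sampling_grid(self, td, grid):
        fit = fit_doubling_time(exp_series(td=td, days=np.sort(grid)), "a")
        assert fit.doubling_time == pytest.approx(td, rel=1e-6)

    def test_shrinking_tumor_excluded_not_error(self):
        fit = fit_doubling_time(exp_series(td=-20.0), animal_id="a")
        assert not fit.included
        assert math.isnan(fit.doubling_time)
        assert "decreased" in fit.reason

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_doubling_time(exp_series(days=np.array([0.0, 3.0])), "a")

    def test_zero_volume_rejected(self):
        df = pd.DataFrame({"day": [0, 3, 7], "volume_mm3": [10.0, 0.0, 5.0]})
        with pytest.raises(ValueError):
            fit_doubling_time(df, "a")

    def test_doubling_time_rate_identity(self):
        fit = fit_doubling_time(exp_series(td=45.0), "a")
        assert fit.doubling_time * fit.rate == pytest.approx(LN2, rel=1e-9)

    def test_cohort_mean_recovery_with_caliper_noise(self):
        """n = 10 animals, 5% caliper cv, truth Td = 31.9 d: cohort mean
        recovered within 10%."""
        truth = EfficacyTruth(groups=(
            GroupTruth("control", 82.9, ((21.0, LN2 / 31.9),), caliper_cv=0.05),))
        sim = simulate_efficacy_cohort(truth, 10, seed=20)
        fits = efficacy.fit_growth_cohort(sim.tumors)
        mean_td = fits.loc[fits.included, "doubling_time_day"].mean()
        assert abs(mean_td - 31.9) / 31.9 < 0.10


def vol_series(days, volumes, animal="a"):
    return pd.DataFrame({"animal_id": animal, "day": days, "volume_mm3": volumes})


def weight_series(days, weights, animal="a"):
    return pd.DataFrame({"animal_id": animal, "day": days, "weight_g": weights})


class TestHumaneEndpoints:
    def test_volume_crossing(self):
        rec = apply_humane_endpoints(
            vol_series([90, 95, 99], [1500, 1900, 2100]), None)
        assert rec.event and rec.time == 99 and rec.cause == "volume"

    def test_censored_at_study_end(self):
        rec = apply_humane_endpoints(
            vol_series([90, 149], [500, 600]), None)
        assert not rec.event
        assert rec.time == 150 and rec.cause == "study-end-censor"

    def test_chronic_weight_loss(self):
        rec = apply_humane_endpoints(
            vol_series([30, 40, 50], [100, 110, 120]),
            weight_series([26, 33, 40], [20.0, 19.0, 15.5]))
        assert rec.event and rec.cause == "weight-loss-chronic"
        assert rec.time == pytest.approx(40, abs=2)

    def test_acute_weight_loss(self):
        rec = apply_humane_endpoints(
            vol_series([30, 40, 50], [100, 110, 120]),
            weight_series([26, 33, 35], [20.0, 20.0, 16.0]))
        assert rec.event and rec.cause == "weight-loss-acute"

    def test_flag_event(self):
        flags = pd.DataFrame({"day": [60.0], "cause": ["ulceration"]})
        rec = apply_humane_endpoints(
            vol_series([30, 60, 90], [100, 120, 140]), None, flags=flags)
        assert rec.event and rec.cause == "ulceration" and rec.time == 60

    def test_earliest_rule_wins(self):
        flags = pd.DataFrame({"day": [95.0], "cause": ["clinical"]})
        rec = apply_humane_endpoints(
            vol_series([90, 99], [1500, 2100]), None, flags=flags)
        assert rec.cause == "clinical" and rec.time == 95

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            apply_humane_endpoints(vol_series([], []), None)

    def test_truncation_never_yields_earlier_event(self):
        """Monotonicity: truncating the series cannot move the event
        earlier (it can only remove it)."""
        days = [30, 60, 90, 99, 120]
        vols = [100, 400, 1500, 2100, 3000]
        full = apply_humane_endpoints(vol_series(days, vols), None)
        for cut in range(1, len(days) + 1):
            part = apply_humane_endpoints(
                vol_series(days[:cut], vols[:cut]), None)
            if part.event:
                assert part.time >= full.time


class TestKaplanMeier:
    def test_hand_computed_curve(self):
        """Events at 2, 4, 6 with no censoring: S = 2/3, 1/3, 0; median 4."""
        df = pd.DataFrame({"time": [2.0, 4.0, 6.0], "event": [True] * 3})
        curve = km_curve(df)
        lookup = dict(zip(curve.times, curve.survival))
        assert lookup[2.0] == pytest.approx(2 / 3)
        assert lookup[4.0] == pytest.approx(1 / 3)
        assert lookup[6.0] == pytest.approx(0.0)
        assert curve.median == 4.0

    def test_all_censored_median_not_reached(self):
        df = pd.DataFrame({"time": [150.0] * 5, "event": [False] * 5})
        curve = km_curve(df)
        assert np.all(curve.survival == 1.0)
        assert not curve.median_reached
        assert curve.median_label(150) == ">150"

    def test_majority_censored_median_not_reached(self):
        df = pd.DataFrame({"time": [100.0, 120.0, 150.0, 150.0, 150.0],
                           "event": [True, True, False, False, False]})
        assert not km_curve(df).median_reached

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(times=st.lists(st.floats(1.0, 200.0), min_size=1, max_size=20))
    def test_no_censoring_equals_empirical_survivor(self, times):
        """Without censoring the KM estimate is the empirical survival
        function (computed here by direct counting)."""
        df = pd.DataFrame({"time": times, "event": True})
        curve = km_curve(df)
        arr = np.asarray(times)
        for t, s in zip(curve.times, curve.survival):
            if t == 0.0 and 0.0 not in arr:
                continue
            assert s == pytest.approx((arr > t).mean(), abs=1e-12)

    def test_nonincreasing(self):
        df = pd.DataFrame({"time": [3.0, 5.0, 5.0, 9.0, 12.0],
                           "event": [True, True, False, True, False]})
        curve = km_curve(df)
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert curve.survival[0] <= 1.0

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            km_curve(pd.DataFrame({"time": [0.0], "event": [True]}))


def numpy_logrank_chi2(times, events, groups):
    """Independent log-rank statistic by direct risk-table counting."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    groups = np.asarray(groups)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        d = events & (times == t)
        n, dtot = at_risk.sum(), d.sum()
        n1 = (at_risk & (groups == 0)).sum()
        o1 = (d & (groups == 0)).sum()
        e1 = dtot * n1 / n
        o_minus_e += o1 - e1
        if n > 1:
            var += dtot * (n1 / n) * (1 - n1 / n) * (n - dtot) / (n - 1)
    return o_minus_e ** 2 / var


class TestLogrank:
    def test_identical_group_against_itself(self):
        df = pd.DataFrame({"time": [3.0, 5.0, 9.0], "event": [True] * 3})
        stat, p = logrank_test(df, df.copy())
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_no_events_anywhere_signalled(self):
        df = pd.DataFrame({"time": [10.0, 20.0], "event": [False, False]})
        with pytest.raises(ValueError, match="no events"):
            logrank_test(df, df.copy())

    def test_statistic_matches_direct_risk_table(self):
        rng = np.random.default_rng(0)
        a = pd.DataFrame({"time": rng.exponential(50, 12).round(1) + 1,
                          "event": True})
        b = pd.DataFrame({"time": rng.exponential(90, 12).round(1) + 1,
                          "event": True})
        stat, _ = logrank_test(a, b)
        times = np.concatenate([a.time, b.time])
        events = np.ones(24, bool)
        groups = np.repeat([0, 1], 12)
        assert stat == pytest.approx(numpy_logrank_chi2(times, events, groups),
                                     rel=1e-9)

    def test_p_matches_permutation_oracle(self):
        """Chi-square p vs a 10,000-shuffle permutation of the same
        statistic on a small fixture."""
        rng = np.random.default_rng(7)
        n = 15
        times = np.concatenate([rng.exponential(60, n), rng.exponential(110, n)])
        times = np.maximum(times.round(1), 0.5)
        events = np.ones(2 * n, bool)
        groups = np.repeat([0, 1], n)
        a = pd.DataFrame({"time": times[:n], "event": True})
        b = pd.DataFrame({"time": times[n:], "event": True})
        obs_stat, p_chi2 = logrank_test(a, b)
        hits = 0
        nperm = 10_000
        for _ in range(nperm):
            perm = rng.permutation(groups)
            if numpy_logrank_chi2(times, events, perm) >= obs_stat - 1e-12:
                hits += 1
        p_perm = hits / nperm
        mc_se = math.sqrt(p_perm * (1 - p_perm) / nperm)
        assert abs(p_chi2 - p_perm) < max(3 * mc_se, 0.02)

    def test_type_one_error_rate(self):
        """Identical-hazard groups: rejection rate at alpha = 0.05 within
        [0.03, 0.07] over 2,000 replicates."""
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 2_000
        for _ in range(reps):
            t = rng.exponential(60, 20)
            times = np.maximum(t, 1e-3)
            a = pd.DataFrame({"time": times[:10], "event": True})
            b = pd.DataFrame({"time": times[10:], "event": True})
            _, p = logrank_test(a, b)
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestSurvivalTable:
    def test_cohort_events_and_censoring(self):
        truth = EfficacyTruth(groups=(
            GroupTruth("fast", 500.0, ((21.0, LN2 / 10.0),), caliper_cv=0.0),
            GroupTruth("shrink", 100.0, ((21.0, -0.02),), caliper_cv=0.0),
        ))
        sim = simulate_efficacy_cohort(truth, 5, seed=30)
        surv = build_survival_table(sim.tumors, sim.weights)
        fast = surv[surv.group == "fast"]
        shrink = surv[surv.group == "shrink"]
        assert fast["event"].all() and (fast["cause"] == "volume").all()
        assert not shrink["event"].any()
        assert (shrink["time"] == 150.0).all()

    def test_event_times_match_generator_truth(self):
        """Measured (noiseless) endpoint crossings land at the first
        caliper day at or after the continuous truth crossing."""
        truth = EfficacyTruth(groups=(
            GroupTruth("g", 300.0, ((21.0, LN2 / 15.0),), caliper_cv=0.0),))
        sim = simulate_efficacy_cohort(truth, 5, seed=31)
        surv = build_survival_table(sim.tumors, sim.weights)
        merged = surv.merge(sim.truth, on="animal_id")
        assert (merged["time"] >= merged["true_crossing_day"] - 1e-9).all()
        assert (merged["time"] - merged["true_crossing_day"] <= 4.0).all()
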