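"""Endpoint derivation, product-limit estimation and the log-rank test."""

from datetime import date

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from hairyscore.config import default_config
from hairyscore.cohort import generate_survival
from hairyscore.survival import (
    ClinicalDates,
    SurvivalInput,
    compute_endpoints,
    km_fit,
    km_median,
    logrank,
)


class TestComputeEndpoints:
    def test_os_event(self):
        d = ClinicalDates(
            diagnosis=date(2010, 1, 1),
            last_followup=date(2016, 1, 1),
            death=date(2015, 1, 1),
        )
        months, event = compute_endpoints(d)["os"]
        assert months == pytest.approx(1826 / 30.4375)  # ~60 months
        assert event == 1

    def test_ttnt_censored_at_last_followup(self):
        d = ClinicalDates(
            diagnosis=date(2010, 1, 1),
            last_followup=date(2014, 1, 1),
            first_treatment_end=date(2012, 1, 1),
        )
        months, event = compute_endpoints(d)["ttnt"]
        assert months == pytest.approx(24.0, abs=0.1)
        assert event == 0

    def test_pfs_uses_earliest_of_progression_and_death(self):
        d = ClinicalDates(
            diagnosis=date(2010, 1, 1),
            last_followup=date(2016, 1, 1),
            progression=date(2013, 1, 1),
            death=date(2015, 6, 1),
        )
        months, event = compute_endpoints(d)["pfs"]
        assert event == 1
        assert months == pytest.approx((date(2013, 1, 1) - date(2010, 1, 1)).days / 30.4375)

    def test_second_treatment_before_first_end_errors(self):
        d = ClinicalDates(
            diagnosis=date(2010, 1, 1),
            last_followup=date(2016, 1, 1),
            first_treatment_end=date(2012, 1, 1),
            second_treatment_start=date(2011, 1, 1),
        )
        with pytest.raises(ValueError):
            compute_endpoints(d)


class TestKaplanMeier:
    def test_uncensored_equals_empirical_survival(self):
        curve = km_fit(SurvivalInput([1, 2, 3, 4], [1, 1, 1, 1]))
        np.testing.assert_allclose(curve.survival, [0.75, 0.5, 0.25, 0.0])

    def test_hand_computed_product_limit_with_censoring(self):
        # at t=3 the censored subject has left the risk set, so n=1, d=1
        curve = km_fit(SurvivalInput([1, 2, 3], [1, 0, 1]))
        np.testing.assert_allclose(curve.event_times, [1, 3])
        np.testing.assert_allclose(curve.survival, [2 / 3, 0.0])

    def test_censored_subject_keeps_later_risk_sets_smaller(self):
        # censoring at t=2 leaves two subjects at risk for the event at 3
        curve = km_fit(SurvivalInput([1, 2, 3, 3], [1, 0, 1, 0]))
        np.testing.assert_allclose(curve.survival, [3 / 4, 3 / 8])

    def test_all_censored_curve_stays_at_one(self):
        curve = km_fit(SurvivalInput([5, 6, 7], [0, 0, 0]))
        assert curve.event_times.size == 0
        assert curve.survival_at(100.0) == 1.0

    def test_negative_duration_errors(self):
        with pytest.raises(ValueError):
            SurvivalInput([-1.0], [1])

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=100.0,
                      allow_nan=False, allow_infinity=False),
            min_size=1, max_size=20,
        )
    )
    def test_uncensored_oracle_any_durations(self, durations):
        """With no censoring KM equals the empirical survival function."""
        data = SurvivalInput(durations, [1] * len(durations))
        curve = km_fit(data)
        xs = np.asarray(durations)
        for t, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx((xs > t).mean())

    def test_matches_lifelines_on_censored_data(self):
        rng = np.random.default_rng(8)
        data = SurvivalInput(
            rng.exponential(30, 200), (rng.random(200) > 0.3).astype(int)
        )
        curve = km_fit(data)
        kmf = KaplanMeierFitter().fit(data.durations, data.events)
        ours = [curve.survival_at(t) for t in curve.event_times]
        theirs = [
            float(kmf.survival_function_at_times(t).iloc[0])
            for t in curve.event_times
        ]
        np.testing.assert_allclose(ours, theirs, atol=1e-12)
        assert km_median(curve) == pytest.approx(kmf.median_survival_time_)


class TestKmMedian:
    def test_first_time_survival_drops_to_half(self):
        curve = km_fit(SurvivalInput([10, 20, 30, 40], [1, 1, 1, 1]))
        assert km_median(curve) == 20.0

    def test_undefined_when_curve_stays_high(self):
        curve = km_fit(SurvivalInput([10, 20, 30, 40, 50], [1, 0, 0, 0, 0]))
        assert km_median(curve) is None

    def test_recovers_exponential_median_at_scale(self):
        cfg = default_config()
        cfg.survival_params["m50"] = (50.0, 0.0)
        obs = generate_survival("m50", 5000, cfg, 21)
        med = km_median(km_fit(SurvivalInput(*zip(*obs))))
        assert abs(med - 50.0) / 50.0 < 0.05


class TestLogRank:
    def test_identical_groups_give_null_statistic(self):
        g = SurvivalInput([1, 2, 3, 4], [1, 1, 1, 1])
        res = logrank(g, g)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_toy_statistic(self):
        """A={1,2}, B={3,4}, all events: chi-square = 49/17 by tabulating
        risk sets by hand."""
        res = logrank(
            SurvivalInput([1, 2], [1, 1]), SurvivalInput([3, 4], [1, 1])
        )
        assert res.chi_square == pytest.approx(49 / 17)
        assert res.degrees_of_freedom == 1

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            logrank(SurvivalInput([], []), SurvivalInput([1], [1]))

    def test_no_events_errors(self):
        with pytest.raises(ValueError):
            logrank(SurvivalInput([1], [0]), SurvivalInput([2], [0]))

    def test_matches_lifelines(self):
        rng = np.random.default_rng(12)
        a = SurvivalInput(rng.exponential(10, 60), (rng.random(60) > 0.2).astype(int))
        b = SurvivalInput(rng.exponential(16, 50), (rng.random(50) > 0.2).astype(int))
        ours = logrank(a, b)
        ref = logrank_test(a.durations, b.durations, a.events, b.events)
        assert ours.chi_square == pytest.approx(ref.test_statistic)
        assert ours.p_value == pytest.approx(ref.p_value)

    def test_duration_scaling_invariance(self):
        rng = np.random.default_rng(13)
        a = SurvivalInput(rng.exponential(10, 40), np.ones(40, int))
        b = SurvivalInput(rng.exponential(20, 40), np.ones(40, int))
        base = logrank(a, b)
        scaled = logrank(
            SurvivalInput(a.durations * 7.5, a.events),
            SurvivalInput(b.durations * 7.5, b.events),
        )
        assert scaled.chi_square == pytest.approx(base.chi_square)
        med = km_median(km_fit(a))
        med_scaled = km_median(km_fit(SurvivalInput(a.durations * 7.5, a.events)))
        assert med_scaled == pytest.approx(7.5 * med)
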