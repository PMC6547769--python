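"""Error metrics, stratified aggregation, paired t test, deprivation flags."""

import math
from dataclasses import replace
from datetime import date

import numpy as np
import pytest
from scipy import stats

from isensesleep import (GroundTruthSleep, PRESETS, SleepEstimate, aggregate,
                         classify_deprivation, estimate_from_events, evaluate,
                         match_nights, paired_one_tailed_t, sample_user_days)

from conftest import dt


def make_estimate(night, start, end):
    dur = (dt(*end) - dt(*start)).total_seconds() / 60
    return SleepEstimate(night_date=dt(night, 0).date(),
                         day_type="weekend" if dt(night, 0).weekday() >= 5 else "weekday",
                         start=dt(*start), end=dt(*end), gross_min=dur, net_min=dur,
                         likelihood=1.0, s_bed=1.0, s_wake=1.0, s_dur=1.0)


def make_truth(night, start, end, net=None):
    gross = (dt(*end) - dt(*start)).total_seconds() / 60
    return GroundTruthSleep(night_date=dt(night, 0).date(), start=dt(*start),
                            end=dt(*end), net_duration_min=net if net is not None else gross)


class TestMatchNights:
    def test_disjoint_dates_leave_both_exclusion_counters_positive(self):
        res = match_nights([make_estimate(1, (0, 23, 0), (1, 7, 0))],
                           [make_truth(2, (1, 23, 0), (2, 7, 0))])
        assert res.comparisons == []
        assert res.unmatched_estimates == 1
        assert res.unmatched_truths == 1

    def test_error_arithmetic_on_one_night(self):
        res = match_nights([make_estimate(1, (0, 23, 30), (1, 7, 0))],
                           [make_truth(1, (0, 23, 15), (1, 7, 5), net=470)])
        (c,) = res.comparisons
        assert c.dur_err_min == pytest.approx(20.0)
        assert c.start_diff_min == pytest.approx(15.0)
        assert c.end_diff_min == pytest.approx(5.0)
        assert c.dur_err_pct == pytest.approx(100 * 20 / 470, abs=1e-9)

    def test_identical_est_and_truth_have_zero_errors(self):
        res = match_nights([make_estimate(1, (0, 23, 0), (1, 7, 0))],
                           [make_truth(1, (0, 23, 0), (1, 7, 0))])
        (c,) = res.comparisons
        assert (c.dur_err_min, c.start_diff_min, c.end_diff_min) == (0, 0, 0)

    def test_duplicate_night_is_a_hard_error(self):
        ests = [make_estimate(1, (0, 23, 0), (1, 7, 0)),
                make_estimate(1, (0, 22, 0), (1, 6, 0))]
        with pytest.raises(ValueError, match="duplicate"):
            match_nights(ests, [make_truth(1, (0, 23, 0), (1, 7, 0))])


class TestAggregate:
    def comparisons(self):
        ests = [make_estimate(i, (i - 1, 23, 0), (i, 7, 0)) for i in range(1, 8)]
        offs = [10, 20, 30, 10, 20, 30, 15]  # truth shifted by these minutes
        truths = [make_truth(i, (i - 1, 23, 0), (i, 7, o)) for i, o in zip(range(1, 8), offs)]
        return match_nights(ests, truths).comparisons

    def test_single_comparison_has_mean_but_no_sd(self):
        res = match_nights([make_estimate(1, (0, 23, 0), (1, 7, 0))],
                           [make_truth(1, (0, 23, 0), (1, 7, 10))])
        agg = aggregate(res.comparisons, "all")
        assert agg["dur_err_min"]["mean"] == pytest.approx(10.0)
        assert agg["dur_err_min"]["sd"] is None

    def test_mean_and_sample_sd_closed_form(self):
        comps = self.comparisons()[:3]  # errors 10, 20, 30
        agg = aggregate(comps, "all")
        assert agg["dur_err_min"]["mean"] == pytest.approx(20.0)
        assert agg["dur_err_min"]["sd"] == pytest.approx(10.0)

    def test_weekend_stratum_uses_saturday_sunday_wake_dates(self):
        comps = self.comparisons()
        we = aggregate(comps, "weekend")
        assert we["n_nights"] == 2  # 2016-01-09/10 are Sat/Sun
        assert all(c.day_type == "weekend" for c in comps
                   if c.night_date.weekday() >= 5)

    def test_stratified_counts_and_pooled_mean_identity(self):
        comps = self.comparisons()
        allr = aggregate(comps, "all")
        wd, we = aggregate(comps, "weekday"), aggregate(comps, "weekend")
        assert wd["n_nights"] + we["n_nights"] == allr["n_nights"]
        pooled = (wd["dur_err_min"]["mean"] * wd["n_nights"]
                  + we["dur_err_min"]["mean"] * we["n_nights"]) / allr["n_nights"]
        assert pooled == pytest.approx(allr["dur_err_min"]["mean"], abs=1e-12)


class TestPairedT:
    def test_exact_agreement_is_adequate_with_no_direction(self):
        res = paired_one_tailed_t([470, 480, 430], [470, 480, 430])
        assert (res.t, res.p, res.verdict, res.direction) == (0.0, 0.5, "adequate", None)

    def test_matches_closed_form_on_worked_pairs(self):
        est, truth = [470, 480, 500, 430], [450, 440, 455, 420]
        d = np.array(est) - np.array(truth)
        t_expected = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        p_expected = stats.t.sf(abs(t_expected), df=len(d) - 1)
        res = paired_one_tailed_t(est, truth)
        assert res.t == pytest.approx(t_expected, abs=1e-12)
        assert res.p == pytest.approx(p_expected, abs=1e-12)
        assert res.direction == ("over" if res.verdict == "differs" else None)

    def test_p_of_035_classifies_as_adequate(self):
        # mothers' pooled comparison in the validation study: p = .35 > .05
        rng = np.random.default_rng(0)
        while True:  # construct a sample whose one-tailed p lands near .35
            truth = rng.normal(450, 20, size=40)
            est = truth + rng.normal(1.5, 25, size=40)
            res = paired_one_tailed_t(est, truth)
            if 0.3 < res.p < 0.4:
                break
        assert res.verdict == "adequate" and res.direction is None

    def test_fewer_than_two_pairs_is_an_error(self):
        with pytest.raises(ValueError):
            paired_one_tailed_t([470], [450])

    def test_agrees_with_scipy_directional_test(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(3, 40))
            truth = rng.normal(450, 30, size=n)
            est = truth + rng.normal(rng.uniform(-20, 20), 25, size=n)
            res = paired_one_tailed_t(est, truth)
            alt = "greater" if (est - truth).mean() > 0 else "less"
            ref = stats.ttest_rel(est, truth, alternative=alt)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-10)
            assert abs(res.t) == pytest.approx(abs(ref.statistic), abs=1e-10)


class TestDeprivation:
    @pytest.mark.parametrize("mean,expected", [
        (377, "deprived"),      # a printed per-subject estimator mean
        (420, "adequate"),      # boundary inclusive into adequate
        (541, "long"),
        (480, "adequate"),
    ])
    def test_classification_against_recommended_band(self, mean, expected):
        assert classify_deprivation(mean) == expected


def test_end_to_end_idealized_simulation_has_zero_errors():
    """With zero boundary gaps and no night checks the pipeline must agree
    with ground truth exactly, night for night."""
    prof = replace(PRESETS["student"], pre_sleep_gap_mean=0.0, post_wake_gap_mean=0.0,
                   night_check_prob=0.0, interruption_prob=0.0, unknown_segment_prob=0.0)
    events, truths = sample_user_days(prof, 30, seed=7)
    report = evaluate(estimate_from_events(events), truths)
    assert report["n_matched"] == 30
    assert report["strata"]["all"]["dur_err_min"]["mean"] == 0.0
    assert report["strata"]["all"]["start_diff_min"]["mean"] == 0.0
    assert report["strata"]["all"]["end_diff_min"]["mean"] == 0.0
    assert report["paired_t"]["verdict"] == "adequate"
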