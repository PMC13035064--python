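import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_larva_events
from startlescreen.metrics import (
    classify_response,
    exclude_nonresponders,
    group_summary,
    habituation_percent,
    initiation_percent,
    kinematic_summary,
    ppi_percent,
    summarize_cohort,
)
from startlescreen.simulate import BehaviorModelConfig, make_metas, simulate_cohort


class TestClassifyResponse:
    def test_below_boundary_is_slc(self):
        assert classify_response(8.0, True) == "SLC"

    def test_above_boundary_is_llc(self):
        assert classify_response(28.0, True) == "LLC"

    def test_boundary_value_is_llc(self):
        assert classify_response(15.0, True) == "LLC"

    def test_no_response(self):
        assert classify_response(None, False) == "none"
        assert classify_response(float("nan"), False) == "none"

    def test_negative_latency_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            classify_response(-1.0, True)

    def test_latency_presence_invariant(self):
        with pytest.raises(ValueError):
            classify_response(None, True)
        with pytest.raises(ValueError):
            classify_response(5.0, False)


class TestExclusion:
    def test_full_responder_kept(self, screen_schedule):
        events = make_larva_events("a", 60, slc_indices=range(1, 61))
        kept, excluded = exclude_nonresponders(events, screen_schedule)
        assert kept == ["a"] and excluded == []

    def test_exactly_60_percent_nonresponse_excluded(self, screen_schedule):
        # 36 of 60 non-responses = 60%: excluded ("60% or more")
        events = make_larva_events("a", 60, slc_indices=range(1, 25))
        kept, excluded = exclude_nonresponders(events, screen_schedule)
        assert excluded == ["a"]

    def test_just_below_threshold_kept(self, screen_schedule):
        # 35 of 60 non-responses = 58.3%: kept
        events = make_larva_events("a", 60, slc_indices=range(1, 26))
        kept, excluded = exclude_nonresponders(events, screen_schedule)
        assert kept == ["a"]

    def test_missing_stimuli_error_lists_gaps(self, screen_schedule):
        events = make_larva_events("a", 60, slc_indices=range(1, 61))
        events = events[events["stimulus_index"] != 17]
        with pytest.raises(ValueError, match=r"a: missing stimuli \[17\]"):
            exclude_nonresponders(events, screen_schedule)


class TestInitiationPercent:
    def test_5_of_20(self):
        events = make_larva_events("a", 60, slc_indices={1, 4, 7, 10, 13})
        window = {1, 2, 4, 5, 7, 8, 10, 11, 13, 14, 16, 17, 19, 20, 22, 23, 25, 26, 28, 29}
        assert initiation_percent(events, window, "SLC") == pytest.approx(25.0)

    def test_zero_responses(self):
        events = make_larva_events("a", 60)
        assert initiation_percent(events, range(1, 61), "SLC") == 0.0

    def test_any_counts_both_classes(self):
        events = make_larva_events(
            "a", 10, slc_indices={1, 2, 3, 4}, llc_indices={5, 6, 7, 8, 9, 10}
        )
        assert initiation_percent(events, range(1, 11), "any") == pytest.approx(100.0)
        assert initiation_percent(events, range(1, 11), "SLC") == pytest.approx(40.0)

    def test_empty_window_rejected(self):
        events = make_larva_events("a", 10)
        with pytest.raises(ValueError, match="empty"):
            initiation_percent(events, set(), "SLC")

    def test_bad_filter_rejected(self):
        events = make_larva_events("a", 10)
        with pytest.raises(ValueError, match="response_filter"):
            initiation_percent(events, {1}, "LLC")


class TestHabituationPercent:
    def test_complete_habituation(self):
        events = make_larva_events("a", 20, slc_indices=range(1, 11))
        assert habituation_percent(events, range(1, 11), range(11, 21)) == pytest.approx(100.0)

    def test_partial(self):
        # first 8/10, late 2/10 -> 100 * (1 - 0.2/0.8) = 75
        events = make_larva_events("a", 20, slc_indices=set(range(1, 9)) | {11, 12})
        assert habituation_percent(events, range(1, 11), range(11, 21)) == pytest.approx(75.0)

    def test_facilitation_negative(self):
        # first 5/10, late 8/10 -> 100 * (1 - 1.6) = -60
        events = make_larva_events("a", 20, slc_indices=set(range(1, 6)) | set(range(11, 19)))
        assert habituation_percent(events, range(1, 11), range(11, 21)) == pytest.approx(-60.0)

    def test_zero_denominator_undefined(self):
        events = make_larva_events("a", 20, slc_indices={11, 12})
        assert habituation_percent(events, range(1, 11), range(11, 21)) is None

    def test_overlapping_windows_rejected(self):
        events = make_larva_events("a", 20, slc_indices={1})
        with pytest.raises(ValueError, match="overlap"):
            habituation_percent(events, range(1, 11), range(10, 21))


class TestPPIPercent:
    def test_full_suppression(self):
        events = make_larva_events("a", 20, slc_indices=range(11, 21))
        assert ppi_percent(events, range(1, 11), range(11, 21)) == pytest.approx(100.0)

    def test_half(self):
        # paired 3/10, unpaired 6/10 -> 100 * (1 - 0.5) = 50
        events = make_larva_events("a", 20, slc_indices={1, 2, 3} | set(range(11, 17)))
        assert ppi_percent(events, range(1, 11), range(11, 21)) == pytest.approx(50.0)

    def test_identity_zero(self):
        events = make_larva_events("a", 20, slc_indices=set(range(1, 7)) | set(range(11, 17)))
        assert ppi_percent(events, range(1, 11), range(11, 21)) == pytest.approx(0.0)

    def test_zero_unpaired_undefined(self):
        events = make_larva_events("a", 20, slc_indices={1, 2})
        assert ppi_percent(events, range(1, 11), range(11, 21)) is None

    def test_overlap_rejected(self):
        events = make_larva_events("a", 20, slc_indices={1})
        with pytest.raises(ValueError, match="overlap"):
            ppi_percent(events, {1, 2}, {2, 3})


class TestKinematicSummary:
    def test_single_response(self):
        events = make_larva_events("a", 10, slc_indices={3}, turn_angle=120.0)
        out = kinematic_summary(events, range(1, 11))
        assert out["turn_angle_deg"] == pytest.approx(120.0)

    def test_mean_of_two(self):
        e1 = make_larva_events("a", 10, slc_indices={1}, turn_angle=100.0)
        e2 = make_larva_events("a", 10, slc_indices={2}, turn_angle=140.0)
        events = pd.concat(
            [e1[e1["stimulus_index"] == 1], e2[e2["stimulus_index"] != 1]]
        )
        out = kinematic_summary(events, range(1, 11))
        assert out["turn_angle_deg"] == pytest.approx(120.0)

    def test_no_responses_absent(self):
        events = make_larva_events("a", 10)
        assert kinematic_summary(events, range(1, 11)) is None


class TestGroupSummary:
    def test_mean_and_sem(self):
        summaries = pd.DataFrame(
            {
                "larva_id": ["a", "b"],
                "excluded": [False, False],
                "hab_pct_final": [100.0, 50.0],
            }
        )
        out = group_summary(summaries).set_index("metric")
        assert out.loc["hab_pct_final", "mean"] == pytest.approx(75.0)
        assert out.loc["hab_pct_final", "sem"] == pytest.approx(25.0)
        assert out.loc["hab_pct_final", "n"] == 2

    def test_single_larva_sem_undefined(self):
        summaries = pd.DataFrame(
            {"larva_id": ["a"], "excluded": [False], "hab_pct_final": [40.0]}
        )
        out = group_summary(summaries).set_index("metric")
        assert out.loc["hab_pct_final", "n"] == 1
        assert math.isnan(out.loc["hab_pct_final", "sem"])

    def test_undefined_entries_skipped(self):
        summaries = pd.DataFrame(
            {
                "larva_id": ["a", "b", "c"],
                "excluded": [False, False, False],
                "hab_pct_final": [100.0, np.nan, 50.0],
            }
        )
        out = group_summary(summaries).set_index("metric")
        assert out.loc["hab_pct_final", "mean"] == pytest.approx(75.0)
        assert out.loc["hab_pct_final", "n"] == 2
        assert out.loc["hab_pct_final", "n_dropped"] == 1

    def test_all_excluded_rejected(self):
        summaries = pd.DataFrame(
            {"larva_id": ["a"], "excluded": [True], "hab_pct_final": [np.nan]}
        )
        with pytest.raises(ValueError, match="excluded"):
            group_summary(summaries)


class TestCohortSummary:
    def test_matches_per_larva_functions(self, screen_schedule, small_cohort):
        """The vectorized cohort summary equals brute-force per-larva calls."""
        summary = summarize_cohort(small_cohort, screen_schedule).set_index("larva_id")
        low_w = screen_schedule.window("baseline_low")
        high_w = screen_schedule.window("baseline_high")
        paired_w = screen_schedule.window("paired_high")
        late_w = screen_schedule.window("hab_41_50")
        kept, excluded = exclude_nonresponders(small_cohort, screen_schedule)
        for larva_id, sub in small_cohort.groupby("larva_id"):
            row = summary.loc[larva_id]
            if larva_id in excluded:
                assert row["excluded"]
                continue
            assert row["slc_init_low_pct"] == pytest.approx(
                initiation_percent(sub, low_w, "SLC")
            )
            assert row["any_init_high_pct"] == pytest.approx(
                initiation_percent(sub, high_w, "any")
            )
            hab = habituation_percent(sub, high_w, late_w)
            if hab is None:
                assert math.isnan(row["hab_pct_41_50"])
            else:
                assert row["hab_pct_41_50"] == pytest.approx(hab)
            ppi = ppi_percent(sub, paired_w, high_w)
            if ppi is None:
                assert math.isnan(row["ppi_pct"])
            else:
                assert row["ppi_pct"] == pytest.approx(ppi)
            kin = kinematic_summary(sub, high_w)
            if kin is None:
                assert math.isnan(row["kin_turn_angle_deg"])
            else:
                assert row["kin_turn_angle_deg"] == pytest.approx(kin["turn_angle_deg"])

    def test_row_order_invariance(self, screen_schedule, small_cohort):
        shuffled = small_cohort.sample(frac=1.0, random_state=0)
        a = summarize_cohort(small_cohort, screen_schedule)
        b = summarize_cohort(shuffled, screen_schedule)
        a = a.sort_values("larva_id").reset_index(drop=True)
        b = b.sort_values("larva_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_habituation_assay_summary(self, hab_schedule):
        metas = make_metas(40, seed=3)
        events = simulate_cohort(hab_schedule, metas, BehaviorModelConfig(), 4)
        summary = summarize_cohort(events, hab_schedule)
        assert "hab_pct_final" in summary.columns
        assert "ppi_pct" not in summary.columns


def _expected_habituation_pct(p_first: float, p_late: list[float], n: int = 10) -> float:
    """Analytic expectation of 100*(1 - (L/n)/(F/n)) given F > 0.

    F ~ Binomial(n, p_first), L the sum of independent Bernoulli(p_late[j])
    draws; F and L independent, so E = 100*(1 - E[L] * E[1/F | F > 0]).
    """
    pmf = stats.binom.pmf(np.arange(n + 1), n, p_first)
    p_pos = 1.0 - pmf[0]
    inv_mean = sum(pmf[k] / k for k in range(1, n + 1)) / p_pos
    return 100.0 * (1.0 - sum(p_late) * inv_mean)


class TestHabituationExpectationOracle:
    def test_group_mean_matches_analytic_ratio_expectation(self, screen_schedule):
        h = 0.55
        config = BehaviorModelConfig(
            h_g={"wildtype": h, "heterozygous": h, "double_mutant": h},
            nonresponder_fraction=0.0,
        )
        metas = make_metas(2500, seed=5)
        events = simulate_cohort(screen_schedule, metas, config, 6)
        summary = summarize_cohort(events, screen_schedule)
        observed = summary.loc[~summary["excluded"], "hab_pct_41_50"].dropna().mean()

        p_first = config.p_slc_high
        p_late = [
            p_first * ((1 - h) + h * math.exp(-j / config.tau)) for j in range(11, 21)
        ]
        expected = _expected_habituation_pct(p_first, p_late)
        assert observed == pytest.approx(expected, abs=2.0)
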