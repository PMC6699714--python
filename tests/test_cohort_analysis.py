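"""Normalized curves, class frequencies, rate statistics, timing histograms
and the normality-gated two-sample comparison."""

import numpy as np
import pytest

from cilialoss.cohort_analysis import (
    NormalizedCurve,
    average_curves,
    class_frequencies,
    compare_conditions,
    normalize_curve,
    rate_statistics,
    timing_histogram,
    unpaired_t,
)
from cilialoss.event_analysis import LossEvent

from conftest import make_traj


def simple_event(cls="gradual", start=0, completion=3, **kw):
    base = dict(
        cilium_id=kw.pop("cilium_id", "c0"),
        condition="serum",
        event_class=cls,
        start_index=start,
        penultimate_index=completion - 1,
        completion_index=completion,
        start_time_min=start * 1.5,
        end_time_min=completion * 1.5,
        start_length_um=5.0,
        penultimate_length_um=3.0,
        max_length_um=5.0,
        fraction_gradual=0.3,
        fraction_instant=0.6,
    )
    base.update(kw)
    return LossEvent(**base)


class TestNormalizeCurve:
    def test_affine_time_map_to_thousand_units(self):
        traj = make_traj([6.0, 6.0, 3.0, 0.0])  # 0..270 s
        ev = simple_event("gradual", start=1, completion=3)
        curve = normalize_curve(traj, ev)
        np.testing.assert_allclose(curve.norm_times, [0, 1000 / 3, 2000 / 3, 1000], rtol=1e-9)

    def test_lengths_normalized_to_trajectory_max(self):
        traj = make_traj([6.0, 6.0, 3.0, 0.0])
        curve = normalize_curve(traj, simple_event("gradual", start=0, completion=3))
        np.testing.assert_allclose(curve.norm_lengths, [1.0, 1.0, 0.5, 0.0])
        assert curve.norm_lengths.max() == 1.0

    def test_instant_start_marker_clusters_near_the_end(self):
        n = 120
        traj = make_traj([5.0] * n + [0.0])
        ev = simple_event("instant", start=n - 1, completion=n)
        curve = normalize_curve(traj, ev)
        assert curve.start_marker > 990  # last ~10 normalized units


class TestAverageCurves:
    def test_single_curve_is_returned_on_the_grid(self):
        traj = make_traj([4.0, 2.0, 0.0])
        curve = normalize_curve(traj, simple_event("gradual", start=0, completion=2))
        grid, mean, markers = average_curves([curve])
        np.testing.assert_allclose(mean, np.interp(grid, curve.norm_times, curve.norm_lengths))
        assert markers == [curve.start_marker]

    def test_mirror_symmetric_curves_average_to_axis(self):
        t = np.linspace(0, 1000, 11)
        up = NormalizedCurve(t, np.linspace(0.0, 1.0, 11), 0.0)
        down = NormalizedCurve(t, np.linspace(1.0, 0.0, 11), 0.0)
        _, mean, _ = average_curves([up, down])
        np.testing.assert_allclose(mean, 0.5)

    def test_twenty_instant_curves_stay_flat_until_terminal_drop(self):
        curves = []
        for i in range(20):
            n = 100 + i
            traj = make_traj([5.0] * n + [0.0], cilium_id=f"c{i}")
            curves.append(
                normalize_curve(traj, simple_event("instant", start=n - 1, completion=n))
            )
        grid, mean, _ = average_curves(curves)
        assert mean[np.searchsorted(grid, 500)] >= 0.95

    def test_empty_list_is_hard_error(self):
        with pytest.raises(ValueError):
            average_curves([])


class TestClassFrequencies:
    def test_published_cohort_counts_give_84_percent_instant_terminal(self):
        events = (
            [simple_event("gradual", cilium_id=f"g{i}") for i in range(11)]
            + [simple_event("instant", start=2, cilium_id=f"i{i}") for i in range(32)]
            + [simple_event("combined", cilium_id=f"c{i}") for i in range(26)]
        )
        f = class_frequencies(events)
        assert f.n == 69
        assert f.instant_terminal == pytest.approx(58 / 69)
        assert sum(f.frequencies.values()) == pytest.approx(1.0)

    def test_katanin_cohort_counts_give_98_percent(self):
        events = (
            [simple_event("gradual")]
            + [simple_event("instant", start=2, cilium_id=f"i{i}") for i in range(25)]
            + [simple_event("combined", cilium_id=f"c{i}") for i in range(24)]
        )
        assert class_frequencies(events).instant_terminal == pytest.approx(0.98)

    def test_single_gradual_event(self):
        assert class_frequencies([simple_event("gradual")]).instant_terminal == 0.0

    def test_all_censored_is_hard_error(self):
        with pytest.raises(ValueError):
            class_frequencies([LossEvent("c0", "serum", "censored")])


class TestRateStatistics:
    def test_identical_samples_give_t_zero_p_one(self):
        events = [
            simple_event("gradual", cilium_id=f"g{i}", gradual_rate=r)
            for i, r in enumerate([0.05, 0.1, 0.2])
        ] + [
            simple_event("combined", cilium_id=f"c{i}", gradual_rate=r, instant_min_rate=3.0)
            for i, r in enumerate([0.05, 0.1, 0.2])
        ]
        stats = rate_statistics(events)
        comp = {c.pair: c for c in stats.comparisons}
        c = comp[("combined_gradual_phase", "gradual")]
        assert c.statistic == pytest.approx(0.0, abs=1e-12)
        assert c.pvalue == pytest.approx(1.0)

    def test_shifted_three_point_samples_are_significant(self):
        _, p = unpaired_t(np.array([1.0, 2.0, 3.0]), np.array([11.0, 12.0, 13.0]))
        assert p < 0.01

    def test_underpowered_comparison_skipped_with_warning(self, caplog):
        import logging

        events = [simple_event("gradual", gradual_rate=0.1)]
        with caplog.at_level(logging.WARNING, logger="cilialoss.cohort"):
            stats = rate_statistics(events)
        assert stats.comparisons == []
        assert any("fewer than 2" in r.message for r in caplog.records)


class TestTimingHistogram:
    def test_hourly_bins(self):
        events = [
            simple_event("gradual", cilium_id=f"c{i}", end_time_min=t)
            for i, t in enumerate([72.0, 95.0, 170.0])
        ]
        h = timing_histogram(events)
        assert h["end_counts"][1] == 2  # 60-120 min
        assert h["end_counts"][2] == 1  # 120-180 min

    def test_no_events_gives_zero_histogram(self):
        h = timing_histogram([])
        assert h["start_counts"].sum() == 0
        assert h["end_counts"].sum() == 0


class TestCompareConditions:
    def test_gaussian_groups_select_t_test(self):
        rng = np.random.default_rng(1)
        res = compare_conditions(rng.normal(5, 1, 60), rng.normal(5, 1, 60))
        assert res.test == "t"
        assert res.pvalue > 0.05

    def test_exponential_groups_select_mannwhitney(self):
        rng = np.random.default_rng(1)
        res = compare_conditions(rng.exponential(1, 60), rng.exponential(1, 60))
        assert res.test == "mannwhitney"

    def test_identical_constant_groups_degenerate_nonsignificant(self):
        res = compare_conditions([2.0] * 5, [2.0] * 5)
        assert res.pvalue == 1.0
        assert "degenerate_constant" in res.flags

    def test_fewer_than_three_values_is_hard_error(self):
        with pytest.raises(ValueError):
            compare_conditions([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_selection_is_deterministic(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 40), rng.normal(0.2, 1, 40)
        first = compare_conditions(a, b)
        second = compare_conditions(a, b)
        assert (first.test, first.statistic, first.pvalue) == (
            second.test,
            second.statistic,
            second.pvalue,
        )
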