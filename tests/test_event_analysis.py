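"""Completion/start detection, classification and per-event metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cilialoss.config import PipelineConfig
from cilialoss.event_analysis import (
    analyze_trajectory,
    classify_event,
    compute_event_metrics,
    detect_completion,
    detect_start,
)
from cilialoss.preprocessing import ControlBaseline, default_baseline, smooth

from conftest import make_traj

BASE = default_baseline()  # mean slope -0.005 um/min, threshold 1.532 um


def straj_of(lengths, window=1, interval_s=90.0):
    return smooth(make_traj(lengths, interval_s=interval_s), window=window)


class TestDetectCompletion:
    def test_first_zero_of_terminal_run(self):
        assert detect_completion(straj_of([5, 5, 0, 0])) == 2

    def test_transient_dip_ignored(self):
        assert detect_completion(straj_of([5, 0, 3, 0])) == 3

    def test_never_zero_is_censored(self):
        assert detect_completion(straj_of([5, 4, 3, 2])) is None

    def test_zero_tol_floor(self):
        assert detect_completion(straj_of([5, 5, 0.2, 0.1]), zero_tol=0.25) == 2


def oracle_backward_scan(derivs, completion, mean_slope, tol_factor=1.0):
    """Independent restatement of the literal stopping rule: check every
    index explicitly and take the largest stopping position."""
    candidates = [
        i + 1
        for i in range(completion)
        if abs(derivs[i]) <= tol_factor * abs(mean_slope)
    ]
    return max(candidates) if candidates else 0


class TestDetectStart:
    def test_flat_then_drop_starts_at_penultimate(self):
        s = straj_of([5.0] * 10 + [0.0])
        assert detect_start(s, 10, BASE, mode="literal") == 9

    def test_pure_decline_exhausts_scan_to_zero(self):
        t_min = np.arange(11) * 1.5
        lengths = np.clip(0.45 - 0.03 * t_min, 0, None)  # reaches 0 at t=15 min
        lengths[-1] = 0.0  # exact zero (clip leaves ~1e-17 of float residue)
        s = smooth(make_traj(lengths, times=t_min * 60), window=1)
        c = detect_completion(s)
        assert detect_start(s, c, BASE, mode="literal") == 0

    def test_piecewise_flat_then_decline_finds_corner(self):
        # 20 flat frames, then decline at -0.03 um/min to zero, then drop
        t_min = np.arange(121) * 1.5
        lengths = np.empty(121)
        lengths[:20] = 4.5
        lengths[20:120] = 4.5 - 0.03 * (t_min[20:120] - t_min[19] - 1.5)
        lengths[120] = 0.0
        base = ControlBaseline(
            mean_slope=-0.005, diff_sd=0.0, max_diff_sd=0.0, instant_threshold=1.532, n_controls=1
        )
        s = smooth(make_traj(lengths, times=t_min * 60), window=1)
        c = detect_completion(s)
        assert c == 120
        start = detect_start(s, c, base, mode="literal")
        derivs = np.diff(s.smoothed_lengths[: c + 1]) / 1.5
        assert start == oracle_backward_scan(derivs, c, base.mean_slope) == 20

    def test_completion_at_zero_is_hard_error(self):
        s = straj_of([5, 5, 0])
        with pytest.raises(ValueError):
            detect_start(s, 0, BASE)

    @settings(derandomize=True, max_examples=120)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=10.0), min_size=3, max_size=50),
        st.floats(min_value=0.5, max_value=3.0),
    )
    def test_literal_mode_matches_brute_force_oracle(self, lengths, tol_factor):
        lengths = list(lengths) + [0.0]
        s = straj_of(lengths)
        c = detect_completion(s)
        if c is None or c == 0:
            return
        got = detect_start(s, c, BASE, slope_tol_factor=tol_factor, mode="literal")
        series = np.append(s.raw_lengths[:c], s.raw_lengths[c])
        derivs = np.diff(series) / 1.5
        assert got == oracle_backward_scan(derivs, c, BASE.mean_slope, tol_factor)


class TestClassify:
    def test_gradual_when_start_early_and_penultimate_below_threshold(self):
        s = straj_of([5, 3, 0.8, 0])
        cls, flags = classify_event(s, 0, 3, BASE)
        assert cls == "gradual" and flags == ()

    def test_instant_when_start_at_penultimate_and_above_threshold(self):
        s = straj_of([5, 5, 5, 0])
        cls, _ = classify_event(s, 2, 3, BASE)
        assert cls == "instant"

    def test_combined_when_both_criteria_hold(self):
        s = straj_of([6, 5, 4, 0])
        cls, _ = classify_event(s, 0, 3, BASE)
        assert cls == "combined"

    def test_degenerate_single_frame_subthreshold_drop_is_flagged_gradual(self):
        s = straj_of([0.9, 0.9, 0.9, 0])
        cls, flags = classify_event(s, 2, 3, BASE)
        assert cls == "gradual" and "degenerate" in flags

    def test_raising_threshold_never_converts_gradual_to_instant(self):
        # monotonicity of the threshold criterion
        s = straj_of([5, 3, 1.0, 0])
        order = []
        for thr in (0.3, 1.1, 1.532, 4.0):
            base = ControlBaseline(-0.005, 0.0, 0.0, thr, 1)
            order.append(classify_event(s, 0, 3, base)[0])
        seen_gradual = False
        for cls in order:
            if cls == "gradual":
                seen_gradual = True
            assert not (seen_gradual and cls in ("instant", "combined"))


class TestMetrics:
    def test_gradual_rate_is_amplitude_over_elapsed_time(self):
        # 6.0 -> 0.9 um over 255 min = 0.02 um/min
        t_min = np.array([0.0, 255.0, 256.5])
        traj = make_traj([6.0, 0.9, 0.0], times=t_min * 60)
        s = smooth(traj, window=1)
        ev = compute_event_metrics(s, 0, 2, "gradual")
        assert ev.gradual_rate == pytest.approx(0.02)

    def test_instant_min_rate_is_penultimate_over_frame(self):
        s = straj_of([4.5, 4.5, 4.5, 0.0])
        ev = compute_event_metrics(s, 2, 3, "instant")
        assert ev.instant_min_rate == pytest.approx(3.0)  # 4.5 um / 1.5 min
        assert ev.fraction_gradual == 0.0

    def test_fraction_instant_matches_penultimate_over_max(self):
        s = straj_of([10.0, 10.0, 7.26, 0.0])
        ev = compute_event_metrics(s, 1, 3, "combined", max_quantile=1.0)
        assert ev.fraction_instant == pytest.approx(0.726)
        assert ev.fraction_gradual + ev.fraction_instant <= 1.0 + 1e-12

    def test_fractions_stay_within_unit_interval_under_noise(self):
        rng = np.random.default_rng(11)
        lengths = np.clip(np.r_[5 + rng.normal(0, 0.4, 60), np.zeros(5)], 0, None)
        lengths[59] = max(lengths[59], 0.5)
        s = smooth(make_traj(lengths), window=5)
        ev = compute_event_metrics(s, 30, 60, "combined")
        assert 0.0 <= ev.fraction_gradual <= 1.0
        assert 0.0 <= ev.fraction_instant <= 1.0
        assert ev.fraction_gradual + ev.fraction_instant <= 1.0 + 1e-12


class TestAnalyzeTrajectory:
    def test_censored_trajectory_reported_not_raised(self):
        ev = analyze_trajectory(make_traj([5, 5, 5, 5]), BASE)
        assert ev.censored

    def test_full_pipeline_on_instant_exemplar(self):
        cfg = PipelineConfig()
        ev = analyze_trajectory(make_traj([5.0] * 40 + [0.0] * 10), BASE, cfg)
        assert ev.event_class == "instant"
        assert ev.completion_index == 40
        assert ev.instant_min_rate == pytest.approx(5.0 / 1.5, rel=1e-6)
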