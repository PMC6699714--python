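"""Detection and classification of terminal cilium-loss events.

A completed loss event ends at the first time point where the measured length
is zero and stays zero (T_final).  Scanning backwards from that point, the
event start (T_start) is the first moment the local rate of length change is
no longer distinguishable from the background decline of control cilia.  The
event is then classified by two criteria:

* did shortening begin before the penultimate frame (T_start != T_final-1)?
* was the length at the penultimate frame (L_final-1) above the
  measurement-error threshold (1.532 um for the published calibration)?

Gradual = shortening only (penultimate length at or below threshold);
Instant = the whole visible cilium disappears within one frame (no prior
shortening, penultimate length above threshold); Combined = a gradual phase
directly followed by a single-frame loss (both criteria true).

Completion and the penultimate-length comparison use the raw series: a
moving-average kernel smears the single-frame drop across its half-width,
which would delay the detected completion into the zero tail and attenuate
the penultimate length.  Derivatives for start detection use the smoothed
series, but smoothing is applied to the pre-completion segment only so the
zero tail cannot bleed an artificial "decline" into the frames before an
Instant drop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .config import PipelineConfig
from .preprocessing import (
    ControlBaseline,
    SmoothedTrajectory,
    derivative_series,
    kernel_weights,
    resolve_baseline,
    smooth,
    smooth_series,
)
from .trajectory_io import LengthTrajectory

logger = logging.getLogger("cilialoss.events")

CLASSES = ("gradual", "instant", "combined")


@dataclass(frozen=True)
class LossEvent:
    """One classified disassembly event (or a censored trajectory).

    Indices refer to the raw trajectory; times are minutes from movie start.
    ``gradual_rate`` is the mean shortening rate of the gradual phase;
    ``instant_min_rate`` is the penultimate length divided by the final frame
    interval — a lower bound, since the actual loss occurs somewhere within
    that single frame.  Fractions are of the (noise-robust) maximum length.
    """

    cilium_id: str
    condition: str
    event_class: str  # gradual | instant | combined | censored
    start_index: Optional[int] = None
    penultimate_index: Optional[int] = None
    completion_index: Optional[int] = None
    start_time_min: Optional[float] = None
    end_time_min: Optional[float] = None
    start_length_um: Optional[float] = None
    penultimate_length_um: Optional[float] = None
    max_length_um: Optional[float] = None
    gradual_rate: Optional[float] = None
    instant_min_rate: Optional[float] = None
    fraction_gradual: Optional[float] = None
    fraction_instant: Optional[float] = None
    flags: Tuple[str, ...] = ()

    def __post_init__(self):
        if self.event_class not in CLASSES + ("censored",):
            raise ValueError(f"unknown event class {self.event_class!r}")
        if self.event_class != "censored":
            if not (self.start_index <= self.penultimate_index < self.completion_index):
                raise ValueError("require start <= penultimate < completion")
            if self.completion_index != self.penultimate_index + 1:
                raise ValueError("completion must directly follow the penultimate point")

    @property
    def censored(self) -> bool:
        return self.event_class == "censored"


def detect_completion(straj: SmoothedTrajectory, zero_tol: float = 0.0) -> Optional[int]:
    """Index of the first raw length <= ``zero_tol`` with all subsequent
    points also <= ``zero_tol``; ``None`` if the cilium never disappears
    (censored).  Transient dips to zero followed by recovery are ignored."""
    lengths = straj.raw_lengths
    above = np.nonzero(lengths > zero_tol)[0]
    if len(above) == 0:
        # already gone at frame 0; treat the first frame as completion
        return 0
    completion = int(above[-1]) + 1
    if completion >= len(lengths):
        return None
    return completion


def _segment_smoothed(straj: SmoothedTrajectory, completion: int) -> np.ndarray:
    """Smoothed lengths of the pre-completion segment raw[0:completion].

    The window shrinks (staying odd) if the segment is shorter than the
    configured window.
    """
    segment = straj.raw_lengths[:completion]
    window = min(straj.window, len(segment))
    if window % 2 == 0:
        window -= 1
    window = max(window, 1)
    return smooth_series(segment, window, straj.kernel)


def _scan_derivatives(straj: SmoothedTrajectory, completion: int) -> np.ndarray:
    """Interval derivatives (um/min) used by the backward scan.

    Intervals 0..completion-2 come from the segment-smoothed series; the
    terminal interval (penultimate -> completion) uses the raw drop so the
    scan always starts on the loss itself.
    """
    seg = _segment_smoothed(straj, completion)
    times = straj.times
    series = np.append(seg, straj.raw_lengths[completion])
    return derivative_series(times[: completion + 1], series)


def _derivative_noise_sd(straj: SmoothedTrajectory, baseline: ControlBaseline) -> float:
    """Propagated SD (um/min) of one smoothed-interval derivative given the
    calibrated consecutive-difference SD of the controls."""
    sigma_meas = baseline.diff_sd / np.sqrt(2.0)
    w = kernel_weights(straj.window, straj.kernel)
    c = np.append(w, 0.0) - np.insert(w, 0, 0.0)  # difference-of-adjacent-windows weights
    dt_min = straj.parent.frame_interval / 60.0
    return float(sigma_meas * np.sqrt(np.sum(c**2)) / dt_min)


def _smoothed_value_sd(straj: SmoothedTrajectory, baseline: ControlBaseline) -> float:
    sigma_meas = baseline.diff_sd / np.sqrt(2.0)
    w = kernel_weights(straj.window, straj.kernel)
    return float(sigma_meas * np.sqrt(np.sum(w**2)))


def _hinge_decline_test(
    straj: SmoothedTrajectory, penult: int, baseline: ControlBaseline
) -> Tuple[Optional[int], float]:
    """Changepoint test for a gradual phase before the terminal drop.

    For every candidate kink index s in [0, penult-1] the raw lengths over
    [0, penult], detrended by the calibrated control slope, are regressed on
    the hinge max(0, t - t_s).  The z-score of the hinge coefficient uses the
    calibrated per-measurement noise SD plus the propagated uncertainty of
    the control slope itself (which otherwise accumulates into a spurious
    trend over hundreds of frames); the most negative z measures the
    evidence that shortening beyond the background drift began at s.
    Returns (argmin index, min z); (None, 0) when the noise SD is not
    calibrated.
    """
    sigma = baseline.diff_sd / np.sqrt(2.0)
    if sigma <= 0 or penult < 2:
        return None, 0.0
    t = straj.times_min[: penult + 1]
    y = straj.raw_lengths[: penult + 1] - baseline.mean_slope * t
    n = penult + 1
    ybar = y.mean()
    tbar = t.mean()
    # suffix sums over j > s, vectorized via reversed cumulative sums
    t1 = np.cumsum(t[::-1])[::-1]  # sum_{j>=s} t_j
    t2 = np.cumsum((t**2)[::-1])[::-1]
    ty = np.cumsum((t * y)[::-1])[::-1]
    y1 = np.cumsum(y[::-1])[::-1]
    s = np.arange(penult)  # candidate kinks, leaving >= 1 point after
    m = n - (s + 1)  # points on the hinge
    ts = t[s]
    sum_x = t1[s + 1] - m * ts
    sum_x2 = t2[s + 1] - 2 * ts * t1[s + 1] + m * ts**2
    sum_xt = t2[s + 1] - ts * t1[s + 1]
    sum_xy = ty[s + 1] - ts * y1[s + 1]
    xbar = sum_x / n
    sxx = sum_x2 - n * xbar**2
    sxt = sum_xt - n * xbar * tbar
    sxy = sum_xy - n * xbar * ybar
    var = sigma**2 * sxx + (baseline.mean_slope_se * sxt) ** 2
    valid = (sxx > 0) & (var > 0)
    z = np.full(penult, np.inf)
    z[valid] = sxy[valid] / np.sqrt(var[valid])
    if not np.any(np.isfinite(z)):
        return None, 0.0
    best = int(np.argmin(z))
    return best, float(z[best])


def detect_start(
    straj: SmoothedTrajectory,
    completion: int,
    baseline: ControlBaseline,
    slope_tol_factor: float = 1.0,
    mode: str = "robust",
    robust_k: float = 3.0,
) -> int:
    """Event start index by backward scan from the completion point.

    ``literal`` mode is the bare rule: walk i from completion-1 down to 0 and
    stop at the first interval whose |derivative| <= slope_tol_factor *
    |mean control slope|; the start is i + 1, or 0 if the scan exhausts the
    trajectory.

    ``robust`` mode (default) guards the same rule against measurement noise
    using the calibrated ``diff_sd``:

    1. *Existence*: the mean slope over the span [i, penultimate] is compared
       against the control slope at z-threshold ``robust_k`` for every i.  If
       no span shows a significant net decline, there is no gradual phase and
       the start is the penultimate point.
    2. *Placement*: otherwise the backward scan runs with the tolerance
       inflated by ``robust_k`` derivative-noise SDs, and the start is capped
       at the latest span index that showed significant decline.

    With ``diff_sd`` = 0 both guards vanish and robust mode reproduces the
    literal rule exactly.
    """
    if completion == 0:
        raise ValueError("completion at index 0: no pre-event data to scan")
    if mode not in ("literal", "robust"):
        raise ValueError(f"unknown start mode {mode!r}")

    derivs = _scan_derivatives(straj, completion)  # length == completion
    tol = slope_tol_factor * abs(baseline.mean_slope) + 1e-12  # absorb float rounding

    # a calibrated measurement error below ~1 nm is numerically noiseless
    if mode == "literal" or baseline.diff_sd <= 1e-6:
        for i in range(completion - 1, -1, -1):
            if abs(derivs[i]) <= tol:
                return i + 1
        return 0

    # robust mode with calibrated noise
    penult = completion - 1
    kink, z_min = _hinge_decline_test(straj, penult, baseline)
    if kink is None or z_min > -robust_k:
        return penult  # no detectable gradual phase: instant-type start

    extra = robust_k * _derivative_noise_sd(straj, baseline)
    scan_start = 0
    for i in range(completion - 1, -1, -1):
        if abs(derivs[i]) <= tol + extra:
            scan_start = i + 1
            break
    return min(scan_start, kink)


def classify_event(
    straj: SmoothedTrajectory,
    start: int,
    completion: int,
    baseline: ControlBaseline,
    degenerate_policy: str = "gradual",
) -> Tuple[str, Tuple[str, ...]]:
    """Assign the event class from the start point and the raw penultimate
    length.

    Combined if the start precedes the penultimate point AND the penultimate
    length exceeds the Instant threshold; Instant if only the threshold
    criterion holds; Gradual if only the start criterion holds.  The
    degenerate case (single-frame drop from at or below threshold, i.e.
    indistinguishable from measurement error) is assigned Gradual and
    flagged.

    The penultimate length is read from the segment-smoothed series (the
    truncated kernel at the segment edge only averages pre-drop frames, so an
    Instant drop is not attenuated while per-frame noise is).
    """
    penult = completion - 1
    seg = _segment_smoothed(straj, completion)
    l_penult = float(seg[penult])
    above = l_penult > baseline.instant_threshold
    if start < penult:
        return ("combined" if above else "gradual"), ()
    if above:
        return "instant", ()
    if degenerate_policy != "gradual":
        raise ValueError(f"unsupported degenerate policy {degenerate_policy!r}")
    return "gradual", ("degenerate",)


def compute_event_metrics(
    straj: SmoothedTrajectory,
    start: int,
    completion: int,
    event_class: str,
    flags: Tuple[str, ...] = (),
    max_quantile: float = 0.95,
) -> LossEvent:
    """Per-phase rates and fractions for a classified event.

    Rates are amplitude over elapsed time (not fitted slopes), using lengths
    read from the segment-smoothed series at the detected indices; at the
    segment edge the truncated kernel only sees pre-drop frames, so the
    penultimate length of an Instant drop is not attenuated.  The maximum
    length for the fractions is a noise-robust maximum — the ``max_quantile``
    quantile of the smoothed pre-completion series, floored at the start and
    penultimate lengths so the fractions stay within [0, 1].
    """
    traj = straj.parent
    penult = completion - 1
    times_min = straj.times_min
    seg = _segment_smoothed(straj, completion)

    start_length = float(seg[start])
    penult_length = float(seg[penult])
    smoothed_start = float(seg[start])
    max_length = float(np.quantile(seg, max_quantile))
    max_length = max(max_length, smoothed_start, penult_length)
    if max_length <= 0:
        raise ValueError(f"{traj.cilium_id}: non-positive maximum length")

    gradual_rate = None
    instant_min_rate = None
    if event_class in ("gradual", "combined") and start < penult:
        elapsed = times_min[penult] - times_min[start]
        if elapsed <= 0:
            raise ValueError(f"{traj.cilium_id}: zero elapsed time in gradual phase")
        gradual_rate = (start_length - penult_length) / elapsed
    if event_class in ("instant", "combined"):
        dt_final = times_min[completion] - times_min[penult]
        if dt_final <= 0:
            raise ValueError(f"{traj.cilium_id}: zero elapsed time in terminal frame")
        instant_min_rate = penult_length / dt_final

    fraction_instant = min(penult_length / max_length, 1.0)
    if start < penult:
        fraction_gradual = max((smoothed_start - penult_length) / max_length, 0.0)
        fraction_gradual = min(fraction_gradual, 1.0 - fraction_instant)
    else:
        fraction_gradual = 0.0

    return LossEvent(
        cilium_id=traj.cilium_id,
        condition=traj.condition,
        event_class=event_class,
        start_index=start,
        penultimate_index=penult,
        completion_index=completion,
        start_time_min=float(times_min[start]),
        end_time_min=float(times_min[completion]),
        start_length_um=start_length,
        penultimate_length_um=penult_length,
        max_length_um=max_length,
        gradual_rate=gradual_rate,
        instant_min_rate=instant_min_rate,
        fraction_gradual=fraction_gradual,
        fraction_instant=fraction_instant,
        flags=flags,
    )


def analyze_trajectory(
    traj: LengthTrajectory,
    baseline: ControlBaseline,
    config: Optional[PipelineConfig] = None,
) -> LossEvent:
    """Run the full per-trajectory pipeline: smooth, find completion and
    start, classify, compute metrics.  Returns a censored event if the cilium
    never disappears (or is already gone at frame 0)."""
    cfg = config or PipelineConfig()
    window = min(cfg.smoothing.window, traj.n_frames)
    if window % 2 == 0:
        window -= 1
    straj = smooth(traj, window=max(window, 1), kernel=cfg.smoothing.kernel)
    completion = detect_completion(straj, zero_tol=cfg.event.zero_tol)
    if completion is None or completion == 0:
        flags = ("zero_at_start",) if completion == 0 else ()
        return LossEvent(
            cilium_id=traj.cilium_id, condition=traj.condition, event_class="censored", flags=flags
        )
    start = detect_start(
        straj,
        completion,
        baseline,
        slope_tol_factor=cfg.event.slope_tol_factor,
        mode=cfg.event.start_mode,
        robust_k=cfg.event.robust_k,
    )
    event_class, flags = classify_event(
        straj, start, completion, baseline, degenerate_policy=cfg.event.degenerate_policy
    )
    return compute_event_metrics(
        straj, start, completion, event_class, flags=flags, max_quantile=cfg.event.max_quantile
    )


@dataclass
class CohortResult:
    baseline: ControlBaseline
    events: List[LossEvent] = field(default_factory=list)

    @property
    def classified(self) -> List[LossEvent]:
        return [e for e in self.events if not e.censored]


def analyze_cohort(
    trajectories: Sequence[LengthTrajectory],
    config: Optional[PipelineConfig] = None,
    baseline: Optional[ControlBaseline] = None,
) -> CohortResult:
    """Calibrate the baseline from the cohort's control cilia (unless one is
    supplied) and classify every experimental trajectory."""
    cfg = config or PipelineConfig()
    if baseline is None:
        baseline = resolve_baseline(trajectories, cfg.baseline)
    events = [
        analyze_trajectory(t, baseline, cfg) for t in trajectories if t.role == "experimental"
    ]
    n_censored = sum(e.censored for e in events)
    if n_censored:
        logger.info("censored %d of %d trajectories (no completed loss)", n_censored, len(events))
    return CohortResult(baseline=baseline, events=events)
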