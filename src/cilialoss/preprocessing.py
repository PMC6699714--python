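"""Smoothing, derivatives and control-baseline calibration.

The control baseline is estimated from serum-starved, non-disassembling cilia
imaged under the same regime as the experimental cells.  Two statistics drive
the downstream event analysis:

``mean_slope``
    Mean over control cilia of the per-cilium least-squares slope of raw
    length vs time (um/min).  This is the background decline against which a
    derivative must stand out to count as active disassembly.

``diff_sd``
    Mean over control cilia of the per-cilium standard deviation of
    consecutive raw length differences (um).  For i.i.d. per-measurement noise
    of SD sigma this converges to sigma * sqrt(2); it proxies the length
    measurement error and calibrates the Instant threshold.  ``max_diff_sd``
    (the maximum over cilia) is also reported, since a conservative reading
    uses the worst control cilium as the error proxy.

Baseline statistics are computed on the raw, unsmoothed series: smoothing
would shrink exactly the frame-to-frame fluctuation the statistic measures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .config import (
    DEFAULT_INSTANT_THRESHOLD_UM,
    DEFAULT_MEAN_SLOPE_UM_PER_MIN,
    BaselineConfig,
)
from .trajectory_io import LengthTrajectory

logger = logging.getLogger("cilialoss.preprocessing")

KERNELS = ("gaussian_weighted", "uniform")


@dataclass(frozen=True)
class SmoothedTrajectory:
    """A trajectory plus its moving-average smoothed lengths.

    Smoothing is a weighted moving average over ``window`` frames; at the
    edges the truncated kernel is renormalized (no padding values are
    invented).  ``window`` = 1 leaves the series untouched.
    """

    parent: LengthTrajectory
    smoothed_lengths: np.ndarray
    window: int
    kernel: str

    @property
    def times(self) -> np.ndarray:
        return self.parent.times

    @property
    def times_min(self) -> np.ndarray:
        return self.parent.times_min

    @property
    def raw_lengths(self) -> np.ndarray:
        return self.parent.lengths

    @property
    def n_frames(self) -> int:
        return self.parent.n_frames


@dataclass(frozen=True)
class ControlBaseline:
    """Calibrated background-drift and measurement-error parameters."""

    mean_slope: float  # um/min, signed
    diff_sd: float  # um, mean per-cilium SD of consecutive differences
    max_diff_sd: float  # um, max per-cilium SD of consecutive differences
    instant_threshold: float  # um
    n_controls: int
    mean_slope_se: float = 0.0  # um/min, standard error of mean_slope over controls

    def __post_init__(self):
        if self.diff_sd < 0:
            raise ValueError("diff_sd must be >= 0")
        if self.max_diff_sd < self.diff_sd - 1e-12:
            raise ValueError("max_diff_sd must be >= diff_sd")
        if self.instant_threshold <= 0:
            raise ValueError("instant_threshold must be > 0")


def kernel_weights(window: int, kernel: str = "gaussian_weighted") -> np.ndarray:
    """Normalized moving-average weights for an odd ``window`` of frames.

    The Gaussian-weighted kernel uses sigma = window / 4 frames, truncated to
    the window; ``uniform`` is a plain moving average.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    if kernel not in KERNELS:
        raise ValueError(f"kernel must be one of {KERNELS}, got {kernel!r}")
    if kernel == "uniform" or window == 1:
        w = np.ones(window)
    else:
        half = window // 2
        sigma = window / 4.0
        offsets = np.arange(-half, half + 1, dtype=float)
        w = np.exp(-0.5 * (offsets / sigma) ** 2)
    return w / w.sum()


def smooth_series(values: np.ndarray, window: int, kernel: str = "gaussian_weighted") -> np.ndarray:
    """Truncated-kernel-renormalized moving average, clipped at 0."""
    values = np.asarray(values, dtype=float)
    if window > len(values):
        raise ValueError(f"window {window} exceeds series length {len(values)}")
    w = kernel_weights(window, kernel)
    if window == 1:
        return values.copy()
    num = np.convolve(values, w, mode="same")
    den = np.convolve(np.ones_like(values), w, mode="same")
    return np.clip(num / den, 0.0, None)


def smooth(
    traj: LengthTrajectory, window: int = 5, kernel: str = "gaussian_weighted"
) -> SmoothedTrajectory:
    """Smooth a trajectory with a (Gaussian-weighted) moving average.

    Raises on an even window or a window larger than the trajectory.
    """
    return SmoothedTrajectory(
        parent=traj,
        smoothed_lengths=smooth_series(traj.lengths, window, kernel),
        window=window,
        kernel=kernel,
    )


def derivative(straj: SmoothedTrajectory, i: int) -> float:
    """Rate of length change (um/min) over the interval starting at index ``i``.

    Defined as (length[i+1] - length[i]) / dt with dt in minutes, attributed
    to the left point; the last index has no interval and is a hard error.
    """
    n = straj.n_frames
    if not 0 <= i < n - 1:
        raise IndexError(f"derivative index {i} out of range for {n} frames")
    dt_min = (straj.times[i + 1] - straj.times[i]) / 60.0
    return float((straj.smoothed_lengths[i + 1] - straj.smoothed_lengths[i]) / dt_min)


def derivative_series(times_s: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """All interval derivatives (um/min) of a series; length n-1."""
    dt_min = np.diff(times_s) / 60.0
    return np.diff(lengths) / dt_min


def estimate_baseline(
    controls: Sequence[LengthTrajectory],
    instant_threshold_override: Optional[float] = None,
) -> ControlBaseline:
    """Calibrate the baseline from control (non-disassembling) cilia.

    Per-cilium least-squares slope of raw length vs time, averaged, gives
    ``mean_slope``; the per-cilium SD of consecutive raw length differences,
    averaged and maximized, gives ``diff_sd`` and ``max_diff_sd``.  The
    Instant threshold defaults to ``diff_sd`` unless overridden.
    """
    controls = list(controls)
    if not controls:
        raise ValueError("estimate_baseline requires at least one control trajectory")
    slopes, diff_sds = [], []
    for traj in controls:
        if np.any(traj.lengths <= 0):
            logger.warning(
                "control cilium %r reaches length 0; controls should be non-disassembling",
                traj.cilium_id,
            )
        slopes.append(float(np.polyfit(traj.times_min, traj.lengths, 1)[0]))
        diff_sds.append(float(np.std(np.diff(traj.lengths), ddof=1)))
    diff_sd = float(np.mean(diff_sds))
    threshold = instant_threshold_override if instant_threshold_override is not None else diff_sd
    if threshold <= 0:
        logger.warning(
            "calibrated instant threshold %.4g um is not positive; falling back to %.3f um",
            threshold,
            DEFAULT_INSTANT_THRESHOLD_UM,
        )
        threshold = DEFAULT_INSTANT_THRESHOLD_UM
    slope_se = (
        float(np.std(slopes, ddof=1) / np.sqrt(len(slopes))) if len(slopes) > 1 else 0.0
    )
    return ControlBaseline(
        mean_slope=float(np.mean(slopes)),
        diff_sd=diff_sd,
        max_diff_sd=float(np.max(diff_sds)),
        instant_threshold=float(threshold),
        n_controls=len(controls),
        mean_slope_se=slope_se,
    )


def default_baseline(
    instant_threshold: float = DEFAULT_INSTANT_THRESHOLD_UM,
    mean_slope: float = DEFAULT_MEAN_SLOPE_UM_PER_MIN,
) -> ControlBaseline:
    """The shipped baseline used when no control cilia are supplied: the
    published Instant threshold (1.532 um) and control slope (-0.005 um/min),
    with zero calibrated measurement error."""
    return ControlBaseline(
        mean_slope=mean_slope,
        diff_sd=0.0,
        max_diff_sd=0.0,
        instant_threshold=instant_threshold,
        n_controls=0,
    )


def resolve_baseline(
    controls: Sequence[LengthTrajectory], baseline_cfg: BaselineConfig
) -> ControlBaseline:
    """Baseline from controls if available, else from configured overrides.

    With no controls and no ``instant_threshold_override`` this is a hard
    error: the Instant/Gradual distinction is meaningless without a
    measurement-error threshold.
    """
    controls = [t for t in controls if t.role == "control"]
    if controls:
        base = estimate_baseline(
            controls, instant_threshold_override=baseline_cfg.instant_threshold_override
        )
        if baseline_cfg.mean_slope_override is not None:
            base = ControlBaseline(
                mean_slope=baseline_cfg.mean_slope_override,
                diff_sd=base.diff_sd,
                max_diff_sd=base.max_diff_sd,
                instant_threshold=base.instant_threshold,
                n_controls=base.n_controls,
                mean_slope_se=base.mean_slope_se,
            )
        return base
    if baseline_cfg.instant_threshold_override is None:
        raise ValueError(
            "no control trajectories and no baseline.instant_threshold_override: "
            "cannot calibrate the Instant threshold"
        )
    mean_slope = (
        baseline_cfg.mean_slope_override
        if baseline_cfg.mean_slope_override is not None
        else DEFAULT_MEAN_SLOPE_UM_PER_MIN
    )
    return default_baseline(
        instant_threshold=baseline_cfg.instant_threshold_override, mean_slope=mean_slope
    )
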