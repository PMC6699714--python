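"""Cohort-level summaries: normalized curves, class frequencies, rate
statistics, event-timing histograms and normality-gated two-sample tests.

To compare events with very different durations, each trajectory is rescaled
to 1,000 arbitrary time units (movie start -> 0, completion -> 1,000) and to
its own maximum length (-> 1).  Averaged normalized curves and the scatter of
event start markers along them are the cohort's dynamic fingerprint: a
Gradual cohort bends early, an Instant cohort stays flat until the terminal
drop, a Combined cohort shows a shallow decline that ends in a cliff.

Two-sample comparisons follow the normality-gated scheme: each group is
subjected to Kolmogorov-Smirnov (Lilliefors), D'Agostino-Pearson and
Shapiro-Wilk normality tests at alpha = 0.05; if every test passes in both
groups an unpaired t test is used, if every applicable test fails a
Mann-Whitney U test is used, and in the mixed case both tests are run and
reported.  No multiple-testing correction is applied to the pairwise rate
comparisons (they are reported raw).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .config import StatsConfig
from .event_analysis import CLASSES, LossEvent
from .preprocessing import SmoothedTrajectory
from .trajectory_io import LengthTrajectory

logger = logging.getLogger("cilialoss.cohort")

NORM_TIME_UNITS = 1000.0


@dataclass(frozen=True)
class NormalizedCurve:
    """A trajectory rescaled to 1,000 time units and unit maximum length,
    with the normalized time of its event start."""

    norm_times: np.ndarray  # 0..1000
    norm_lengths: np.ndarray  # 0..1, max exactly 1
    start_marker: float

    def __post_init__(self):
        if not math.isclose(self.norm_times[0], 0.0, abs_tol=1e-9):
            raise ValueError("normalized time must start at 0")
        if not math.isclose(self.norm_times[-1], NORM_TIME_UNITS, rel_tol=1e-9):
            raise ValueError("normalized time must end at 1000")
        if not (0.0 <= self.start_marker <= NORM_TIME_UNITS):
            raise ValueError("start marker must lie within [0, 1000]")


def normalize_curve(traj: LengthTrajectory, event: LossEvent) -> NormalizedCurve:
    """Normalize a completed event's trajectory (movie start -> 0, completion
    -> 1,000; lengths divided by the trajectory maximum up to completion)."""
    if event.censored:
        raise ValueError("cannot normalize a censored trajectory")
    c = event.completion_index
    times = traj.times[: c + 1]
    lengths = traj.lengths[: c + 1]
    max_length = float(np.max(lengths))
    if max_length <= 0:
        raise ValueError(f"{traj.cilium_id}: maximum length is 0")
    span = times[-1] - times[0]
    norm_times = NORM_TIME_UNITS * (times - times[0]) / span
    start_marker = float(NORM_TIME_UNITS * (traj.times[event.start_index] - times[0]) / span)
    return NormalizedCurve(
        norm_times=norm_times, norm_lengths=lengths / max_length, start_marker=start_marker
    )


def average_curves(
    curves: Sequence[NormalizedCurve], grid: int = 1001
) -> Tuple[np.ndarray, np.ndarray, List[float]]:
    """Pointwise mean of normalized curves on a common 0-1000 grid.

    Each curve is linearly interpolated onto the grid.  Returns
    (grid_times, mean_curve, start_markers); start markers are passed through
    untouched (they are plotted as open circles on the averaged curve).
    """
    if not curves:
        raise ValueError("average_curves requires at least one curve")
    grid_times = np.linspace(0.0, NORM_TIME_UNITS, grid)
    stack = np.stack(
        [np.interp(grid_times, c.norm_times, c.norm_lengths) for c in curves]
    )
    return grid_times, stack.mean(axis=0), [c.start_marker for c in curves]


@dataclass
class ClassFrequencies:
    counts: Dict[str, int]
    frequencies: Dict[str, float]
    instant_terminal: float  # fraction of events whose terminal loss is single-frame
    n: int


def class_frequencies(events: Sequence[LossEvent]) -> ClassFrequencies:
    """Counts and relative frequencies per class over classified (non-
    censored) events, plus the fraction whose terminal loss is Instant
    (Instant + Combined)."""
    classified = [e for e in events if not e.censored]
    if not classified:
        raise ValueError("no classified events (all censored)")
    counts = {cls: sum(e.event_class == cls for e in classified) for cls in CLASSES}
    n = len(classified)
    freqs = {cls: counts[cls] / n for cls in CLASSES}
    instant_terminal = (counts["instant"] + counts["combined"]) / n
    return ClassFrequencies(counts=counts, frequencies=freqs, instant_terminal=instant_terminal, n=n)


@dataclass
class RateSample:
    label: str
    values: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if len(self.values) else math.nan

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else math.nan

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class PairwiseTest:
    pair: Tuple[str, str]
    test: str
    statistic: float
    pvalue: float


@dataclass
class RateStatistics:
    samples: Dict[str, RateSample]
    comparisons: List[PairwiseTest] = field(default_factory=list)


def _collect_rate_samples(events: Sequence[LossEvent]) -> Dict[str, RateSample]:
    def grab(cls: str, attr: str) -> np.ndarray:
        vals = [
            getattr(e, attr)
            for e in events
            if e.event_class == cls and getattr(e, attr) is not None
        ]
        return np.asarray(vals, dtype=float)

    return {
        "gradual": RateSample("gradual", grab("gradual", "gradual_rate")),
        "instant": RateSample("instant", grab("instant", "instant_min_rate")),
        "combined_gradual_phase": RateSample(
            "combined_gradual_phase", grab("combined", "gradual_rate")
        ),
        "combined_instant_phase": RateSample(
            "combined_instant_phase", grab("combined", "instant_min_rate")
        ),
    }


#: The published pairwise rate comparisons: each combined phase against its
#: pure counterpart, and gradual against instant.
RATE_COMPARISONS = [
    ("combined_gradual_phase", "gradual"),
    ("combined_instant_phase", "instant"),
    ("gradual", "instant"),
]


def unpaired_t(
    a: np.ndarray, b: np.ndarray, variant: str = "welch"
) -> Tuple[float, float]:
    """Two-sided unpaired t test; Welch (unequal variances) by default."""
    res = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(res.statistic), float(res.pvalue)


def rate_statistics(
    events: Sequence[LossEvent], t_variant: str = "welch"
) -> RateStatistics:
    """Per-class rate mean +/- SD and the pairwise unpaired t tests.

    A comparison whose sides do not both have >= 2 events is skipped with a
    warning.  Identical samples give t = 0, p = 1.
    """
    samples = _collect_rate_samples(events)
    comparisons: List[PairwiseTest] = []
    for left, right in RATE_COMPARISONS:
        a, b = samples[left].values, samples[right].values
        if len(a) < 2 or len(b) < 2:
            logger.warning("skipping %s vs %s: fewer than 2 events on one side", left, right)
            continue
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            stat, p = 0.0, 1.0
        else:
            stat, p = unpaired_t(a, b, t_variant)
        comparisons.append(PairwiseTest(pair=(left, right), test=f"t_{t_variant}", statistic=stat, pvalue=p))
    return RateStatistics(samples=samples, comparisons=comparisons)


def timing_histogram(
    events: Sequence[LossEvent], bin_minutes: float = 60.0, window_min: Optional[float] = None
) -> Dict[str, np.ndarray]:
    """Hourly (by default) counts of event start and end points.

    Returns bin edges (minutes) and the start/end counts per bin over the
    imaging window; with no events the histogram is all zeros over one bin.
    """
    starts = np.array([e.start_time_min for e in events if not e.censored], dtype=float)
    ends = np.array([e.end_time_min for e in events if not e.censored], dtype=float)
    if window_min is None:
        window_min = float(max(ends, default=0.0))
    n_bins = max(int(math.ceil(window_min / bin_minutes)), 1)
    edges = np.arange(0.0, (n_bins + 1) * bin_minutes, bin_minutes)
    start_counts, _ = np.histogram(starts, bins=edges)
    end_counts, _ = np.histogram(ends, bins=edges)
    return {"edges_min": edges, "start_counts": start_counts, "end_counts": end_counts}


# ---------------------------------------------------------------------------
# normality-gated two-sample comparison
# ---------------------------------------------------------------------------

@dataclass
class NormalityReport:
    pvalues: Dict[str, Optional[float]]  # test name -> p (None if not applicable)

    def verdicts(self, alpha: float) -> Dict[str, Optional[bool]]:
        return {
            name: (None if p is None else bool(p > alpha)) for name, p in self.pvalues.items()
        }


@dataclass
class ComparisonResult:
    """Outcome of a normality-gated comparison of two groups of measurements.

    ``test`` is ``t``, ``mannwhitney`` or ``both`` (mixed normality verdicts:
    both tests run, ``statistic``/``pvalue`` from the t test and
    ``secondary_*`` from Mann-Whitney).
    """

    test: str
    statistic: float
    pvalue: float
    normality_a: NormalityReport
    normality_b: NormalityReport
    secondary_statistic: Optional[float] = None
    secondary_pvalue: Optional[float] = None
    flags: Tuple[str, ...] = ()

    @property
    def significant(self) -> bool:
        return self.pvalue < 0.05


def normality_tests(values: np.ndarray) -> NormalityReport:
    """Kolmogorov-Smirnov (Lilliefors), D'Agostino-Pearson and Shapiro-Wilk
    normality p-values.  D'Agostino-Pearson needs n >= 8 and is reported as
    not-applicable below that."""
    from statsmodels.stats.diagnostic import lilliefors

    values = np.asarray(values, dtype=float)
    p: Dict[str, Optional[float]] = {}
    if np.ptp(values) == 0:
        return NormalityReport(pvalues={"ks_lilliefors": None, "dagostino_pearson": None, "shapiro": None})
    p["ks_lilliefors"] = float(lilliefors(values, dist="norm")[1])
    p["dagostino_pearson"] = (
        float(sps.normaltest(values).pvalue) if len(values) >= 8 else None
    )
    p["shapiro"] = float(sps.shapiro(values).pvalue)
    return NormalityReport(pvalues=p)


def compare_conditions(
    group_a: Sequence[float],
    group_b: Sequence[float],
    stats_cfg: Optional[StatsConfig] = None,
) -> ComparisonResult:
    """Normality-gated two-sample comparison (see module docstring).

    Requires >= 3 values per group.  Two identical constant groups are
    degenerate and reported as non-significant with a flag.
    """
    cfg = stats_cfg or StatsConfig()
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("compare_conditions requires at least 3 values per group")

    rep_a, rep_b = normality_tests(a), normality_tests(b)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        flags = ("degenerate_constant",)
        if a[0] == b[0]:
            return ComparisonResult("t", 0.0, 1.0, rep_a, rep_b, flags=flags)
        logger.warning("constant groups with different values; reporting Mann-Whitney")
        u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        return ComparisonResult("mannwhitney", float(u), float(p), rep_a, rep_b, flags=flags)

    verdicts = [
        v
        for rep in (rep_a, rep_b)
        for v in rep.verdicts(cfg.alpha).values()
        if v is not None
    ]
    all_normal = all(verdicts) if verdicts else True
    none_normal = not any(verdicts) if verdicts else False

    t_stat, t_p = unpaired_t(a, b, cfg.t_variant)
    u_res = sps.mannwhitneyu(a, b, alternative="two-sided")
    if all_normal:
        return ComparisonResult("t", t_stat, t_p, rep_a, rep_b)
    if none_normal:
        return ComparisonResult("mannwhitney", float(u_res.statistic), float(u_res.pvalue), rep_a, rep_b)
    return ComparisonResult(
        "both",
        t_stat,
        t_p,
        rep_a,
        rep_b,
        secondary_statistic=float(u_res.statistic),
        secondary_pvalue=float(u_res.pvalue),
        flags=("mixed_normality",),
    )


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

@dataclass
class CohortSummary:
    frequencies: ClassFrequencies
    rates: RateStatistics
    histogram: Dict[str, np.ndarray]
    n_censored: int

    def to_dict(self) -> dict:
        return {
            "n_classified": self.frequencies.n,
            "n_censored": self.n_censored,
            "counts": self.frequencies.counts,
            "relative_frequencies": self.frequencies.frequencies,
            "instant_terminal_fraction": self.frequencies.instant_terminal,
            "rates": {
                name: {"mean": s.mean, "sd": s.sd, "n": s.n}
                for name, s in self.rates.samples.items()
            },
            "rate_comparisons": [
                {
                    "pair": list(c.pair),
                    "test": c.test,
                    "statistic": c.statistic,
                    "pvalue": c.pvalue,
                }
                for c in self.rates.comparisons
            ],
            "timing_histogram": {
                "edges_min": self.histogram["edges_min"].tolist(),
                "start_counts": self.histogram["start_counts"].tolist(),
                "end_counts": self.histogram["end_counts"].tolist(),
            },
            "note": "pairwise rate tests are reported without multiple-testing correction",
        }


def summarize_cohort(
    events: Sequence[LossEvent],
    t_variant: str = "welch",
    bin_minutes: float = 60.0,
) -> CohortSummary:
    classified = [e for e in events if not e.censored]
    return CohortSummary(
        frequencies=class_frequencies(events),
        rates=rate_statistics(classified, t_variant=t_variant),
        histogram=timing_histogram(classified, bin_minutes=bin_minutes),
        n_censored=sum(e.censored for e in events),
    )
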