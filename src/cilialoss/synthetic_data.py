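"""Synthetic cohorts of cilium length trajectories with known ground truth.

The generator emulates SSTR3::GFP-derived length traces from long-term
confocal imaging: 30-90 s frame intervals over 6-12 h movies, a slight
background decline shared by all cilia (-0.005 um/min), and substantial
per-measurement noise (defaults calibrated so that the SD of consecutive
length differences of control cilia is 1.53 um, i.e. per-measurement sigma =
1.53 / sqrt(2)).  Event trajectories come in the three observed flavours:

gradual
    linear shortening at a log-normally distributed rate until the length
    reaches zero;
instant
    a flat (drifting) trace that drops from its penultimate length to zero
    within exactly one frame;
combined
    a plateau, then a gradual phase that ends when the remaining length is
    ``combined_instant_fraction`` of the maximum, then a single-frame drop.

Measurement noise is added only while the cilium exists: once it is gone
there is no object to measure and the recorded length is exactly zero, as in
the source movies.  Event end times are drawn so that completions peak 1-3 h
after serum addition (triangular distribution with mode 2 h by default).

Everything is bit-reproducible: a cohort is fully determined by its
:class:`SimulationConfig` (which includes the master seed); per-trajectory
generators are spawned from the master seed, so two master seeds give
disjoint noise realizations with identical cohort structure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .trajectory_io import (
    CohortManifest,
    LengthTrajectory,
    ManifestEntry,
    save_manifest,
    write_trajectories,
)

logger = logging.getLogger("cilialoss.synthetic")

RngLike = Union[int, np.random.Generator]


def _as_rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class TruncNormalSpec:
    """Normal(mean, sd) truncated below at ``floor``."""

    mean: float
    sd: float
    floor: float

    def draw(self, rng: np.random.Generator, floor: Optional[float] = None) -> float:
        lo = self.floor if floor is None else max(self.floor, floor)
        if self.sd == 0:
            if self.mean < lo:
                raise ValueError(f"degenerate truncated normal below its floor ({self.mean} < {lo})")
            return self.mean
        a = (lo - self.mean) / self.sd
        return float(sps.truncnorm.rvs(a, np.inf, loc=self.mean, scale=self.sd, random_state=rng))


@dataclass(frozen=True)
class LogNormalSpec:
    """Log-normal moment-matched to a natural-scale mean and SD, clipped
    below at ``floor``.  Rates are positive and strongly right-skewed in the
    source data (SDs rival or exceed the means), which a normal cannot
    represent."""

    mean: float
    sd: float
    floor: float = 0.0

    def params(self) -> Tuple[float, float]:
        sigma2 = math.log(1.0 + (self.sd / self.mean) ** 2)
        mu = math.log(self.mean) - sigma2 / 2.0
        return mu, math.sqrt(sigma2)

    def draw(self, rng: np.random.Generator) -> float:
        if self.sd == 0:
            return max(self.mean, self.floor)
        mu, sigma = self.params()
        return max(float(rng.lognormal(mu, sigma)), self.floor)


@dataclass(frozen=True)
class OnsetSpec:
    """Distribution of event *end* times (minutes from movie start).

    ``triangular`` peaks completions at the mode (default 2 h, so that the
    hourly end-point histogram is maximal at 1-3 h); ``uniform`` spreads them
    across the movie.
    """

    kind: str = "triangular"
    lo: float = 0.0
    mode: float = 120.0
    hi: float = 720.0

    def draw(self, rng: np.random.Generator) -> float:
        if self.kind == "triangular":
            return float(rng.triangular(self.lo, self.mode, self.hi))
        if self.kind == "uniform":
            return float(rng.uniform(self.lo, self.hi))
        raise ValueError(f"unknown onset distribution {self.kind!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative specification of a synthetic cohort.

    Defaults are the study conditions: 12-h movies at 90-s intervals, control
    drift -0.005 um/min, per-measurement noise 1.53/sqrt(2) um, gradual rates
    0.08 +/- 0.11 um/min, combined gradual-phase rates 0.08 +/- 0.26 um/min
    (clipped below at 0.01 um/min so the phase is distinguishable from the
    background drift), 72.6% of the maximum length lost in the instant phase
    of combined events, and the 11/32/26 gradual/instant/combined class
    counts with 10 controls.
    """

    n_control: int = 10
    n_gradual: int = 11
    n_instant: int = 32
    n_combined: int = 26
    duration_min: float = 720.0
    frame_interval_s: float = 90.0
    max_length: TruncNormalSpec = field(default_factory=lambda: TruncNormalSpec(5.0, 1.5, 2.0))
    gradual_rate: LogNormalSpec = field(default_factory=lambda: LogNormalSpec(0.08, 0.11, 0.001))
    combined_gradual_rate: LogNormalSpec = field(
        default_factory=lambda: LogNormalSpec(0.08, 0.26, 0.01)
    )
    instant_penultimate_floor: float = 1.6
    combined_instant_fraction: float = 0.726
    onset: OnsetSpec = field(default_factory=OnsetSpec)
    drift: float = -0.005  # um/min, applied to every trajectory
    noise_sd: float = 1.53 / math.sqrt(2.0)  # um, per measurement
    condition: str = "serum"
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0 or self.max_length.sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0.0 < self.combined_instant_fraction < 1.0:
            raise ValueError("combined_instant_fraction must be in (0, 1)")
        if self.instant_penultimate_floor <= 0:
            raise ValueError("instant_penultimate_floor must be > 0")
        if self.frame_interval_s <= 0 or self.duration_min <= 0:
            raise ValueError("frame_interval_s and duration_min must be > 0")

    @property
    def frame_interval_min(self) -> float:
        return self.frame_interval_s / 60.0

    @property
    def n_frames(self) -> int:
        return int(math.floor(self.duration_min / self.frame_interval_min)) + 1

    def grid_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_min

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data or {})
        if "max_length" in data and isinstance(data["max_length"], dict):
            data["max_length"] = TruncNormalSpec(**data["max_length"])
        for key in ("gradual_rate", "combined_gradual_rate"):
            if key in data and isinstance(data[key], dict):
                data[key] = LogNormalSpec(**data[key])
        if "onset" in data and isinstance(data["onset"], dict):
            data["onset"] = OnsetSpec(**data["onset"])
        return cls(**data)


@dataclass(frozen=True)
class TruthEvent:
    """Ground truth of one simulated loss event."""

    cilium_id: str
    event_class: str
    start_time_min: float  # onset of detectable shortening (drop time for instant)
    end_time_min: float  # completion (first zero frame)
    max_length_um: float
    penultimate_length_um: float
    gradual_rate: Optional[float]  # um/min, None for instant
    instant_min_rate: Optional[float]  # um/min, None for gradual
    fraction_instant: float


def _noisy(
    noiseless: np.ndarray, end_index: Optional[int], noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Add measurement noise where the cilium exists; exact zeros after loss."""
    out = noiseless.copy()
    live = np.ones(len(out), dtype=bool)
    if end_index is not None:
        live[end_index:] = False
    if noise_sd > 0:
        out[live] += rng.normal(0.0, noise_sd, size=int(live.sum()))
    out[live] = np.clip(out[live], 0.0, None)
    out[~live] = 0.0
    return out


def simulate_control(
    config: SimulationConfig, seed: RngLike, cilium_id: str = "control_000"
) -> LengthTrajectory:
    """A non-disassembling control cilium: initial length from the max-length
    distribution, linear drift, i.i.d. Gaussian measurement noise, clipped at
    zero.  Warns if the drift alone would take the noiseless track to zero
    within the movie (a control should not disassemble)."""
    rng = _as_rng(seed)
    # a control is a cilium that visibly persists for the whole movie: its
    # initial length is drawn conditioned on ending above the ~1 um
    # resolvability scale after the full background drift
    survival_floor = max(0.0, -config.drift) * config.duration_min + 1.0
    l0 = config.max_length.draw(rng, floor=survival_floor)
    t = config.grid_min()
    noiseless = l0 + config.drift * t
    if noiseless[-1] <= 0:
        logger.warning(
            "control %s: drift %.4g um/min drives the noiseless track to 0 within %g min",
            cilium_id,
            config.drift,
            config.duration_min,
        )
    noiseless = np.clip(noiseless, 0.0, None)
    lengths = _noisy(noiseless, None, config.noise_sd, rng)
    return LengthTrajectory(
        cilium_id=cilium_id,
        condition=config.condition,
        role="control",
        times=t * 60.0,
        lengths=lengths,
        frame_interval=config.frame_interval_s,
    )


def _snap_end_index(config: SimulationConfig, t_end: float) -> int:
    """Grid index of the first zero frame, clamped so that at least two
    pre-event frames exist and the zero frame is inside the movie."""
    j = int(round(t_end / config.frame_interval_min))
    return int(np.clip(j, 2, config.n_frames - 1))


def _draw_instant_geometry(config: SimulationConfig, rng: np.random.Generator):
    pen = config.max_length.draw(rng, floor=config.instant_penultimate_floor)
    j_end = _snap_end_index(config, config.onset.draw(rng))
    return pen, j_end


def _draw_gradual_geometry(config: SimulationConfig, rng: np.random.Generator):
    m = config.max_length.draw(rng)
    rate = config.gradual_rate.draw(rng)
    j_end = _snap_end_index(config, config.onset.draw(rng))
    return m, rate, j_end


def _draw_combined_geometry(config: SimulationConfig, rng: np.random.Generator, max_tries: int = 200):
    """Draw (max length, rate, end index) such that the combined event fits:
    a plateau of at least one frame, a gradual phase of at least one frame,
    and a penultimate length above the floor (the max-length draw is floored
    at instant_penultimate_floor / combined_instant_fraction).

    The observable gradual-phase drop (plateau value at onset minus the
    penultimate length) must retain at least half of the nominal
    (1 - combined_instant_fraction) share of the maximum length: the Combined
    category is operationally defined by a visible gradual phase, and a phase
    whose length loss has been pre-consumed by the background drift is not an
    exemplar of it.
    """
    f = config.combined_instant_fraction
    dt = config.frame_interval_min
    for _ in range(max_tries):
        m = config.max_length.draw(rng, floor=config.instant_penultimate_floor / f)
        rate = config.combined_gradual_rate.draw(rng)
        if rate + config.drift <= 0:
            continue  # phase slower than the background drift: no distinct onset
        for _ in range(100):
            j_end = _snap_end_index(config, config.onset.draw(rng))
            t_pen = (j_end - 1) * dt
            pen = f * m
            # onset of the gradual phase: intersection of the plateau
            # (m + drift t) with the decline line through (t_pen, pen)
            t_s = (pen + rate * t_pen - m) / (rate + config.drift)
            if not (dt <= t_s <= t_pen - dt):
                continue
            phase_drop = (m + config.drift * t_s) - pen
            if phase_drop >= 0.5 * (1.0 - f) * m:
                return m, rate, j_end, t_s
    raise ValueError("could not draw a feasible combined event; check simulation parameters")


def simulate_event(
    event_class: str,
    config: SimulationConfig,
    seed: RngLike,
    cilium_id: Optional[str] = None,
) -> Tuple[LengthTrajectory, TruthEvent]:
    """One labelled disassembling trajectory plus its ground truth.

    Instant events are parameterized by their pre-drop (penultimate) length,
    drawn from the max-length distribution floored at
    ``instant_penultimate_floor``; the plateau is back-extrapolated along the
    drift, so the drawn value is exactly the noiseless penultimate length.
    """
    if event_class not in ("gradual", "instant", "combined"):
        raise ValueError(f"unknown event class {event_class!r}")
    rng = _as_rng(seed)
    cid = cilium_id or f"{event_class}_000"
    t = config.grid_min()
    dt = config.frame_interval_min
    drift = config.drift

    if event_class == "instant":
        pen, j_end = _draw_instant_geometry(config, rng)
        t_pen = t[j_end - 1]
        noiseless = np.clip(pen + drift * (t - t_pen), 0.0, None)
        truth = TruthEvent(
            cilium_id=cid,
            event_class="instant",
            start_time_min=float(t_pen),
            end_time_min=float(t[j_end]),
            max_length_um=float(noiseless[0]),
            penultimate_length_um=pen,
            gradual_rate=None,
            instant_min_rate=pen / dt,
            fraction_instant=pen / float(noiseless[0]),
        )
    elif event_class == "gradual":
        m, rate, j_end = _draw_gradual_geometry(config, rng)
        t_end = t[j_end]
        plateau = m + drift * t
        decline = rate * (t_end - t)
        noiseless = np.clip(np.minimum(plateau, decline), 0.0, None)
        below = np.nonzero(decline < plateau)[0]  # frames on the decline branch
        t_s = float(t[below[0]]) if len(below) else float(t[j_end - 1])
        pen = float(noiseless[j_end - 1])
        truth = TruthEvent(
            cilium_id=cid,
            event_class="gradual",
            start_time_min=float(max(t_s, 0.0)),
            end_time_min=float(t_end),
            max_length_um=float(noiseless[0]),
            penultimate_length_um=pen,
            gradual_rate=rate,
            instant_min_rate=None,
            fraction_instant=pen / float(np.max(noiseless)),
        )
    else:  # combined
        m, rate, j_end, t_s = _draw_combined_geometry(config, rng)
        t_pen = t[j_end - 1]
        pen = config.combined_instant_fraction * m
        plateau = m + drift * t
        decline = pen + rate * (t_pen - t)
        noiseless = np.clip(np.minimum(plateau, decline), 0.0, None)
        truth = TruthEvent(
            cilium_id=cid,
            event_class="combined",
            start_time_min=float(t_s),
            end_time_min=float(t[j_end]),
            max_length_um=float(noiseless[0]),
            penultimate_length_um=pen,
            gradual_rate=rate,
            instant_min_rate=pen / dt,
            fraction_instant=pen / float(np.max(noiseless)),
        )

    lengths = _noisy(noiseless, j_end, config.noise_sd, rng)
    # the pre-drop frame keeps a strictly positive measured value so the
    # noiseless penultimate point is never absorbed into the zero tail
    if lengths[j_end - 1] <= 0.0:
        lengths[j_end - 1] = max(noiseless[j_end - 1], 1e-6)
    traj = LengthTrajectory(
        cilium_id=cid,
        condition=config.condition,
        role="experimental",
        times=t * 60.0,
        lengths=lengths,
        frame_interval=config.frame_interval_s,
    )
    return traj, truth


@dataclass
class SimulatedCohort:
    trajectories: List[LengthTrajectory]
    truth: List[TruthEvent]
    manifest: CohortManifest
    config: SimulationConfig

    @property
    def truth_by_id(self) -> Dict[str, TruthEvent]:
        return {t.cilium_id: t for t in self.truth}


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """A full labelled cohort: controls plus events of each class, one
    spawned random stream per trajectory (bit-reproducible for a fixed
    config)."""
    counts = {
        "control": config.n_control,
        "gradual": config.n_gradual,
        "instant": config.n_instant,
        "combined": config.n_combined,
    }
    if all(v == 0 for v in counts.values()):
        raise ValueError("simulate_cohort: all counts are zero")
    plan = [
        (kind, f"{kind}_{i:03d}")
        for kind in ("control", "gradual", "instant", "combined")
        for i in range(counts[kind])
    ]
    streams = np.random.SeedSequence(config.seed).spawn(len(plan))
    trajectories: List[LengthTrajectory] = []
    truth: List[TruthEvent] = []
    entries: List[ManifestEntry] = []
    for (kind, cid), ss in zip(plan, streams):
        rng = np.random.default_rng(ss)
        if kind == "control":
            trajectories.append(simulate_control(config, rng, cilium_id=cid))
        else:
            traj, tr = simulate_event(kind, config, rng, cilium_id=cid)
            trajectories.append(traj)
            truth.append(tr)
        entries.append(
            ManifestEntry(
                cilium_id=cid,
                condition=config.condition,
                role="control" if kind == "control" else "experimental",
            )
        )
    return SimulatedCohort(
        trajectories=trajectories, truth=truth, manifest=CohortManifest(entries), config=config
    )


def truth_to_frame(truth: Sequence[TruthEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cilium_id": t.cilium_id,
                "class": t.event_class,
                "start_time_min": t.start_time_min,
                "end_time_min": t.end_time_min,
                "max_length_um": t.max_length_um,
                "penultimate_length_um": t.penultimate_length_um,
                "gradual_rate_um_per_min": t.gradual_rate,
                "instant_min_rate_um_per_min": t.instant_min_rate,
                "fraction_instant": t.fraction_instant,
            }
            for t in truth
        ]
    )


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> Dict[str, Path]:
    """Write a fixture directory: trajectories.csv (long layout),
    manifest.csv, truth.csv and the generating config (for provenance)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "trajectories": outdir / "trajectories.csv",
        "manifest": outdir / "manifest.csv",
        "truth": outdir / "truth.csv",
        "config": outdir / "simulation_config.yaml",
    }
    write_trajectories(cohort.trajectories, paths["trajectories"])
    save_manifest(cohort.manifest, paths["manifest"])
    truth_to_frame(cohort.truth).to_csv(paths["truth"], index=False, float_format="%.6f")
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cohort.config.to_dict(), fh, sort_keys=False)
    return paths
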