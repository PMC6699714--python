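"""Pipeline configuration.

Every threshold used anywhere in the pipeline lives here with its default, so a
run is fully specified by one flat YAML file plus a seed.  The defaults encode
the published analysis constants for SSTR3::GFP length traces: an Instant
threshold of 1.532 um (length-measurement error of the imaging setup) and a
control drift of -0.005 um/min (background decline of non-disassembling cilia
over 12 h).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

#: Length-measurement-error threshold (um) separating a genuine single-frame
#: loss from noise, used when no control cilia are available to calibrate one.
DEFAULT_INSTANT_THRESHOLD_UM = 1.532

#: Background length drift (um/min) of non-disassembling control cilia.
DEFAULT_MEAN_SLOPE_UM_PER_MIN = -0.005


@dataclass
class IOConfig:
    """Table layout for trajectory input: ``long`` (cilium_id, time_s,
    length_um) or ``wide`` (time_s column + one length column per cilium)."""

    layout: str = "long"

    def validate(self) -> None:
        if self.layout not in ("long", "wide"):
            raise ValueError(f"io.layout must be 'long' or 'wide', got {self.layout!r}")


@dataclass
class SmoothingConfig:
    """Moving-average smoothing applied before derivative-based detection.

    ``kernel`` is either ``gaussian_weighted`` (Gaussian weights with
    sigma = window/4 frames) or ``uniform``.  ``window`` is in frames and must
    be odd; window 1 disables smoothing.
    """

    window: int = 5
    kernel: str = "gaussian_weighted"

    def validate(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"smoothing.window must be a positive odd integer, got {self.window}")
        if self.kernel not in ("gaussian_weighted", "uniform"):
            raise ValueError(f"unknown smoothing.kernel {self.kernel!r}")


@dataclass
class BaselineConfig:
    """Overrides for the control-derived baseline.

    When control trajectories are present the baseline is estimated from them;
    an override, if set, wins.  With no controls, analysis requires
    ``instant_threshold_override`` to be set (the shipped constant 1.532 um is
    the natural choice) and uses ``DEFAULT_MEAN_SLOPE_UM_PER_MIN`` unless
    ``mean_slope_override`` says otherwise.
    """

    instant_threshold_override: Optional[float] = None
    mean_slope_override: Optional[float] = None


@dataclass
class EventConfig:
    """Event detection and classification knobs.

    zero_tol
        Length (um) at or below which the cilium counts as gone.  0.0 reads
        "length = 0 um" literally; raise it if the background fluorescence
        leaves a floor.
    slope_tol_factor
        The backward scan stops when |derivative| <= slope_tol_factor *
        |mean control slope|.  1.0 reads "not different in magnitude" as <=.
    start_mode
        ``robust`` (default): a span-significance test decides whether any
        gradual phase exists before the terminal drop, and the backward scan
        uses a noise-adaptive tolerance.  Reduces exactly to ``literal`` when
        the calibrated measurement error is zero.  ``literal``: the bare
        per-frame rule.
    robust_k
        z-threshold for the robust mode's significance tests.
    degenerate_policy
        Class assigned when the start coincides with the penultimate point but
        the penultimate length is at or below the Instant threshold (a
        single-frame drop indistinguishable from measurement error).  Only
        ``gradual`` is implemented; such events are flagged ``degenerate``.
    max_quantile
        Quantile of the smoothed pre-completion series used as the noise-robust
        maximum length for the per-phase fractions (1.0 = plain maximum).
    """

    zero_tol: float = 0.0
    slope_tol_factor: float = 1.0
    start_mode: str = "robust"
    robust_k: float = 3.0
    degenerate_policy: str = "gradual"
    max_quantile: float = 0.95

    def validate(self) -> None:
        if self.zero_tol < 0:
            raise ValueError("event.zero_tol must be >= 0")
        if self.slope_tol_factor < 0:
            raise ValueError("event.slope_tol_factor must be >= 0")
        if self.start_mode not in ("robust", "literal"):
            raise ValueError(f"unknown event.start_mode {self.start_mode!r}")
        if self.degenerate_policy != "gradual":
            raise ValueError("event.degenerate_policy: only 'gradual' is supported")
        if not 0.0 < self.max_quantile <= 1.0:
            raise ValueError("event.max_quantile must be in (0, 1]")


@dataclass
class StatsConfig:
    """Two-sample comparison settings: Welch's unpaired t test by default
    (``student`` selects the pooled-variance variant) and the alpha used by
    the normality gate."""

    t_variant: str = "welch"
    alpha: float = 0.05

    def validate(self) -> None:
        if self.t_variant not in ("welch", "student"):
            raise ValueError(f"unknown stats.t_variant {self.t_variant!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("stats.alpha must be in (0, 1)")


@dataclass
class PipelineConfig:
    io: IOConfig = field(default_factory=IOConfig)
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    event: EventConfig = field(default_factory=EventConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def validate(self) -> "PipelineConfig":
        self.io.validate()
        self.smoothing.validate()
        self.event.validate()
        self.stats.validate()
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        cfg = cls()
        sections = {
            "io": cfg.io,
            "smoothing": cfg.smoothing,
            "baseline": cfg.baseline,
            "event": cfg.event,
            "stats": cfg.stats,
        }
        for name, payload in (data or {}).items():
            if name == "simulation":  # handled by synthetic_data
                continue
            if name not in sections:
                raise KeyError(f"unknown config section {name!r}")
            section = sections[name]
            for key, value in (payload or {}).items():
                if not hasattr(section, key):
                    raise KeyError(f"unknown config key {name}.{key}")
                setattr(section, key, value)
        return cfg.validate()


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline configuration from a YAML file (missing keys keep
    their defaults)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
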