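"""Reading and writing trajectories, cohort manifests and event tables.

The atomic input is one cilium's length-vs-time series measured from
fluorescence (SSTR3::GFP) movies: times in seconds from movie start, lengths
in micrometres.  Two table layouts are accepted: *long* (``cilium_id, time_s,
length_um``) and *wide* (a ``time_s`` column plus one length column per
cilium, matching spreadsheets with per-cilium blocks).  A cohort manifest maps
cilium ids to a condition label and a role (``control`` for non-disassembling
serum-starved cilia used to calibrate the baseline, ``experimental`` for cilia
undergoing serum-induced loss).

Negative raw lengths are clipped to zero with a warning; rows are never
silently dropped (every input trajectory is either stored or warned about).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger("cilialoss.io")

ROLES = ("control", "experimental")

#: Fixed header of the per-event output table.
EVENT_COLUMNS = [
    "cilium_id",
    "condition",
    "class",
    "start_time_min",
    "end_time_min",
    "start_length_um",
    "penultimate_length_um",
    "max_length_um",
    "gradual_rate_um_per_min",
    "instant_min_rate_um_per_min",
    "fraction_gradual",
    "fraction_instant",
    "flags",
]


class ManifestError(ValueError):
    """A manifest entry could not be matched to the data."""


@dataclass(frozen=True)
class LengthTrajectory:
    """One cilium's length time series with its cohort metadata.

    ``times`` are seconds from movie start (strictly increasing, >= 3 points);
    ``lengths`` are micrometres, non-negative.  ``frame_interval`` is the
    nominal acquisition interval in seconds (30-90 s movies; manually sampled
    pre-event stretches may be much sparser, in which case the trajectory is
    flagged ``irregular`` and derivative computations use the actual dt).
    """

    cilium_id: str
    condition: str
    role: str
    times: np.ndarray
    lengths: np.ndarray
    frame_interval: float
    flags: Tuple[str, ...] = ()

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        lengths = np.asarray(self.lengths, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "lengths", lengths)
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if times.ndim != 1 or lengths.shape != times.shape:
            raise ValueError("times and lengths must be 1-D and of equal length")
        if len(times) < 3:
            raise ValueError(f"trajectory {self.cilium_id!r} has fewer than 3 points")
        if np.any(np.diff(times) <= 0):
            raise ValueError(f"trajectory {self.cilium_id!r}: times must be strictly increasing")
        if np.any(lengths < 0):
            raise ValueError(f"trajectory {self.cilium_id!r}: lengths must be >= 0 (clip on read)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        med = float(np.median(np.diff(times)))
        if abs(med - self.frame_interval) > 0.1 * self.frame_interval and "irregular" not in self.flags:
            object.__setattr__(self, "flags", self.flags + ("irregular",))

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def times_min(self) -> np.ndarray:
        """Acquisition times in minutes from movie start."""
        return self.times / 60.0


@dataclass(frozen=True)
class ManifestEntry:
    cilium_id: str
    condition: str
    role: str
    source: Optional[str] = None


@dataclass
class CohortManifest:
    """Assignment of trajectories to conditions and control/experimental roles."""

    entries: List[ManifestEntry] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for e in self.entries:
            key = (e.condition, e.cilium_id)
            if key in seen:
                raise ManifestError(f"duplicate cilium_id {e.cilium_id!r} in condition {e.condition!r}")
            seen.add(key)
            if e.role not in ROLES:
                raise ManifestError(f"{e.cilium_id}: role must be one of {ROLES}, got {e.role!r}")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)


def load_manifest(path: str | Path) -> CohortManifest:
    """Read a manifest CSV with columns cilium_id, condition, role[, source]."""
    df = _read_table(path)
    required = {"cilium_id", "condition", "role"}
    if not required.issubset(df.columns):
        raise ManifestError(f"manifest must have columns {sorted(required)}, got {list(df.columns)}")
    entries = [
        ManifestEntry(
            cilium_id=str(r.cilium_id),
            condition=str(r.condition),
            role=str(r.role),
            source=str(r.source) if "source" in df.columns and not pd.isna(r.source) else None,
        )
        for r in df.itertuples()
    ]
    return CohortManifest(entries)


def save_manifest(manifest: CohortManifest, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"cilium_id": e.cilium_id, "condition": e.condition, "role": e.role, "source": e.source}
            for e in manifest
        ]
    ).to_csv(path, index=False)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tsv", ".tab"):
        return pd.read_csv(path, sep="\t")
    if suffix in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path)


def _infer_frame_interval(times: np.ndarray) -> float:
    return float(np.median(np.diff(times)))


def read_trajectories(
    source: str | Path | pd.DataFrame,
    manifest: CohortManifest,
    layout: str = "long",
) -> List[LengthTrajectory]:
    """Read one :class:`LengthTrajectory` per manifest entry from a table.

    Negative lengths are clipped to 0 (warning logged).  Trajectories with
    fewer than 3 points are skipped with a warning; non-monotone time is a
    hard error; a manifest id missing from the table is a hard error naming
    the id.  Ids present in the table but absent from the manifest are
    warned about, never silently dropped.
    """
    df = source if isinstance(source, pd.DataFrame) else _read_table(source)
    if layout == "wide":
        series = _series_from_wide(df)
    elif layout == "long":
        series = _series_from_long(df)
    else:
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")

    manifest_ids = {e.cilium_id for e in manifest}
    for extra in sorted(set(series) - manifest_ids):
        logger.warning("cilium %r present in data but not in manifest; ignored", extra)

    out: List[LengthTrajectory] = []
    for entry in manifest:
        if entry.cilium_id not in series:
            raise ManifestError(f"manifest entry {entry.cilium_id!r} not found in data source")
        times, lengths = series[entry.cilium_id]
        order = np.argsort(times, kind="stable")
        if np.any(np.diff(times) < 0):
            raise ValueError(f"trajectory {entry.cilium_id!r}: non-monotone time")
        times, lengths = times[order], lengths[order]
        n_neg = int(np.sum(lengths < 0))
        if n_neg:
            logger.warning("cilium %r: clipped %d negative length(s) to 0", entry.cilium_id, n_neg)
            lengths = np.clip(lengths, 0.0, None)
        if len(times) < 3:
            logger.warning("cilium %r: fewer than 3 points; skipped", entry.cilium_id)
            continue
        traj = LengthTrajectory(
            cilium_id=entry.cilium_id,
            condition=entry.condition,
            role=entry.role,
            times=times,
            lengths=lengths,
            frame_interval=_infer_frame_interval(times),
            flags=("clipped",) if n_neg else (),
        )
        if "irregular" in traj.flags:
            logger.warning("cilium %r: irregular frame spacing", entry.cilium_id)
        out.append(traj)
    return out


def _series_from_long(df: pd.DataFrame) -> dict:
    required = {"cilium_id", "time_s", "length_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"long layout needs columns {sorted(required)}, got {list(df.columns)}")
    series = {}
    for cid, group in df.groupby("cilium_id", sort=False):
        series[str(cid)] = (
            group["time_s"].to_numpy(dtype=float),
            group["length_um"].to_numpy(dtype=float),
        )
    return series


def _series_from_wide(df: pd.DataFrame) -> dict:
    if "time_s" not in df.columns:
        raise ValueError("wide layout needs a 'time_s' column")
    times = df["time_s"].to_numpy(dtype=float)
    series = {}
    for col in df.columns:
        if col == "time_s":
            continue
        values = df[col].to_numpy(dtype=float)
        keep = ~np.isnan(values)
        series[str(col)] = (times[keep], values[keep])
    return series


def write_trajectories(trajectories: Sequence[LengthTrajectory], path: str | Path) -> None:
    """Write trajectories as a long-format CSV (cilium_id, time_s, length_um)."""
    frames = [
        pd.DataFrame(
            {"cilium_id": t.cilium_id, "time_s": t.times, "length_um": t.lengths}
        )
        for t in trajectories
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def events_to_frame(events: Iterable) -> pd.DataFrame:
    """Flatten LossEvent objects into the fixed-header output table."""
    rows = []
    for ev in events:
        rows.append(
            {
                "cilium_id": ev.cilium_id,
                "condition": ev.condition,
                "class": ev.event_class,
                "start_time_min": ev.start_time_min,
                "end_time_min": ev.end_time_min,
                "start_length_um": ev.start_length_um,
                "penultimate_length_um": ev.penultimate_length_um,
                "max_length_um": ev.max_length_um,
                "gradual_rate_um_per_min": ev.gradual_rate,
                "instant_min_rate_um_per_min": ev.instant_min_rate,
                "fraction_gradual": ev.fraction_gradual,
                "fraction_instant": ev.fraction_instant,
                "flags": ";".join(ev.flags) if ev.flags else "",
            }
        )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_events_table(events: Iterable, path: str | Path) -> pd.DataFrame:
    """Write the per-event results table as CSV (4-decimal precision).

    One row per event; absent rates (for example the gradual rate of a pure
    Instant event) are left empty.  An empty event list yields a header-only
    file.  Returns the frame written.
    """
    df = events_to_frame(events)
    df.to_csv(path, index=False, float_format="%.4f")
    return df


def read_events_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns and c != "flags"]
    if missing:
        raise ValueError(f"events table {path} is missing columns {missing}")
    if "flags" in df.columns:
        df["flags"] = df["flags"].fillna("")
    return df
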