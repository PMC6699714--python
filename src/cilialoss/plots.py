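"""Figure helpers (matplotlib, Agg backend): raw curves, averaged normalized
curves with event-start markers, stacked class frequencies, and rate dot
plots."""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cohort_analysis import ClassFrequencies, NormalizedCurve, RateStatistics, average_curves
from .trajectory_io import LengthTrajectory

CLASS_COLORS = {"gradual": "#4878CF", "instant": "#D65F5F", "combined": "#6ACC65"}


def plot_raw_curves(trajectories: Sequence[LengthTrajectory], path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for traj in trajectories:
        ax.plot(traj.times_min, traj.lengths, lw=0.8, alpha=0.6)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("cilium length (μm)")
    ax.set_title("raw length trajectories")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_normalized_average(
    curves_by_class: Dict[str, Sequence[NormalizedCurve]], path: str | Path
) -> None:
    """Averaged normalized curves per class; open circles mark individual
    event start points on the averaged curve."""
    fig, axes = plt.subplots(1, max(len(curves_by_class), 1), figsize=(4 * max(len(curves_by_class), 1), 3.2), squeeze=False)
    for ax, (cls, curves) in zip(axes[0], sorted(curves_by_class.items())):
        if not curves:
            ax.set_visible(False)
            continue
        grid, mean_curve, markers = average_curves(curves)
        color = CLASS_COLORS.get(cls, "k")
        ax.plot(grid, mean_curve, color=color, lw=2)
        marker_y = np.interp(markers, grid, mean_curve)
        ax.plot(markers, marker_y, "o", mfc="none", mec=color, ms=5)
        ax.axhline(0.5, ls="--", c="grey", lw=0.7)
        ax.axvline(800, ls="--", c="grey", lw=0.7)
        ax.set_ylim(0, 1.05)
        ax.set_title(f"{cls} (n={len(curves)})")
        ax.set_xlabel("normalized time (a.u.)")
    axes[0][0].set_ylabel("normalized length")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_class_frequencies(freqs: ClassFrequencies, path: str | Path, label: str = "") -> None:
    fig, ax = plt.subplots(figsize=(3, 4))
    bottom = 0.0
    for cls in ("gradual", "instant", "combined"):
        frac = freqs.frequencies[cls]
        ax.bar([0], [frac], bottom=[bottom], color=CLASS_COLORS[cls], label=cls)
        bottom += frac
    ax.set_xticks([0])
    ax.set_xticklabels([label or f"n={freqs.n}"])
    ax.set_ylabel("relative frequency")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_rates(stats: RateStatistics, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    order = ["gradual", "combined_gradual_phase", "combined_instant_phase", "instant"]
    rng = np.random.default_rng(0)  # jitter only, cosmetic
    for x, name in enumerate(order):
        sample = stats.samples[name]
        if sample.n == 0:
            continue
        jitter = rng.uniform(-0.12, 0.12, sample.n)
        ax.plot(x + jitter, sample.values, "o", ms=3, alpha=0.6)
        ax.errorbar([x], [sample.mean], yerr=[sample.sd] if sample.n > 1 else None, fmt="_", c="k", capsize=4)
    ax.set_yscale("log")
    ax.set_xticks(range(len(order)))
    ax.set_xticklabels([o.replace("_", "\n") for o in order], fontsize=8)
    ax.set_ylabel("rate (μm/min)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
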