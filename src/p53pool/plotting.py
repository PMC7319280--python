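"""Report figures: fit overlays, condensed-sensitivity grids, rankings."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .calibration import CalibrationConfig, simulated_extrema
from .clustering import PeakBasedMean
from .pool import ModelPool

__all__ = ["plot_fit_overlays", "plot_sensitivity_grid", "plot_ranking"]

_CALL_COLORS = {"increase": "#c0392b", "decrease": "#2e6da4",
                "no-effect": "#bfbfbf", "inconsistent": "#ffffff",
                "undefined": "#f2e3c6"}


def plot_fit_overlays(pool: ModelPool, targets: Sequence[PeakBasedMean],
                      path: str | Path, config: CalibrationConfig = CalibrationConfig()) -> None:
    """Per-subpopulation simulated p53 with the target extrema overlaid."""
    k = pool.n_subpopulations
    ncol = min(5, k)
    nrow = int(np.ceil(k / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.2 * nrow),
                             squeeze=False, sharex=True)
    for i in range(nrow * ncol):
        ax = axes[i // ncol][i % ncol]
        if i >= k:
            ax.axis("off")
            continue
        traj, _ = simulated_extrema(pool.member_params(i), config,
                                    scale=pool.scale, offset=pool.offset)
        ax.plot(traj.times, traj.values, color="crimson", lw=1.2, label="simulation")
        t = targets[i]
        ax.plot(t.peak_times, t.peak_values, "o", color="navy", ms=4, label="target maxima")
        ok = ~np.isnan(t.min_times)
        ax.plot(t.min_times[ok], t.min_values[ok], "s", color="steelblue", ms=3.5)
        ax.set_title(f"subpopulation {i + 1} (n={t.n_members})", fontsize=8)
    fig.supxlabel("time post IR (h)")
    fig.supylabel("p53 reporter (a.u.)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_sensitivity_grid(report: pd.DataFrame, path: str | Path) -> None:
    """Condensed-call grid: rows = combination x feature, columns = subpopulations."""
    report = report.copy()
    report["row"] = report["combination"] + " | " + report["feature"]
    rows = sorted(report["row"].unique())
    cols = sorted(report["subpopulation"].unique())
    fig, ax = plt.subplots(figsize=(0.45 * len(cols) + 3, 0.3 * len(rows) + 1.5))
    for _, rec in report.iterrows():
        i = rows.index(rec["row"])
        j = cols.index(rec["subpopulation"])
        ax.add_patch(plt.Rectangle((j, i), 1, 1, ec="0.6",
                                   fc=_CALL_COLORS.get(rec["call"], "white")))
    ax.set_xlim(0, len(cols))
    ax.set_ylim(len(rows), 0)
    ax.set_xticks(np.arange(len(cols)) + 0.5, [str(c) for c in cols], fontsize=7)
    ax.set_yticks(np.arange(len(rows)) + 0.5, rows, fontsize=6)
    ax.set_xlabel("subpopulation")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_ranking(table: pd.DataFrame, path: str | Path,
                 score: str = "chi2") -> None:
    """Horizontal bar chart of ranked combination scores (log scale)."""
    fig, ax = plt.subplots(figsize=(6, 0.3 * len(table) + 1.2))
    ax.barh(table["combination"], table[score], color="slategray")
    ax.set_xscale("log")
    ax.invert_yaxis()
    ax.set_xlabel(score)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
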