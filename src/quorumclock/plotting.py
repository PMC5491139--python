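"""Small diagnostic figures for trajectories and synchronization reports."""

from __future__ import annotations

import numpy as np

from .analysis import SyncReport, weighted_mean_trace
from .ensemble import EnsembleTrajectory


def plot_population_gfp(traj: EnsembleTrajectory, n_show: int = 20, ax=None,
                        t_max: float | None = None):
    """Per-cell GFP traces with arithmetic and weighted means overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    g = traj.gfp
    mask = slice(None) if t_max is None else traj.times <= t_max
    t = traj.times[mask]
    for i in range(min(n_show, traj.n_cells)):
        ax.plot(t, g[mask][:, i], lw=0.5, alpha=0.5)
    ax.plot(t, g[mask].mean(axis=1), "k-", lw=2, label="arithmetic mean")
    ax.plot(t, weighted_mean_trace(g[mask]), "k--", lw=2, label="weighted mean")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("GFP (model units)")
    ax.legend(frameon=False)
    return ax


def plot_sync_report(report: SyncReport, axes=None):
    """Windowed SD and order-parameter series; marks the sync time."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(2, 1, figsize=(9, 6), sharex=True)
    ax1, ax2 = axes
    ax1.plot(report.sd_times, report.sd_series, "o-", ms=3)
    ax1.set_ylabel("windowed SD of GFP")
    r = report.order_parameter_series
    ax2.plot(np.arange(len(r)), r, lw=0.8)
    ax2.set_ylabel("order parameter")
    ax2.set_ylim(0, 1.05)
    ax2.set_xlabel("frame")
    if report.sync_time is not None:
        ax1.axvline(report.sync_time, color="r", ls=":",
                    label=f"sync at {report.sync_time:.0f} min")
        ax1.legend(frameon=False)
    return axes
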