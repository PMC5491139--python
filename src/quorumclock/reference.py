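"""Reference study conditions and their summary quantities.

Bundles the simulation protocols the package's headline numbers come from:
the isolated-cell (AI -> 0) period, and the 500-cell coupled run from
desynchronized initial conditions with its per-cell and bulk periods,
synchronization time and partial-synchronization onset.  Both the test
suite and the reproduction script drive these functions, so every reported
quantity is recomputed from scratch by an actual simulation.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import analysis
from .ensemble import EnsembleTrajectory, init_population, integrate
from .errors import NoOscillationError
from .model import ModelParameters

#: Study conditions: population size and horizons (minutes).
N_CELLS = 500
FULL_HORIZON = 43200.0        # 30 days
ISOLATED_HORIZON = 5000.0
DT_OUT = 10.0
TRANSIENT = 500.0


def isolated_period(seed: int, p: ModelParameters | None = None,
                    t_end: float = ISOLATED_HORIZON,
                    dt_out: float = DT_OUT) -> float:
    """Peak-to-peak GFP period (minutes) of one isolated cell (Q = 0)."""
    p = p or ModelParameters()
    pop = init_population(1, p, seed=seed)
    traj = integrate(pop, p, t_end, dt_out, seed=seed + 1, S_ext_override=0.0)
    trace = traj.gfp[traj.times >= TRANSIENT, 0]
    period, _ = analysis.estimate_period(trace, dt_out)
    return period


def isolated_period_median(seed: int, n_seeds: int = 10,
                           p: ModelParameters | None = None) -> float:
    """Median isolated-cell period over ``n_seeds`` replicate seeds."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(2**30, size=n_seeds)
    return float(np.median([isolated_period(int(s), p) for s in seeds]))


def coupled_run(seed: int, p: ModelParameters | None = None,
                n_cells: int = N_CELLS, t_end: float = FULL_HORIZON,
                dt_out: float = DT_OUT) -> EnsembleTrajectory:
    """The reference coupled ensemble from desynchronized initial states."""
    p = p or ModelParameters()
    pop = init_population(n_cells, p, seed=seed)
    return integrate(pop, p, t_end, dt_out, seed=seed + 1)


def _sustained_threshold_time(g: np.ndarray, dt: float, threshold: float):
    return analysis.detect_sync_time(g, dt, criterion="order_parameter",
                                     threshold=threshold)


def coupled_summary(traj: EnsembleTrajectory) -> dict:
    """All population-level summary quantities of a coupled run.

    Returns a dict with (minutes unless noted):
      sync_time          earliest sustained order parameter >= 0.9
      partial_sync_time  earliest sustained order parameter >= 0.5
      coupled_period     median per-cell period after sync_time
      bulk_period        weighted-mean-trace period; measured over the first
                         1080 min if the bulk oscillates there, else over the
                         pre-synchronization epoch in which the bulk signal
                         first shows detectable oscillation
      bulk_period_window (start, stop) of the interval actually used
      final_order_parameter, mean_trace_agreement (relative), and the
      windowed SD series (sd_times, sd_series).
    """
    g, dt = traj.gfp, traj.dt
    sync_time = _sustained_threshold_time(g, dt, 0.9)
    partial_time = _sustained_threshold_time(g, dt, 0.5)

    post_start = sync_time if sync_time is not None else 0.6 * traj.times[-1]
    post = g[traj.times >= post_start]
    pers = []
    for i in range(g.shape[1]):
        try:
            pers.append(analysis.estimate_period(post[:, i], dt)[0])
        except NoOscillationError:
            pass
    coupled_period = float(np.median(pers)) if pers else float("nan")

    bulk_period, window = float("nan"), (0.0, 1080.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            wm = analysis.weighted_mean_trace(g[traj.times <= 1080.0])
            bulk_period = analysis.estimate_period(wm, dt)[0]
        except NoOscillationError:
            # incoherent bulk is flat; use the partial-coherence epoch
            start = partial_time if partial_time is not None else 0.0
            stop = sync_time if sync_time is not None else traj.times[-1]
            if stop - start < 2000.0:
                stop = min(start + 4000.0, traj.times[-1])
            window = (float(start), float(stop))
            mask = (traj.times >= start) & (traj.times <= stop)
            try:
                wm = analysis.weighted_mean_trace(g[mask])
                bulk_period = analysis.estimate_period(wm, dt)[0]
            except NoOscillationError:
                pass

    r = analysis.order_parameter_series(g, dt)
    tail = slice(-int(1440.0 / dt), None)  # final day
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final_r = float(np.nanmean(r[tail]))
    am = g.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wm_full = analysis.weighted_mean_trace(g)
    agree = float(np.nanmax(np.abs(wm_full[tail] - am[tail])
                            / np.maximum(am[tail], 1e-9)))
    sd_times, sd_series = analysis.windowed_sd(g, dt)
    return {"sync_time": sync_time, "partial_sync_time": partial_time,
            "coupled_period": coupled_period, "bulk_period": bulk_period,
            "bulk_period_window": window, "final_order_parameter": final_r,
            "mean_trace_agreement": agree,
            "sd_times": sd_times, "sd_series": sd_series,
            "n_oscillating": len(pers)}
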