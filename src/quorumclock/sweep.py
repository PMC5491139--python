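"""Parameter sensitivity sweeps.

Sweeps one numeric model parameter over a grid, re-running a reduced-scale
ensemble simulation plus synchronization analysis at every grid point, and
records the response of the oscillation period and synchronization time.
Sensitivity is read off as the finite-difference variation of these metrics
across the grid relative to their replicate scatter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np

from . import analysis
from .ensemble import init_population, integrate
from .errors import InvalidArgumentError, NoOscillationError
from .model import ModelParameters, calibrate_timescale

#: Default sweep grid: 7 logarithmic points spanning x1/4 .. x4 of base.
DEFAULT_GRID_SPAN = 4.0
DEFAULT_GRID_POINTS = 7
DEFAULT_REPLICATES = 3


def default_grid(base_value: float, span: float = DEFAULT_GRID_SPAN,
                 n_points: int = DEFAULT_GRID_POINTS) -> np.ndarray:
    """Logarithmic grid centred on ``base_value`` spanning x1/span .. xspan."""
    if base_value <= 0:
        raise InvalidArgumentError("default grid needs a positive base value")
    return base_value * np.logspace(-np.log10(span), np.log10(span), n_points)


@dataclass
class SweepResult:
    """Metrics of a one-parameter sweep."""

    parameter: str
    values: np.ndarray
    metrics: list                      # one dict per grid value
    seeds: list                        # seeds used per grid point
    base: ModelParameters | None = None

    def metric_array(self, name: str) -> np.ndarray:
        """Stack one metric's replicate means across the grid (NaN-safe)."""
        return np.array([m.get(name, np.nan) for m in self.metrics], dtype=float)

    def is_control_parameter(self, metric: str = "isolated_period") -> bool:
        """True if the metric varies across the grid by more than its
        replicate SD (the parameter can be used to tune the system)."""
        vals = self.metric_array(metric)
        sds = self.metric_array(metric + "_sd")
        ok = np.isfinite(vals)
        if ok.sum() < 2:
            return False
        spread = np.nanmax(vals) - np.nanmin(vals)
        noise = np.nanmax(np.where(np.isfinite(sds), sds, 0.0))
        return bool(spread > max(noise, 1e-12))


def _point_metrics(p: ModelParameters, n_cells: int, duration: float,
                   dt_out: float, seeds: list[int], transient: float) -> dict:
    iso_periods, cpl_periods, bulk_periods, sync_times = [], [], [], []
    oscillating = True
    for sd in seeds:
        # isolated single cell (coupling off) for the isolated-period metric
        y0, scales = init_population(1, p, seed=sd)
        try:
            t_iso = integrate((y0, scales), p, duration, dt_out, seed=sd,
                              S_ext_override=0.0)
            per, _ = analysis.estimate_period(
                t_iso.gfp[t_iso.times >= transient, 0], dt_out)
            iso_periods.append(per)
        except NoOscillationError:
            oscillating = False
        # coupled reduced ensemble
        y0, scales = init_population(n_cells, p, seed=sd + 1)
        traj = integrate((y0, scales), p, duration, dt_out, seed=sd + 1)
        post = traj.gfp[traj.times >= transient]
        pers = []
        for i in range(n_cells):
            try:
                per, _ = analysis.estimate_period(post[:, i], dt_out)
                pers.append(per)
            except NoOscillationError:
                pass
        if pers:
            cpl_periods.append(float(np.median(pers)))
        else:
            oscillating = False
        try:
            wm = analysis.weighted_mean_trace(traj.gfp)
            per, _ = analysis.estimate_period(wm[traj.times >= transient], dt_out)
            bulk_periods.append(per)
        except NoOscillationError:
            pass
        try:
            st = analysis.detect_sync_time(traj.gfp, dt_out)
        except InvalidArgumentError:
            st = None
        sync_times.append(np.nan if st is None else st)

    def mean_sd(xs):
        xs = np.asarray(xs, dtype=float)
        xs = xs[np.isfinite(xs)]
        if xs.size == 0:
            return float("nan"), float("nan")
        return float(xs.mean()), float(xs.std())

    out = {"oscillating": oscillating}
    for name, xs in (("isolated_period", iso_periods),
                     ("coupled_period", cpl_periods),
                     ("bulk_period", bulk_periods),
                     ("sync_time", sync_times)):
        m, s = mean_sd(xs)
        out[name] = m
        out[name + "_sd"] = s
    return out


def sweep(parameter: str, grid, base: ModelParameters,
          n_cells: int = 20, replicates: int = DEFAULT_REPLICATES,
          seed: int = 0, duration: float = 4000.0, dt_out: float = 10.0,
          transient: float = 500.0) -> SweepResult:
    """Sweep one numeric ``ModelParameters`` field over ``grid``.

    For each value, integrates an isolated cell and a reduced coupled
    ensemble over ``replicates`` seeds and records period and
    synchronization-time metrics (means and SDs).  Grid points where the
    oscillation is lost are flagged in the metrics, not fatal.
    """
    names = {f.name for f in dc_fields(ModelParameters)}
    if parameter not in names:
        raise InvalidArgumentError(f"unknown parameter name: {parameter!r}")
    base_val = getattr(base, parameter)
    if isinstance(base_val, bool):
        grid_arr = np.asarray([bool(v) for v in grid])
    else:
        if not isinstance(base_val, (int, float)):
            raise InvalidArgumentError(f"parameter {parameter!r} is not numeric")
        grid_arr = np.asarray(list(grid), dtype=float)
    if grid_arr.size == 0:
        raise InvalidArgumentError("grid must be nonempty")

    rng = np.random.default_rng(seed)
    metrics, seeds_used = [], []
    for val in grid_arr:
        p = base.copy(**{parameter: bool(val) if isinstance(base_val, bool) else float(val)})
        pt_seeds = [int(s) for s in rng.integers(2**30, size=replicates)]
        metrics.append(_point_metrics(p, n_cells, duration, dt_out, pt_seeds,
                                      transient))
        seeds_used.append(pt_seeds)
    return SweepResult(parameter=parameter, values=grid_arr, metrics=metrics,
                       seeds=seeds_used, base=base)
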