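"""Population-level integration of the coupled cell ensemble.

Advances all cells simultaneously under the exact synchronous mean field
(the extracellular AI is recomputed from the current population inside every
right-hand-side evaluation).  Deterministic runs use an adaptive scheme;
runs with stochastic forcing use fixed-step Euler-Maruyama with additive
noise on the mRNA equations.  External times are minutes; integration is
carried out in the model's dimensionless time and mapped through
``params.time_scale``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .errors import IntegrationError, InvalidArgumentError
from .model import (GFP_INDEX, N_SPECIES, I_M_TETR, I_M_LACI, I_S,
                    ModelParameters, population_rhs)

#: mRNA columns receiving additive stochastic forcing.
_NOISE_COLUMNS = slice(I_M_TETR, I_M_LACI + 1)


@dataclass
class EnsembleTrajectory:
    """Time grid x cells x species array with its provenance.

    ``times`` are minutes, strictly increasing; ``values[t, i, s]`` is the
    concentration of species ``s`` (ordered as :data:`quorumclock.model.SPECIES`)
    in cell ``i``.
    """

    times: np.ndarray
    values: np.ndarray
    params: ModelParameters
    seed: int | None
    cell_scales: np.ndarray
    n_clipped: int = 0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise InvalidArgumentError("times must be strictly increasing")
        if self.values.shape[0] != len(self.times):
            raise InvalidArgumentError("values/time length mismatch")
        if self.values.shape[1] != len(self.cell_scales):
            raise InvalidArgumentError("cell count does not match cell_scales")

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def gfp(self) -> np.ndarray:
        """Reporter array of shape (time, cell)."""
        return self.values[:, :, GFP_INDEX]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def init_population(n_cells: int, p: ModelParameters, seed: int,
                    init_high: float = 50.0, s_high: float = 1.0):
    """Random desynchronized initial conditions and per-cell scale factors.

    Species are drawn independently per cell, uniform on [0, ``init_high``]
    (the autoinducer on [0, ``s_high``]); relaxation onto the limit cycle
    spreads the resulting phases over the full cycle.  ``cell_scales`` are
    lognormal with mean 1 and coefficient of variation
    ``p.heterogeneity_cv``, and multiply each cell's protein turnover rate.

    Returns ``(states, cell_scales)`` with ``states`` of shape
    (n_cells, N_SPECIES).
    """
    if n_cells < 1:
        raise InvalidArgumentError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    y0 = rng.uniform(0.0, init_high, size=(n_cells, N_SPECIES))
    y0[:, I_S] = rng.uniform(0.0, s_high, size=n_cells)
    cv = p.heterogeneity_cv
    if cv > 0:
        sigma2 = np.log1p(cv * cv)
        scales = rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2),
                               size=n_cells)
    else:
        scales = np.ones(n_cells)
    return y0, scales


def integrate(initial, p: ModelParameters, t_end: float, dt_out: float,
              seed: int | None = None, cell_scales=None,
              dt_internal: float = 0.01, S_ext_override: float | None = None,
              method: str = "auto") -> EnsembleTrajectory:
    """Integrate the coupled population from ``initial`` for ``t_end`` minutes.

    ``initial`` is either the (states, cell_scales) pair returned by
    :func:`init_population` or a bare state array (then ``cell_scales``
    defaults to ones).  With ``p.noise_sigma == 0`` the result is
    deterministic and independent of the output grid; otherwise fixed-step
    Euler-Maruyama (step ``dt_internal`` in dimensionless units) is used and
    is reproducible from ``seed``.  Output is sampled every ``dt_out``
    minutes, starting at 0.  ``S_ext_override`` forces the external AI field
    (0 gives the isolated AI -> 0 limit for every cell).
    """
    if isinstance(initial, tuple):
        y0, cell_scales = initial
    else:
        y0 = initial
    y0 = np.atleast_2d(np.asarray(y0, dtype=float))
    n_cells = y0.shape[0]
    if cell_scales is None:
        cell_scales = np.ones(n_cells)
    cell_scales = np.asarray(cell_scales, dtype=float)
    if t_end <= 0 or dt_out <= 0:
        raise InvalidArgumentError("t_end and dt_out must be > 0")
    if t_end < dt_out:
        raise InvalidArgumentError("t_end shorter than one output interval")
    if not np.all(np.isfinite(y0)) or np.any(y0 < 0):
        raise InvalidArgumentError("initial states must be finite and >= 0")

    ts = p.time_scale
    t_out_min = np.arange(0.0, t_end + dt_out / 2, dt_out)
    t_out = t_out_min / ts  # dimensionless output grid

    if p.noise_sigma > 0:
        values, n_clipped = _euler_maruyama(y0, p, cell_scales, t_out,
                                            dt_internal, seed, S_ext_override)
    else:
        values = _deterministic(y0, p, cell_scales, t_out, S_ext_override, method)
        n_clipped = 0
    return EnsembleTrajectory(times=t_out_min, values=values, params=p,
                              seed=seed, cell_scales=cell_scales,
                              n_clipped=n_clipped)


def _deterministic(y0, p, cell_scales, t_out, S_ext_override, method):
    n_cells = y0.shape[0]

    def rhs(t, flat):
        y = flat.reshape(n_cells, N_SPECIES)
        return population_rhs(np.maximum(y, 0.0), p, cell_scales,
                              S_ext=S_ext_override).ravel()

    if method == "auto":
        method = "LSODA" if n_cells * N_SPECIES <= 600 else "RK45"
    sol = solve_ivp(rhs, (t_out[0], t_out[-1]), y0.ravel(), t_eval=t_out,
                    method=method, rtol=1e-6, atol=1e-9)
    if not sol.success:
        raise IntegrationError(f"deterministic integration failed: {sol.message}")
    values = sol.y.T.reshape(len(t_out), n_cells, N_SPECIES)
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        raise IntegrationError("non-finite state encountered",
                               time=float(t_out[bad[0]] * p.time_scale),
                               cell=int(bad[1]))
    return np.maximum(values, 0.0)


def _euler_maruyama(y0, p, cell_scales, t_out, dt, seed, S_ext_override):
    """Fixed-step Euler-Maruyama with additive mRNA forcing.

    The state is clipped at zero after every step (additive noise can push a
    near-zero mRNA concentration transiently negative); clip events are
    counted, not fatal.  Output samples are linearly interpolated between the
    two internal steps bracketing each output time.
    """
    rng = np.random.default_rng(seed)
    n_cells = y0.shape[0]
    y = y0.copy()
    sig = p.noise_sigma * np.sqrt(dt)
    out = np.empty((len(t_out), n_cells, N_SPECIES))
    n_clipped = 0
    t = t_out[0]
    k = 0
    if t_out[0] <= t:
        out[0] = y
        k = 1
    max_t = t_out[-1]
    while k < len(t_out):
        dy = population_rhs(y, p, cell_scales, S_ext=S_ext_override)
        y_new = y + dy * dt
        noise = rng.standard_normal((n_cells, 3))
        y_new[:, _NOISE_COLUMNS] += sig * noise
        neg = y_new < 0
        if neg.any():
            n_clipped += int(neg.sum())
            np.clip(y_new, 0.0, None, out=y_new)
        if not np.all(np.isfinite(y_new)):
            bad = np.argwhere(~np.isfinite(y_new))[0]
            raise IntegrationError("non-finite state during stochastic step",
                                   time=float(t * p.time_scale), cell=int(bad[0]))
        t_new = t + dt
        while k < len(t_out) and t_out[k] <= t_new + 1e-12:
            w = (t_out[k] - t) / dt
            out[k] = (1 - w) * y + w * y_new
            k += 1
        y, t = y_new, t_new
        if t > max_t + dt:
            break
    return out, n_clipped


def _simulate_isolated_cell(p: ModelParameters, t_end: float, dt_out: float,
                            y0: np.ndarray | None = None):
    """Deterministic single cell with the coupling removed (dimensionless time).

    Used by time-scale calibration.  Returns (times, values[t, species]).
    """
    if y0 is None:
        y0 = np.zeros(N_SPECIES)
        y0[I_M_TETR] = 5.0  # asymmetric start so the limit cycle is reached

    def rhs(t, flat):
        return population_rhs(np.maximum(flat[None, :], 0.0), p, 1.0,
                              S_ext=0.0).ravel()

    t_eval = np.arange(0.0, t_end + dt_out / 2, dt_out)
    sol = solve_ivp(rhs, (0.0, t_end), y0, t_eval=t_eval, method="LSODA",
                    rtol=1e-8, atol=1e-10)
    if not sol.success:
        raise IntegrationError(f"isolated-cell integration failed: {sol.message}")
    return t_eval, np.maximum(sol.y.T, 0.0)
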