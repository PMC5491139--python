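"""Core ODE model: repressilator + quorum-sensing communication module.

Each cell carries a three-gene repressilator (tetR -| cI -| lacI -| tetR)
and a communication module in which the P_Llac01 promoter (repressed by the
total LacI pool) drives LuxR and LuxI, LuxI synthesizes the diffusible
autoinducer AI, and the LuxR·AI complex activates the luxbox promoter
driving GFP, the lactonase AiiB and a second LacI species.  AiiB hydrolyzes
AI, closing a negative feedback on the coupling signal.  Cells communicate
through a uniform (mean-field) extracellular AI concentration.

The model is dimensionless: concentrations are in units of their promoters'
half-repression constants and time is in units of the mRNA lifetime.  A
single calibration constant ``time_scale`` (minutes per dimensionless time
unit) maps simulated time to wall-clock minutes; it is chosen so that an
isolated cell (mean-field coupling removed, Q = 0) oscillates with a period
of 270 min.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict, replace
from typing import Sequence

import numpy as np

from .errors import CalibrationError, InvalidArgumentError

#: Canonical species ordering used throughout the package.
SPECIES: tuple[str, ...] = (
    "m_tetR", "m_cI", "m_lacI",
    "p_TetR", "p_CI", "p_LacI",
    "p_LuxI", "p_LuxR", "p_AiiB", "p_LacI2", "p_GFP",
    "S",
)
N_SPECIES = len(SPECIES)

(I_M_TETR, I_M_CI, I_M_LACI,
 I_P_TETR, I_P_CI, I_P_LACI,
 I_P_LUXI, I_P_LUXR, I_P_AIIB, I_P_LACI2, I_P_GFP,
 I_S) = range(N_SPECIES)

#: Column index of the observable reporter.
GFP_INDEX = I_P_GFP


@dataclass
class CellState:
    """Concentrations of all per-cell species (dimensionless units).

    ``S`` is the intracellular autoinducer; ``p_GFP`` is the observable.
    All fields must be nonnegative and finite.
    """

    m_tetR: float = 0.0
    m_cI: float = 0.0
    m_lacI: float = 0.0
    p_TetR: float = 0.0
    p_CI: float = 0.0
    p_LacI: float = 0.0
    p_LuxI: float = 0.0
    p_LuxR: float = 0.0
    p_AiiB: float = 0.0
    p_LacI2: float = 0.0
    p_GFP: float = 0.0
    S: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "CellState":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (N_SPECIES,):
            raise InvalidArgumentError(
                f"state array must have shape ({N_SPECIES},), got {arr.shape}")
        return cls(**{name: float(v) for name, v in zip(SPECIES, arr)})

    def validate(self) -> None:
        arr = self.to_array()
        if not np.all(np.isfinite(arr)):
            raise InvalidArgumentError("cell state contains non-finite values")
        if np.any(arr < 0):
            raise InvalidArgumentError("cell state contains negative concentrations")


@dataclass
class ModelParameters:
    """All rate constants, Hill parameters, coupling constants and toggles.

    Defaults are the package's calibrated reference set: the repressilator
    backbone follows the published dimensionless coupled-repressilator model
    (alpha, n, beta, eta, Q(delta, rho), k_s0, k_s1), extended with the
    lactonase feedback (k_h) and the luxbox/P_Llac01 promoter parameters of
    the communication module.  ``time_scale`` converts dimensionless time to
    minutes and is set by :func:`calibrate_timescale`.
    """

    # repressilator backbone
    alpha: float = 216.0        # maximal repressilator transcription rate
    n: float = 2.0              # Hill coefficient of repression
    beta: float = 2.0           # protein/mRNA lifetime ratio
    # luxbox promoter (LuxR·AI-activated)
    kappa_lux: float = 90.0     # maximal luxbox transcription rate
    n_lux: float = 2.0
    K_lux: float = 1.0          # half-activation constant for the complex C
    k_RS: float = 1.0           # effective LuxR·AI complex-formation constant
    # P_Llac01 promoter (drives luxR and luxI, repressed by total LacI)
    alpha_lac01: float = 216.0
    K_lac01: float = 1.0
    n_lac01: float = 2.0
    # autoinducer kinetics
    k_s1: float = 0.08          # AI synthesis per LuxI
    k_s0: float = 1.0           # basal AI decay
    k_h: float = 3.0            # AiiB-mediated hydrolysis rate constant
    eta: float = 8.0            # AI membrane diffusion rate
    # mean-field coupling strength Q = delta*rho/(1+delta*rho)
    delta: float = 24.0
    rho: float = 1.0
    # protein degradation
    gamma_mod: float = 1.0      # base decay rate of communication-module proteins
    deg_tagged: float = 2.0     # decay multiplier for ssrA-tagged proteins
    proteolysis_on: bool = False
    proteolysis_rate: float = 0.1   # extra first-order loss when proteolysis_on
    aiib_on: bool = True
    hydrolysis_km: float | None = None  # None = mass action; else Michaelis-Menten Km
    # calibration and stochasticity
    time_scale: float = 33.96   # minutes per unit, from calibrate_timescale
    noise_sigma: float = 0.03   # additive forcing intensity on mRNA equations
    heterogeneity_cv: float = 0.01  # CV of the per-cell scatter applied to beta

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        nonneg = ("alpha", "beta", "kappa_lux", "K_lux", "k_RS", "alpha_lac01",
                  "K_lac01", "k_s1", "k_s0", "k_h", "eta", "delta", "rho",
                  "gamma_mod", "deg_tagged", "proteolysis_rate", "time_scale",
                  "noise_sigma")
        for name in nonneg:
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"parameter {name} must be >= 0")
        for name in ("n", "n_lux", "n_lac01"):
            if getattr(self, name) < 1:
                raise InvalidArgumentError(f"Hill coefficient {name} must be >= 1")
        if not 0 <= self.heterogeneity_cv < 1:
            raise InvalidArgumentError("heterogeneity_cv must lie in [0, 1)")
        if self.time_scale <= 0:
            raise InvalidArgumentError("time_scale must be > 0")
        if self.hydrolysis_km is not None and self.hydrolysis_km <= 0:
            raise InvalidArgumentError("hydrolysis_km must be positive or None")

    @property
    def Q(self) -> float:
        """Mean-field dilution factor in [0, 1)."""
        return mean_field_Q(self.delta, self.rho)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidArgumentError(
                f"unknown parameter key(s): {', '.join(sorted(unknown))}")
        return cls(**d)

    def copy(self, **updates) -> "ModelParameters":
        return replace(self, **updates)


def hill_repression(x: float, alpha: float, K: float, n: float):
    """Repressive Hill function ``alpha / (1 + (x/K)^n)``.

    Strictly decreasing in the repressor concentration ``x``; equals ``alpha``
    at ``x = 0`` and ``alpha/2`` at ``x = K``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise InvalidArgumentError("repressor concentration must be >= 0")
    if alpha < 0:
        raise InvalidArgumentError("maximal rate alpha must be >= 0")
    if K <= 0:
        raise InvalidArgumentError("half-repression constant K must be > 0")
    if n < 1:
        raise InvalidArgumentError("Hill coefficient n must be >= 1")
    out = alpha / (1.0 + (x / K) ** n)
    return out if out.ndim else float(out)


def lux_activation(S, R, p: ModelParameters):
    """Luxbox promoter activity driven by the LuxR·AI complex.

    The complex is treated at quasi-equilibrium, ``C = k_RS * S * R``, and
    activates transcription through a Hill function saturating at
    ``kappa_lux``.  Zero whenever either the autoinducer or the receptor is
    absent.
    """
    S = np.asarray(S, dtype=float)
    R = np.asarray(R, dtype=float)
    if np.any(S < 0) or np.any(R < 0):
        raise InvalidArgumentError("S and R must be >= 0")
    C = p.k_RS * S * R
    Cn = C ** p.n_lux
    out = p.kappa_lux * Cn / (p.K_lux ** p.n_lux + Cn)
    return out if out.ndim else float(out)


def mean_field_Q(delta: float, rho: float) -> float:
    """Diffusion-density dilution factor ``delta*rho / (1 + delta*rho)``.

    Bounded in [0, 1); 0 at zero cell density (fully decoupled population)
    and approaching 1 in the dense-culture limit.
    """
    if delta < 0 or rho < 0:
        raise InvalidArgumentError("delta and rho must be >= 0")
    dr = delta * rho
    return dr / (1.0 + dr)


def external_AI(states, p: ModelParameters) -> float:
    """Uniform extracellular autoinducer under the mean-field approximation.

    ``S_ext = Q * <S_i>`` where the average runs over all cells.  With Q = 0
    the population is fully decoupled.

    ``states`` may be a sequence of :class:`CellState` or an array whose last
    axis is the species axis.
    """
    if isinstance(states, np.ndarray):
        if states.size == 0:
            raise InvalidArgumentError("population must be nonempty")
        S = states[..., I_S]
    else:
        states = list(states)
        if not states:
            raise InvalidArgumentError("population must be nonempty")
        S = np.array([st.S for st in states])
    return float(p.Q * np.mean(S))


def population_rhs(y: np.ndarray, p: ModelParameters,
                   cell_scales: np.ndarray | float = 1.0,
                   S_ext: float | None = None) -> np.ndarray:
    """Vectorized time-derivative of the full population state.

    ``y`` has shape (n_cells, N_SPECIES).  If ``S_ext`` is None it is
    recomputed from ``y`` (exact synchronous mean field); passing a value
    overrides it, which is how the isolated AI -> 0 limit is simulated.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    scales = np.broadcast_to(np.asarray(cell_scales, dtype=float), (y.shape[0],))
    if S_ext is None:
        S_ext = p.Q * float(np.mean(y[:, I_S]))

    m = y[:, (I_M_TETR, I_M_CI, I_M_LACI)]
    prot = y[:, (I_P_TETR, I_P_CI, I_P_LACI)]
    luxI, luxR = y[:, I_P_LUXI], y[:, I_P_LUXR]
    aiiB, lacI2, gfp = y[:, I_P_AIIB], y[:, I_P_LACI2], y[:, I_P_GFP]
    S = y[:, I_S]

    lacT = prot[:, 2] + lacI2  # total LacI pool represses tetR and P_Llac01

    dy = np.empty_like(y)
    # repressilator mRNAs: unit decay + Hill repression by the upstream protein
    dy[:, I_M_TETR] = -m[:, 0] + p.alpha / (1.0 + lacT ** p.n)
    dy[:, I_M_CI] = -m[:, 1] + p.alpha / (1.0 + prot[:, 0] ** p.n)
    dy[:, I_M_LACI] = -m[:, 2] + p.alpha / (1.0 + prot[:, 1] ** p.n)
    # repressilator proteins
    b = p.beta * scales
    extra = p.proteolysis_rate if p.proteolysis_on else 0.0
    dy[:, I_P_TETR] = b * (m[:, 0] - prot[:, 0]) - extra * prot[:, 0]
    dy[:, I_P_CI] = b * (m[:, 1] - prot[:, 1]) - extra * prot[:, 1]
    dy[:, I_P_LACI] = b * (m[:, 2] - prot[:, 2]) - extra * prot[:, 2]
    # communication module, P_Llac01 branch (luxR, luxI); module proteins decay
    # at gamma_mod (untagged LuxI: slow, dilution-dominated) or
    # deg_tagged*gamma_mod (ssrA-tagged LuxR, GFP, AiiB, LacI2: fast)
    g_mod = p.gamma_mod * scales
    g_tag = p.deg_tagged * g_mod
    p01 = p.alpha_lac01 / (1.0 + (lacT / p.K_lac01) ** p.n_lac01)
    dy[:, I_P_LUXI] = p01 - g_mod * luxI                # LuxI is untagged
    dy[:, I_P_LUXR] = p01 - g_tag * luxR
    # luxbox branch (GFP, AiiB, LacI2), all ssrA-tagged
    C = p.k_RS * S * luxR
    Cn = C ** p.n_lux
    lux = p.kappa_lux * Cn / (p.K_lux ** p.n_lux + Cn)
    dy[:, I_P_GFP] = lux - g_tag * gfp
    dy[:, I_P_AIIB] = lux - g_tag * aiiB
    dy[:, I_P_LACI2] = lux - g_tag * lacI2
    # intracellular autoinducer
    if p.aiib_on:
        if p.hydrolysis_km is None:
            hyd = p.k_h * aiiB * S
        else:
            hyd = p.k_h * aiiB * S / (p.hydrolysis_km + S)
    else:
        hyd = 0.0
    dy[:, I_S] = p.k_s1 * luxI - p.k_s0 * S - hyd - p.eta * (S - S_ext)
    return dy


def cell_rhs(state: CellState, S_ext: float, p: ModelParameters,
             cell_scale: float = 1.0) -> CellState:
    """Time-derivative of a single cell exposed to extracellular AI ``S_ext``."""
    if S_ext < 0:
        raise InvalidArgumentError("S_ext must be >= 0")
    state.validate()
    y = state.to_array()[None, :]
    dy = population_rhs(y, p, cell_scale, S_ext=S_ext)
    return CellState.from_array(dy[0])


def calibrate_timescale(p: ModelParameters, target_period_min: float = 270.0,
                        t_end_dimless: float = 400.0,
                        transient_dimless: float = 100.0) -> float:
    """Minutes-per-unit time scale pinning the isolated-cell period.

    Simulates a single cell with the mean-field coupling removed (S_ext = 0,
    membrane leak retained), measures the dimensionless oscillation period of
    the GFP reporter, and returns ``target_period_min / period_dimless``.
    The default target of 270 min is the model's isolated-limit period.
    """
    from .ensemble import _simulate_isolated_cell
    from .analysis import estimate_period
    from .errors import NoOscillationError

    if target_period_min <= 0:
        raise InvalidArgumentError("target period must be > 0")
    dt = 0.05
    times, traj = _simulate_isolated_cell(p, t_end=t_end_dimless, dt_out=dt)
    trace = traj[:, GFP_INDEX]
    keep = times >= transient_dimless
    try:
        period, _ = estimate_period(trace[keep], dt)
    except NoOscillationError as exc:
        raise CalibrationError(
            "isolated cell does not oscillate at these parameters") from exc
    return target_period_min / period
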