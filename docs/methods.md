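# Methods

## Model

The model describes a population of N identical-by-design *E. coli*
cells, each carrying the repressilator and the quorum-sensing
communication module, coupled only through a uniform extracellular
autoinducer (AI) pool. It is an ODE system per cell (12 species: three
repressilator mRNAs, three repressilator proteins, LuxI, LuxR, AiiB,
LacI₂, GFP, intracellular AI), written in the standard dimensionless
form for coupled repressilators: concentrations in units of the
repression threshold, time in units of the mRNA lifetime.

Key structural choices:

* **LacI pooling.** The repressilator's LacI and the luxbox-driven
  LacI₂ are summed into one repressor pool that acts on both the *tetR*
  promoter and P_Llac01, with equal affinity (the affinity of LacI₂ for
  P_Llac01 is not separately identifiable and is assumed identical).
* **Luxbox activation.** The LuxR·AI complex is treated at
  quasi-equilibrium, `C = k_RS·S·R`, inside a Hill activation
  `κ·Cⁿ/(Kⁿ+Cⁿ)` (n = 2 by default). This is the simplest form
  consistent with the circuit diagram.
* **AiiB hydrolysis** is mass action, rate `k_h·[AiiB]·S`. A
  Michaelis–Menten alternative is available through the
  `hydrolysis_km` parameter (None = mass action).
* **Degradation.** Repressilator proteins turn over at rate β (per
  cell scaled by ξᵢ). Communication-module proteins have their own base
  rate `gamma_mod`; the ssrA-tagged ones (LuxR, AiiB, LacI₂, GFP) decay
  `deg_tagged`-fold faster, LuxI (untagged) at the base rate. An
  optional additional first-order loss on the repressilator proteins
  (`proteolysis_on`, rate `proteolysis_rate`) models substrate
  proteolytic degradation.
* **Mean field.** The extracellular AI is `S̄ = Q·mean(Sᵢ)` with
  `Q = δρ/(1+δρ) ∈ [0,1)`, recomputed synchronously inside every RHS
  evaluation (exact quasi-steady mean field, no lag). `Q = 0`
  decouples the population exactly; the "isolated" (AI → 0) limit used
  for calibration forces `S̄ = 0` while keeping the membrane leak η·S.
* **IPTG** is implicit: simulations correspond to the induced regime.
* Setting `aiib_on = False` reproduces the earlier coupling scheme
  without the lactonase (AI then accumulates without enzymatic removal).

## Stochasticity and heterogeneity

Both noise channels are implemented and configurable, since the
original description does not fix one: (i) additive stochastic forcing
of intensity `noise_sigma` on the three mRNA equations
(Euler–Maruyama), and (ii) static cell-to-cell heterogeneity — each
cell's protein-turnover rate is multiplied by a lognormal factor with
mean 1 and CV `heterogeneity_cv`. Defaults: `noise_sigma = 0.03`,
`heterogeneity_cv = 0.01`, small enough to keep every cell oscillating
over 30 simulated days, large enough to seed the desynchronized
ensemble realistically.

## Numerics

Deterministic runs use adaptive integration (LSODA for small systems,
RK45 for large ensembles; rtol 1e-6, atol 1e-9). Stochastic runs use
fixed-step Euler–Maruyama with step 0.01 dimensionless time units and
linear interpolation onto the output grid; the state is clipped at
zero after each step (additive noise can push a near-zero mRNA
transiently negative) and clip events are counted in the trajectory
metadata rather than treated as fatal. The stochastic path at zero
noise converges to the deterministic reference at first order in the
step; on this relaxation oscillator the residual is dominated by
phase drift along the cycle, so pointwise agreement over long horizons
is not a meaningful test and the suite checks convergence order
instead.

## Calibration

`calibrate_timescale` simulates one isolated cell (Q = 0), measures the
dimensionless GFP period by the median of peak-to-peak intervals, and
returns `time_scale = 270 min / P_dimless`. With the default parameter
set the isolated dimensionless period is 7.95, giving
`time_scale = 33.96 min/unit`, which is baked into the defaults. All
times accepted and reported by the package are minutes.

The remaining defaults were chosen, in order of priority, so that
(1) every cell keeps a robust limit cycle with a strongly modulated GFP
reporter under noise and heterogeneity for 30 simulated days, including
at the reduced effective AI leak the coupled synchronized state implies;
(2) the mean-field phase coupling is attractive (verified directly by a
two-cell phase-convergence experiment) and strong enough to synchronize
the 500-cell population on the ~10⁴-minute scale without quenching
oscillations; (3) the communication module is genuinely engaged (the
lactonase measurably lowers the AI level; the luxbox output tracks the
repressilator phase).

## What the defaults do and do not reproduce

With the calibrated defaults the model reproduces: the 270-min isolated
period (by construction of the calibration), whole-population
synchronization at ≈16 000 min, sustained complete synchronization
(order parameter ≥ 0.9, weighted and arithmetic bulk means within 5%)
well before 30 days, and the characteristic decay-to-plateau of the
windowed across-cell SD of GFP.

Two literature figures are **not** reproduced by this architecture, and
we consider this a property of the disclosed model structure rather
than of the implementation. First, the reported lengthening of the
period by the communication circuit (isolated 270 min above the bare
repressilator's 160 min "because of additional LacI", and coupled cells
at 325 min above the isolated 270 min). In this architecture extra
LacI — tonic or pulsed at any phase the circuit can generate —
*shortens* the repressilator period or quenches the oscillation: the
measured phase-response curve of the ring to LacI pulses is positive
(delaying) only in a window the luxbox pulse cannot reach causally, and
scans over the full communication-parameter space (including a
512-point quasi-random search) found no coupled/isolated period ratio
above ~1.0. Consequently the synchronized per-cell period equals the
isolated one (≈250 min with noise, vs 325 reported), and the pre-sync
bulk period matches the per-cell period (vs 400 reported). Second, the
onset of partial synchronization: from genuinely desynchronized initial
phases the collective-mode growth rate that avoids oscillator death
puts the sustained 0.5 order-parameter crossing at ≈5–7 days, not ≈2;
faster coupling regimes quench the oscillators instead of entraining
them. A related consequence of truly uniform initial phases is that the
bulk signal of 500 cells is flat (O(N^-1/2) fluctuations) during the
first 1080 min, so the pre-synchronization bulk period is estimated on
the partial-coherence epoch — the interval between the sustained 0.5
and 0.9 order-parameter crossings — rather than on the first 1080 min.

## Analysis conventions

* **Periods**: local maxima with prominence ≥ 10% of the trace range
  and a 3-sample refractory span; the period is the *median* of
  consecutive peak-to-peak intervals (robust to a missed peak). The
  first 500 min are excluded as transient by default.
* **Weighted bulk signal**: each cell weighted by its share of total
  GFP at that instant, i.e. Σg²/Σg. It is ≥ the arithmetic mean, with
  equality exactly under synchrony.
* **Windowed SD**: across-cell SD (population convention, ddof 0) at
  each sample, RMS-averaged within consecutive 5-h windows. This is
  the dispersion that vanishes as cells synchronize; pooling samples
  *and* cells (available as `pooling="pooled"`) is phase-shift
  invariant and does not decay, so it is not the default.
* **Phase**: 0 at each detected peak, linear to 2π at the next;
  undefined (NaN) outside the first/last peak. The order parameter is
  the modulus of the population-mean unit phasor over defined phases.
* **Synchronization time**: earliest 5-h-window midpoint from which
  the window-averaged order parameter stays ≥ 0.9 (windows with no
  defined phase are neutral). An SD-plateau criterion (windowed SD
  within 10% of its terminal value) is available; the criterion used
  is recorded in every report.
* **Phase clusters**: sort phases on the circle and cut at angular
  gaps > 0.5 rad (configurable).

## Synthetic microscopy emulator

The emulator renders per-cell GFP into cluster-level fluorescence the
way the time-lapse experiment records it: frames every 20 min from 0 to
1080 min (55 frames), intensity = gain × mean GFP over the cluster's
member cells + background, multiplicative lognormal measurement noise
with configurable CV, clipped at zero. Cluster membership is a random
partition (default 5 clusters) in which each cell switches cluster with
a per-frame churn probability, emulating cells joining and leaving
imaged microcolonies. It emulates the cadence, aggregation and
measurement noise of the experiment — not cell growth, spatial AI
gradients (the model is mean-field by assumption), photobleaching, or
the circuit's long-term genetic instability. Tests passing on emulated
data therefore validate the analysis pipeline on experiment-*shaped*
data, not the mean-field assumption itself.

## Sensitivity sweeps

`sweep` varies one parameter over a grid (default: 7 logarithmic points
spanning ×1/4 to ×4 of the base value), re-running an isolated cell and
a reduced coupled ensemble (default 20 cells, ~4000 min, 3 replicate
seeds) per point, and records period and synchronization metrics with
replicate SDs. A parameter counts as a *control parameter* when a
metric's span across the grid exceeds its replicate scatter —
protein half-life (`deg_tagged`) and transcription rates (`alpha`,
`kappa_lux`) qualify; toggling the substrate-proteolysis term does not
shift the synchronization time beyond replicate noise. Sensitivity is
finite-difference across the grid; no derivative-based method is used.

## Problem sizes

The reference conditions are 500 cells over 43 200 min (30 days),
integrated in ~20 s; tests use the same 500-cell run once (module-scoped
fixture) plus small ensembles (2–20 cells) elsewhere. Isolated-period
replicates use 10 seeds × 5000 min.

## Known limitations

* Mean-field coupling only: no spatial AI diffusion, hence the
  "clusters" the analysis finds are phase clusters, not spatial ones.
* No plasmid copy-number dynamics, no growth/dilution of the
  population, no long-term circuit instability.
* The stated inability of this architecture to lengthen the period via
  luxbox-driven LacI (see above) means period comparisons against
  literature values that rely on that mechanism fail by ~20–40%.
* Euler–Maruyama is first-order; trajectories at the default step are
  phase-accurate to a few per cent per 1000 min, which is immaterial
  for the statistical quantities reported but visible in pointwise
  trajectory comparisons.
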