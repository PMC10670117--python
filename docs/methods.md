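# Methods

## Model overview

The network is a theta-paced CA3-like microcircuit: 800 five-compartment
pyramidal cells, 200 single-compartment fast-spiking basket cells, 200
single-compartment OLM cells, and a medial-septum (MS) pacemaker that
delivers slow inhibitory conductance events (τ₁ = 20 ms, τ₂ = 40 ms,
reversal −80 mV) to every interneuron once per 150 ms. Pyramidal cells
excite each other (basal dendrite), basket cells (soma) and OLM cells
(soma) through AMPA and NMDA receptors; basket cells inhibit pyramidal
somata and each other (GABA_A, τ₂ = 9.1 ms); OLM cells inhibit the
mid-apical pyramidal compartment through a slower GABA_A synapse
(τ₂ = 20 ms). Poisson background drives (1000 Hz AMPA/GABA_A at all
somata, 1000 Hz AMPA/GABA_A and 10 Hz NMDA at the distal apical
compartment) model the in vivo high-conductance state and entorhinal
input.

The baseline regime this produces: pyramidal cells fire sparsely
(~2–3 Hz), gated into theta windows by the OLM/MS loop; basket volleys
chop the windows into γ cycles of ≈30 ms; the LFP (pyramidal-mean
distal-minus-basal dendritic voltage) shows theta with nested γ whose
γ-band spectral peak sits at ≈33 Hz.

## Membrane dynamics and integration

Compartments follow C·dV/dt = −Σ g_i·(V − E_i) + I_axial + I_syn.
Channel kinetics are canonical hippocampal formulations — Traub-style
transient Na⁺/delayed-rectifier K⁺ for excitatory cells and OLM cells,
Wang–Buzsáki kinetics for basket cells (with the activation rates of m
sped ×5 in place of the original's instantaneous-activation assumption),
sigmoidal A-type K⁺ (pyramidal), Ih with a bell-shaped time constant,
and, for OLM cells, an L-type Ca²⁺ current (s² gating) feeding a
first-order Ca²⁺ pool that activates a K(Ca) current
(Ca/(Ca + K_D) gating). Every rate constant, half-activation voltage and
density is a config field, because published descriptions of this model
class specify channel *types*, not rate equations; the defaults were chosen
so that each cell type reproduces its qualitative phenotype (sparse
regular pyramidal spiking with 50–200 MΩ input resistance; basket fast
spiking without depolarization block up to ≈1 nA equivalent drive; OLM
burst followed by K(Ca)-mediated after-burst quiescence).

Integration is fixed-step (dt = 0.025 ms): exponential Euler for gating
variables and Ca²⁺, and a semi-implicit exponential voltage update in
which all conductances are frozen over the step and axial neighbors are
taken at their previous-step voltage. Spike detection is an upward
0 mV crossing at the soma with a 3 ms refractory constraint.

The network engine runs one fused, numba-compiled loop. Gating
steady-states and decay factors are evaluated through voltage-indexed
lookup tables (0.02 mV grid, linear interpolation) built from the same
rate functions as the pure-NumPy single-cell reference integrator; the
test suite checks the two paths against each other (sub-threshold
agreement < 0.1 mV; spike-time agreement < 0.5 ms). Synapses with equal
kinetics converging on a compartment are aggregated into one linear
two-state filter; an event of weight w raises the conductance to a peak
of exactly w nS (peak-normalized double exponential), so the tabulated
conductances and the scaling factors act directly on peak values.

## Randomness and pairing

One master seed spawns named substreams for wiring, initial conditions
and background events. Control and scaled runs of a pair are built from
the same master seed, so wiring and every background event stream are
bit-identical and only AMPA peak conductances differ. Background events
are drawn per (drive, cell, step) by thinning, which consumes one
uniform variate per step regardless of outcome — this is what makes the
stream alignment exact. Initial voltages get hyperpolarizing-only jitter
(uniform in [−2, 0] mV) to break symmetry without firing near-rheobase
cells at t = 0.

## Free parameters and calibration

The tabulated synaptic conductances, time constants, delays, background
rates, population sizes and the MS period are inputs taken as printed.
Parameters without published values — channel densities, compartment
geometry, convergence numbers — are config inputs whose defaults were
calibrated once so the baseline network reaches the documented regime:

- convergences: P→P 25, P→B 100, P→O 10, B→P 75, B→B 199 (all-to-all),
  O→P 20; the MS input counts 10 synapses per interneuron (per-synapse
  conductance kept at the tabulated 1.6 nS). The strong, shared B→B
  coupling and the strong septal gate are what synchronize basket
  volleys into γ; with a weak septal gate the basket population drifts
  into fast (>70 Hz) asynchronous cluster states and the LFP shows no γ.
- NMDA receptors carry the standard sigmoidal Mg²⁺ block
  1/(1 + 0.28·e^(−0.062·V)). With the block disabled the tabulated 6.5 nS
  distal NMDA background alone drives pyramidal cells above 200 Hz and
  no oscillatory regime exists; the block is therefore on by default and
  exposed as a config toggle.

## Analysis definitions

- LFP: mean over pyramidal cells of (V_Adend3 − V_Bdend), sampled at
  1 kHz, analysis window excluding the first 3000 ms of each 7000 ms run.
- Spectra: Welch, 1 s Hann segments, 50 % overlap (fixed in config).
- γ power: sum of Welch power over bins with 30 ≤ f ≤ 100 Hz.
- Δγ: γ(condition)/γ(control) − 1, seed-matched pairs.
- Raster γ: pooled spike times binned at 1 ms, convolved with a
  unit-area 5 ms boxcar, then treated exactly like the LFP.
- Dominant γ frequency: argmax of Welch power within 30–100 Hz. The
  unrestricted spectrum also contains the imposed 6.67 Hz septal pacing
  line and its first harmonics; the γ-cycle length is defined by the
  γ-band peak, which is how the reported ≈33 Hz value is measured.
- Seizure verdict: a run is epileptic if its mean pyramidal rate exceeds
  20× the seed-matched baseline rate (absolute fallback 25 Hz when the
  baseline is near-silent) or if the integrator reports runaway spike
  counts. Classification is made monotone in krec when summarizing a
  sweep. In this parameterization the abrupt epileptic transition sits
  near krec ≈ 25–28 (seed-dependent; pyramidal rates jump from ~3–5 Hz
  to >180 Hz); the delay-sweep design therefore defaults to krec ≤ 19,
  while the krec-sweep protocol deliberately crosses the transition.

## Statistics

`Δγ ~ kext + krec` is ordinary least squares with classical standard
errors on the raw (unstandardized) condition table, so coefficients stay on the
natural scale of the factors. Mediation uses z-scored X
(scaling factor), M (mean pyramidal rate) and Y (γ power): ACME = â·b̂
from the mediator (M~X) and outcome (Y~X+M) fits, ADE = ĉ′,
TE = ACME + ADE (an algebraic identity for linear models, asserted to
10⁻¹⁰ in tests), with 1000-resample percentile bootstrap CIs and
sign-inversion p-values. The bootstrap replaces the quasi-Bayesian
draws of the R implementation this mirrors; for linear models the two
are asymptotically equivalent, and the point estimates are cross-checked
against `statsmodels.stats.mediation` in the test suite.

## Synthetic fixtures

`fixtures` generates: sums of sinusoids plus Gaussian noise (band powers
known in closed form, A²/2 per component), rasters with population
volleys at a chosen rhythm and per-spike Gaussian jitter (spectral peak
at the rhythm frequency; large jitter degenerates to Poisson), linear
X→M→Y mediation tables with planted path coefficients, and down-scaled
network configs (populations and convergences × scale). These exercise
the full analysis and inference chain without the simulator. What they
do not emulate: conductance dynamics, theta-γ cross-frequency structure,
or any dependence of M and Y on a common biophysical cause — so passing
fixture tests validates the measurement code, not the network model.

## Problem sizes used in tests

The test suite runs one full-size 7 s baseline (the spectral-peak
check), direction checks at full size with shortened 4 s recordings and
2 seeds, and grid/probe bookkeeping on 0.1-scale networks. The full
16-condition × 16-seed grid behind the regression/mediation tables is
reproducible through the CLI (`ca3gamma grid`); the suite validates the
inference chain on synthetic tables with planted coefficients instead of
re-running it.

## Known limitations

- Channel rate equations are canonical rather than copied from the
  predecessor code; quantitative voltages/latencies differ in detail.
- The seizure threshold (krec ≈ 30 here vs ≈ 37 reported) and absolute
  γ power values are parameterization-dependent; sign structure and
  mechanism are the reproducible content.
- The LFP is a voltage-difference proxy, not a volume-conductor model.
- Basket-population synchrony relies on the strong septal gate; regimes
  with weak pacing show asynchronous fast basket activity instead of γ.
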