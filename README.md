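# ca3gamma

Simulation and analysis of sustained γ-power changes in a hippocampal CA3
microcircuit after synaptic potentiation — the setting used to ask whether
the lasting increase in γ (30–100 Hz) oscillation power seen after
subanaesthetic ketamine is better explained by potentiation of *external*
glutamatergic synapses onto pyramidal cells (disinhibition-driven,
activity-dependent LTP) or by potentiation restricted to *recurrent
collateral* synapses (direct, local AMPAR upscaling).

The package is aimed at computational neuroscientists who want a fast,
self-contained re-implementation of this model class: a spiking network
with conductance-based multicompartment neurons, the oscillation
statistics used to quantify γ power, the synaptic-scaling experiment
designs, and the regression/mediation inference that turns the simulated
condition tables into effect estimates.

## Model

Three populations with Hodgkin–Huxley-style dynamics:

- **800 pyramidal cells** — five compartments (soma, basal dendrite,
  three apical compartments) with transient Na⁺, delayed-rectifier K⁺,
  A-type K⁺ and Ih currents;
- **200 basket cells** — fast-spiking single compartments
  (Wang–Buzsáki kinetics), perisomatic-targeting;
- **200 OLM cells** — single compartments with high-threshold Ca²⁺,
  a Ca²⁺ pool and a Ca²⁺-activated K⁺ current (burst / after-burst
  quiescence), targeting the mid-apical dendrite;
- a **medial-septum pacemaker** inhibiting every interneuron once per
  theta period (150 ms).

All synapses are peak-normalized double-exponential conductances
g·N·(e^(−t/τ₂) − e^(−t/τ₁)) with a 2 ms delay; wiring follows fixed
convergence numbers with presynaptic partners drawn uniformly without
replacement.

Post-ketamine AMPAR potentiation is modeled by two multiplicative
factors applied to AMPA peak conductances:

- `krec` — recurrent pyramidal→pyramidal synapses (basal dendrite);
- `kext` — external (background) synapses at the pyramidal soma and
  distal apical dendrite.

The LFP proxy is the pyramidal-population mean of distal-apical minus
basal dendritic voltage; **γ power** is Welch spectral power summed over
30–100 Hz; **Δγ = γ(condition)/γ(seed-matched control) − 1**. "Raster γ"
applies the same measure to the pooled all-neuron spike train after 5 ms
boxcar smoothing. The inferential chain is OLS (`Δγ ~ kext + krec`) and
linear causal mediation (ACME = a·b, ADE = c′, TE = ACME + ADE, with
percentile-bootstrap CIs) using the mean pyramidal rate as mediator.

## Worked example

```python
from ca3gamma import (default_config, run_paired, ScalingCondition,
                      compute_lfp, welch_power, band_power,
                      peak_frequency, delta_gamma)

control, scaled = run_paired(default_config(seed=1),
                             ScalingCondition(krec=1.0, kext=1.75))
g0 = band_power(welch_power(compute_lfp(control)))
g1 = band_power(welch_power(compute_lfp(scaled)))
print(f"baseline gamma-band peak: "
      f"{peak_frequency(welch_power(compute_lfp(control)), 30, 100):.0f} Hz")
print(f"gamma power {g0:.3f} -> {g1:.3f},  dgamma = {delta_gamma(g1, g0):+.2f}")
```

prints (seed 1):

```
baseline gamma-band peak: 33 Hz
gamma power 0.120 -> 0.157,  dgamma = +0.31
```

i.e. the baseline network oscillates with a γ cycle of ≈ 30 ms, and
scaling the external AMPA conductances by 1.75 raises γ power by ~31 %,
while the same factor applied to the recurrent collaterals leaves γ
power flat or slightly reduced — the signature that favors the
disinhibition account. Mechanistically, recurrent input arrives half a
γ cycle out of phase at the pyramidal somata and partially cancels the
extant oscillation; the `delay-sweep` experiment shows the effect invert
when an extra half-cycle delay is added to the recurrent synapses, and
the `probe` experiment shows the recurrent EPSP peaking between γ peaks.

A CLI mirrors the workflow: `ca3gamma simulate`, `ca3gamma grid`,
`ca3gamma krec-sweep`, `ca3gamma delay-sweep`, `ca3gamma probe`,
`ca3gamma analyze regression|mediation`, `ca3gamma fixtures`.

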