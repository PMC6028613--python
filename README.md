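# navsig

Voltage-clamp simulation and activation-sigmoidicity analysis for
voltage-gated sodium channels.

## The problem

Whether CNS sodium channels obey classical Hodgkin–Huxley (HH) gating is
not settled: several nucleated-patch studies report that the current
after a step from a hyperpolarized holding potential rises with a
pronounced delay, as if the channel had to traverse many closed states
before opening — the Cole–Moore effect familiar from potassium
channels. The standard way to quantify this is the *sigmoidicity* of
the current onset: fit the early rise (up to 50% of the peak, after
discarding the first 50 µs contaminated by the capacitive transient)
with the exponential-power model

```
I(t) = Imax · (1 − e^(−t/τ))^N
```

where the exponent N is the *apparent number of activation gates*. For
an HH scheme with p independent gates, N = p at every voltage; for a
sequential (linear Markov chain) scheme, N tracks how deep in the chain
of closed states the channel sits before the step, so N falls as the
pre-pulse potential is depolarized. In the depolarized regime where
backward rates are negligible, the mean latency to first opening of a
chain is

```
δ(V) = Σᵢ 1/αᵢ(V)
```

the mean first-passage time from the deepest closed state to the open
state.

`navsig` packages everything needed to study this on simulated data:

* **Gating models** — HH-style independent-gate schemes (`m^p·h^q`) and
  linear Markov chains `C_N ⇌ … ⇌ C₁ ⇌ O` with optional inactivated
  states, all with configurable voltage-dependent rate functions
  (constant / exponential / linoid / sigmoid), solved exactly per
  constant-voltage epoch (analytic relaxation or matrix exponential),
  with a fixed-step RK4 integrator retained for cross-validation.
* **Protocols** — activation families (hold, then step to test
  potentials) and steady-state-inactivation families (150 ms pre-pulse
  sweep, common test step).
* **Acquisition emulation** — linear leak, capacitive transients, P/4
  subtraction, 4-pole Bessel low-pass at 20 kHz (group-delay
  compensated), resampling to 100 kHz, band-limited Gaussian noise, and
  exclusion of the first 50 µs after the step, so analysis code can be
  validated on data with realistic structure.
* **Analysis** — statsmodels-style model/results objects for the onset
  sigmoidicity fit, the activation I–V fit
  `I/|Imax| = B(V−E_Na)/(1+e^(−(V−V½)/z))`, and the steady-state
  inactivation Boltzmann `1/(1+e^((V−V½)/z))`, plus per-patch peak
  normalization and N-versus-voltage profile aggregation.

Units package-wide: mV, ms, nS, pA; rates in 1/ms.

## Worked example

Fit the onset of the built-in HH sodium model stepped from −110 to
−10 mV, then profile the fitted N against the pre-pulse potential in a
steady-state-inactivation sweep:

```python
import numpy as np
import navsig as ns

model = ns.hh_sodium_model()
proto = ns.build_activation_protocol(hold=-110, hold_duration=150,
                                     test_voltages=[-10], test_duration=25)[0]
trace = ns.simulate_current(model, proto)
print(ns.OnsetSigmoidicityModel(trace).fit().summary())

protos = ns.build_inactivation_protocol(np.arange(-120, -49, 10), 150, 0, 25)
traces = []
for p in protos:
    tr = ns.simulate_current(model, p)
    tr.condition_voltage = p.epochs[0][1]
    traces.append(tr)
print(ns.sigmoidicity_profile(traces, condition="prepulse").to_string(index=False))
```

prints

```
Onset sigmoidicity fit: I = Imax (1 - exp(-t/tau))^N
  window       : 0.050 .. 0.305 ms (52 samples)
  peak         : -391.3 pA
  imax         : 504.5 +/- 1.17
  tau          : 0.227 +/- 0.000516
  n            : 3.076 +/- 0.00377
  residual norm: 0.434
  converged    : True

 voltage   n_mean  n_sem  tau_mean  n_reps  n_failed
  -120.0 3.071851    0.0  0.187970       1         0
  -110.0 3.070692    0.0  0.188023       1         0
  -100.0 3.066015    0.0  0.188237       1         0
   -90.0 3.047734    0.0  0.189084       1         0
   -80.0 2.980058    0.0  0.192331       1         0
   -70.0 2.752713    0.0  0.205322       1         0
   -60.0 2.229227    0.0  0.247795       1         0
   -50.0 2.079102    0.0  0.180008       1         0
```

Read: the HH model's three activation gates are recovered (N ≈ 3.08)
from a hyperpolarized origin, the fit stays at N ≈ 3 for all pre-pulses
below the activation threshold (−120…−80 mV), and N falls once the
pre-pulse begins to redistribute gate occupancy — the Cole–Moore
signature. A sequential chain with six closed states shows the same
qualitative profile starting from N ≈ 6.5 (see the test suite).

A command-line interface mirrors the library
(`navsig simulate | synth | analyze-onset | activation-curve |
inactivation-curve | profile`); every run writes a `run_log.yaml`
recording the resolved configuration, seed and package version.

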