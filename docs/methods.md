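# Methods

## Gating models and their solution

Two scheme families are implemented.

**Independent-gate (HH) schemes.** Open probability `m(t)^p · h(t)^q`
with `p ≥ 1` activation gates and `q ≥ 0` inactivation gates. Each gate
relaxes as `x(t) = x∞ − (x∞ − x0) e^(−t/τx)` with `x∞ = α/(α+β)`,
`τx = 1/(α+β)`; under a piecewise-constant voltage command this
analytic per-epoch solution is exact, so no integrator is involved.
Setting `q = 0` *removes* inactivation (the gate is absent, not
frozen). The built-in sodium model uses the classic squid-axon rate
laws expressed on the modern membrane-potential scale (resting
potential near −65 mV), `p = 3`, `q = 1`, `g_max = 20 nS`,
`E_rev = +50 mV`. These are defaults of a configuration, not constants:
any model can be swapped in through the YAML model format
(`navsig.io.load_model`), which is also the hook for hand-translated
literature Markov schemes.

**Linear chains.** States are ordered `C_Nc … C₁, O`, then inactivated
states; the generator `Q(V)` acts on column occupancy vectors
(`dp/dt = Q p`) and has zero column sums, so total occupancy is
conserved by construction. The default propagator is the matrix
exponential of `Q·dt` applied stepwise — exact for constant voltage —
with a classical RK4 fixed-step integrator retained solely for
cross-validation (the two agree to < 1e−4 occupancy at the 5 µs step
used throughout). Stationary states are computed from the null space
of `Q(V)`; a null space of dimension ≠ 1 (disconnected scheme) is an
error, not a silent choice.

**Rate functions.** Four forms: constant, exponential
`r₀ e^((V−Vref)/k)`, linoid `r₀ (V−Vref)/(1 − e^(−(V−Vref)/k))` (the
removable singularity at `V = Vref` is evaluated analytically as
`r₀·k`), and logistic sigmoid `r₀/(1 + e^(−(V−Vref)/k))`. The sigmoid
form is required by the classic HH inactivation closing rate and is a
deliberate extension of the minimal form set. Units: mV, ms, nS, pA,
rates 1/ms.

**Mean activation latency.** For a chain in the depolarized regime
where backward rates are negligible, `δ(V) = Σᵢ 1/αᵢ(V)` is the mean
first-passage time from the deepest closed state to the open state.
`mean_activation_latency` evaluates this sum directly and errors on any
non-positive forward rate (infinite latency); the test suite verifies
it against an independent absorbing-chain linear solve.

## Protocols and simulation

A protocol is an ordered list of constant-voltage epochs with one
designated test epoch; its onset defines `t = 0` (ideal clamp: the
command transition is instantaneous; series-resistance shaping of the
command is out of scope). Simulation starts from the stationary state
at the first epoch's voltage and propagates with continuity across
steps. Current is `g_max · P_open · (V − E_rev)` in pA, inward
negative. The default integration/sampling step is 5 µs and the default
test epoch 25 ms — long enough for the full transient at every test
potential used here.

## Acquisition-chain emulation

The synthetic-data layer converts ideal traces into "recordings" with
the statistical structure of nucleated-patch data:

1. add linear leak `g_leak (V(t) − E_leak)` (default 1 nS, 0 mV) and a
   capacitive transient at every command step (default 10 pA/mV of
   step, τ = 20 µs, i.e. decayed to baseline well inside 40 µs);
2. add white Gaussian noise (default SD 2 pA) *before* filtering, so
   recorded noise is band-limited as in a real amplifier chain;
3. P/4 leak subtraction, emulated analytically: the linear part of the
   leak and transient is subtracted exactly, which is what an ideal
   P/4 protocol achieves; a residual survives only if the transient is
   given a nonlinear amplitude component (`cap_nonlinear_fraction`);
4. causal 4-pole low-pass Bessel filter at 20 kHz (the exact filter
   family of the recording hardware is a modelling choice; Bessel is
   the conventional anti-alias filter in patch clamp). The filter's
   constant group delay (≈17 µs at 20 kHz) is compensated by a pure
   sample shift — legitimate because the Bessel response is
   maximally-flat-delay — so the recorded time base stays aligned with
   the command step and onset fits on recorded and ideal traces agree
   (N = 3.11 vs 3.07 on the built-in HH model);
5. resample to the 100 kHz acquisition grid (10 µs);
6. mark the first 50 µs after the test onset as excluded; the samples
   are retained but never enter peaks or fits.

Multi-patch datasets draw an independent log-normal conductance scale
per patch (default CV 0.2) and independent noise; kinetic parameters
are *not* jittered (kinetics are pooled across patches). Default
ensemble sizes are 9 (activation) and 11 (inactivation) patches,
matching typical nucleated-patch studies.

What the generator does **not** emulate: series-resistance and
space-clamp errors, amplifier saturation, drift/rundown, channel
stochasticity (ensemble currents only), liquid-junction-potential
offsets (noted, not applied), temperature effects. Tests passing on
these data therefore validate the analysis pipeline's correctness and
statistical behaviour, not robustness to every artifact of real
recordings.

**Parametric recovery families.** For Monte-Carlo validation of the
curve fits, a second generator produces traces whose onset is exactly
`Imax(1−e^(−t/τ))^N` and whose peak amplitudes follow a prescribed
activation I–V relation (half-activation −24 mV, slope 5.2 mV,
reversal +75 mV, normalized to the −10 mV response) or availability
Boltzmann (half-inactivation −64.5 mV, slope 8.3 mV). On top of
acquisition noise these add per-sweep amplitude scatter of 0.05
normalized units, the realistic sweep-to-sweep variability scale for
such ensembles; without it the Monte-Carlo spread of the fitted curve
parameters collapses to the microvolt scale and ceases to represent
experimental uncertainty. Epochs are shortened to 5 ms here (the curve
parameters do not depend on epoch length).

## The fits

**Onset sigmoidicity.** Nonlinear least squares of the
baseline-subtracted current magnitude against `Imax(1−e^(−t/τ))^N`,
with `t` physical time since the step (the model stays anchored at the
true onset even though early samples are excluded). Window: from the
truncation boundary (50 µs; any wider per-trace exclusion mask is
honored) to the first sample at ≥ 50% of the peak magnitude,
inclusive; at least 8 samples are required, otherwise the fit is
refused. Baseline is the mean current over the last 1 ms before the
step; the peak is the extremum of the baseline-subtracted current over
the test epoch. Initialization `N₀ = 3`, `τ₀ = t₅₀ − t₁₀`,
`Imax₀ = 2|peak|`; bounds `N ∈ [0.5, 40]`, `τ ∈ [dt, 100 ms]`,
`Imax ∈ [0.5, 10]·|peak|`. N is reported as a continuous shape
statistic (non-integer values are meaningful). A result whose free
parameter lands on a bound is flagged `at_bound` and excluded from
profiles; when N is deliberately fixed (e.g. at 3 for the HH
comparison) the constrained optimum is reported as converged.

Degenerate regime: once the pre-pulse leaves the channel substantially
open before the step, the onset is dominated by the instantaneous
driving-force jump and the baseline-subtracted magnitude is no longer
a monotone rise; fitted N is then not a meaningful gate count.
Profiles flag and exclude non-converged fits, and the Cole–Moore
monotonicity claim is asserted only over the pre-pulse range that
still reshuffles *closed*-state occupancy (for the six-state reference
chain, pre-pulses up to −50 mV, where steady-state open probability at
the pre-pulse is still small).

**Activation I–V.** `I/|Imax| = B (V − E_Na)/(1 + e^(−(V−V½)/z))` fit
to per-patch-normalized, across-patch-averaged peaks (each patch
divided by the magnitude of its −10 mV response, preserving sign, so
the reference point is −1 for inward current). The printed source form
of this equation is typographically garbled; the implemented form is
the standard Boltzmann-activation-times-driving-force expression
consistent with the stated parameter meanings, with `z > 0` under the
convention that makes activation increase with V. All-zero data is
flagged degenerate rather than fitted.

**Steady-state inactivation.** `1/(1 + e^((V−V½)/z))` fit to peaks
normalized to the −110 mV pre-pulse response. Grossly non-monotone
data is still fitted but flagged. Because the −110 mV reference is not
exactly full availability (availability 0.996 for the default
parameters), the normalized curve is scaled by 1/0.996, which biases
the fitted half-voltage by ≈ +0.17 mV; this is an intrinsic property
of the normalization convention, shared with the experimental
procedure, and is small against the Monte-Carlo spread under realistic
sweep scatter.

## Numerical choices

* Probability conservation is asserted (1e−8) at every propagation
  sample; occupancy clipping is never applied silently.
* Matrix-exponential stepping is used rather than eigendecomposition
  because equal-rate forward-only chains have defective generators.
* Trace tables round-trip losslessly: floats are written with 17
  significant digits and parsed with correctly-rounded conversion.
* Determinism: every stochastic element (noise, patch scales) flows
  from a single `numpy` Generator seeded explicitly; identical seed and
  configuration give byte-identical outputs.

## Problem sizes used in the shipped studies

Sigmoidicity profiles use 150 ms conditioning epochs and 25 ms test
epochs at 5 µs resolution (35 001 samples/trace). The Monte-Carlo
recovery study runs 100 seeds × (9-patch activation + 11-patch
inactivation) families with 5 ms epochs; the first-passage check uses
100 random chains of 2–8 transitions. These sizes make every headline
claim reproducible on a laptop in about two minutes total.

## Known limitations

* Ensemble (mean-field) currents only; no single-channel stochasticity.
* No Q10/temperature scaling (all reference work at 25 °C).
* No NMODL translation; literature models must be hand-translated into
  the YAML scheme format.
* The onset-sigmoidicity statistic is undefined for conditions whose
  pre-step open probability is substantial (see above); profiles report
  such conditions as failed fits rather than numbers.
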