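# Methods

## Equivalent-circuit model

The electrode-tissue interface is the three-element network
`Rs + (Rp ‖ Cp)`: a series electrode resistance feeding a parallel
tissue resistance and capacitance. Its complex impedance at frequency
`f` (Hz; `ω = 2πf` is internal) is

```
Z(f) = Rs + Rp/(1 + ω²Rp²Cp²) − j · ωRp²Cp/(1 + ω²Rp²Cp²)
```

with magnitude asymptotes `Rs + Rp` (ω→0) and `Rs` (ω→∞), a single
pole at `f_c = 1/(2πRpCp)`, and discharge time constant
`τ = RsRpCp/(Rs + Rp)`. At the pole the real part is exactly
`Rs + Rp/2` while the *measured magnitude* is
`√((Rp/2)² + (Rs + Rp/2)²)`, because the imaginary component peaks
(at `Rp/2`) exactly there. Constant-phase-element behaviour and
Faradaic nonlinearity are out of scope; the model is linear and
time-invariant between degradation steps.

Component values outside 16 Ω – 66 kΩ only *warn* at construction:
that window is a limitation of the measurement chain (compliance
voltage and DAC resolution), not of the circuit algebra.

## Waveforms and hardware quantization

Current amplitudes snap to the 6.3 µA DAC step (ties toward zero, so a
quantized amplitude never exceeds the request) and clamp at ±1.6 mA;
switch times snap to 1 µs. Waveforms are sampled at `dt = 0.1 µs` by
default — ten times below the device timing resolution, so sampling
error is negligible against every design bound. Phases occupy
half-open windows on the sample grid; charge is integrated with the
trapezoid rule (linear interpolation at fractional bounds).

### Closed-form discharge vs. the transient oracle

The capacitor-coupled anodic phase is modelled in closed form as
`I(t) = Vcap/(Rs+Rp) · e^(−t/τ)` with `Vcap = Ipos·tcharge/Csource` —
the tissue time constant and a fixed initial amplitude. A physical
discharge also depletes `Csource` itself (effective decay
`≈ Csource(Rs+Rp)` when `Csource ≪ Cp`) and initially shunts through
the uncharged `Cp`. The package therefore carries a numerical oracle:
a fixed-step RK4 integration of the two-capacitor state
`(v_source, v_tissue)` with the switch state frozen per step (sampled
at the step midpoint) so no step straddles a phase boundary. The
oracle conserves charge against the source-capacitor voltage drop to
<0.1 %, converges to the ideal-voltage-source step response as
`Csource → ∞` and to a single-RC decay as `Cp → 0`, and rejects
`dt` above a fiftieth of the fastest relevant time constant.

For the bench scenario (0.1 µF source, `Rs = 220 Ω`, `Rp = 510 Ω`,
`Cp = 22 µF`) the oracle shows the closed form **overestimates the
delivered anodic charge by roughly 60 %**. The balancing algebra and
its audit both use the closed form — consistently, so the balance
itself is accurate — but absolute charge figures derived from it
inherit that approximation. The test suite asserts the gap is present
and measured rather than pretending it is small.

## Measurement-chain simulation

One monitoring sweep reads, per grid frequency (log-spaced,
8 points/decade, 1 Hz – 10 kHz inclusive → 33 points), the voltage
`|Z(f)|·i_stim`, adds Gaussian voltage noise averaged over 1000
samples, quantizes the average with a 14-bit ADC over 0 – 3.3 V,
divides by the test current and adds an optional constant ohmic bias
(such an offset is a documented artefact of real ADC chains). The
default per-sample noise sd is one ADC step; after 1000-sample
averaging it is ~6 µV, far below the 201 µV quantizer step, so the
simulated chain is **quantization-dominated**: repeated sweeps with
different noise seeds usually produce identical readings. This is a
faithful consequence of the described chain, not a simplification —
and it means extraction error is essentially deterministic at these
settings (~0.5 % worst case). Phase is not measured; only the
magnitude is available, which is why the correction step below exists.
A sweep whose DC voltage `(Rs+Rp)·i_stim` would exceed the rail raises
a compliance error (the device's indicator-LED condition).

## Parameter extraction

Given a raw magnitude spectrum:

1. `Rs` ← mean of the two highest-frequency magnitudes;
   `Rs + Rp` ← mean of the two lowest-frequency ones. Two points
   average noise without leaving the asymptotic region on the default
   grid.
2. Locate the pole: take the 3 points whose magnitude is nearest the
   expected pole value, fit magnitude against `log10 f` by least
   squares, and solve the line for the target. On the first pass —
   before any `Cp` estimate exists — the *raw* spectrum is used with
   the magnitude-at-cutoff target `√((Rp/2)² + (Rs+Rp/2)²)`.
3. `Cp ← 1/(2πRp·f_cutoff)`.
4. Correct the spectrum by removing the modelled imaginary component
   in quadrature, `Zreal = √(max(0, |Z|² − Im²))`, then repeat 1–3 on
   the **corrected** spectrum with pole target `Rs + Rp/2`, iterating
   until all three estimates move < 0.1 % (≤ 10 iterations).

The two-stage target choice is deliberate: the raw magnitude curve is
asymmetric in `log f`, which biases the 3-point line fit by ~1 %,
whereas the corrected (real-part) curve is an antisymmetric sigmoid in
`log f` around the pole, and the same regression recovers `f_cutoff`
to ~0.2 %. Noise-free recovery of all three parameters is < 1 %;
under 14-bit quantization the worst case over the three bench circuits
is ~0.6 %.

Degenerate inputs: a flat (purely resistive) spectrum has no pole and
raises an extraction failure naming the offending stage; a zero-slope
regression line falls back to the nearest point's frequency with a
warning. A constant ohmic bias lands entirely in `Rs` (the asymptote
difference cancels it out of `Rp`) — a documented limitation, tested
as such.

## Charge balancing

`balance_biphasic` solves `tneg = Ipos·tpos/Ineg`;
`balance_cap_coupled` evaluates the discharge integral
`Q = Vcap/(Rs+Rp)·τ·(1 − e^(−tpos/τ))` and sets `tneg = Q/Ineg`.
(The intermediate algebraic form with `τ` inside the parenthesis that
sometimes appears for this quantity is dimensionally inconsistent; the
evaluated integral is what is implemented.) Both results are
quantized to 1 µs, so a freshly balanced setting carries a residual of
at most `(1 µs / tneg)·100 % + 0.1 %` when audited by integration.
The audit (`verify_balance`) integrates the cathodic and anodic phases
of the sampled waveform separately and reports
`|Qneg − Qpos|/Qpos · 100 %` — normalized by the anodic charge.

Across the four bench degradation scenarios
(`Rs ∈ {220, 330, 440, 510} Ω`, `Rp = 510 Ω`, `Cp = 22 µF`, 0.5 mA
phases, 200 µs discharge, 0.1 µF source charged 150 µs) the residual
is < 0.1 % from true parameters and < 1 % when balancing from noisy
AIM estimates — inside the 5 % design bound with a wide margin.

## Closed loop and degradation law

Every 30 simulated minutes the loop synthesizes a spectrum from the
*current* true circuit, extracts parameters, and (when enabled)
recomputes `tneg` from the estimates — never from the truth, so the
monitoring→balancing chain is exercised honestly. Between checks the
electrode degrades by an **explicitly invented** law (real degradation
is electrochemical and outside what circuit data can determine):

- baseline drift: 0.2 Ω/h regardless of balance (→ 16 Ω over 80 h);
- wear: 15 Ω per coulomb of accumulated imbalance charge
  (`residual/100 · Qpos · pulses`);
- breakage: once cumulative imbalance crosses 8 C the resistance jumps
  to ≥ 660 Ω (strand fracture).

The calibration reproduces the two observed endpoints it is built
from: a balanced electrode drifts < 20 Ω over 80 h of 1 kHz
stimulation (288 million pulses), while a ~36 % imbalanced one breaks
near 31 h. Only this qualitative contrast is meaningful; the law's
shape between the endpoints is plumbing, and all four constants are
config-exposed (`DegradationParams`). Per-pulse effects are
aggregated analytically per 30-minute interval, so an 80 h run costs
161 checks, not 288 million pulse updates. Traces are bit-reproducible
for a fixed `(seed, config)`: per-check measurement seeds are spawned
deterministically from the run seed.

## What the synthetic data does and does not show

The generator emulates the *described instrument*: ideal linear RC
load, Gaussian voltage noise, uniform ADC quantization, exact test
currents. It does not emulate constant-phase electrodes, electrode
drift within a sweep, PWM timing interleaving, thermal effects, or the
electrochemistry of real degradation. Passing tests therefore
demonstrate the correctness and internal consistency of the
algorithms under the stated model — not instrument-grade accuracy on
real tissue, where fitted hardware measurements have shown errors up
to ~10 % (the bound the extraction tests assert) rather than the
~0.5 % the idealized chain achieves.

## Problem sizes

Default test and acceptance runs use 33-point spectra, 100 measurement
seeds per bench circuit, 0.1 µs waveform sampling over 1 ms periods,
and closed-loop runs of 8–30 simulated hours; the whole suite and the
acceptance script each complete in a few seconds.
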