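# stimbalance

Charge-balanced neurostimulation with active impedance monitoring, in
pure software.

Implanted current stimulators must inject zero *net* charge per pulse:
any residual between the cathodic and anodic phases corrodes the
electrode and injures tissue. Balancing is trivial for square biphasic
pulses (`Ipos·tpos = Ineg·tneg`) but not for **capacitor-coupled**
stimulation, where the anodic phase is the exponential discharge of a
source capacitor through the electrode-tissue load — and where the
balance point drifts as the electrode degrades. `stimbalance` models
the full computation chain such a device runs:

- **Equivalent circuit** — series electrode resistance `Rs` feeding a
  parallel tissue pair `Rp ‖ Cp`, with impedance

  `Z(f) = Rs + Rp/(1 + (ωRpCp)²) − j·ωRp²Cp/(1 + (ωRpCp)²)`, `ω = 2πf`,

  low/high-frequency asymptotes `Rs + Rp` and `Rs`, pole at
  `f_c = 1/(2πRpCp)` and discharge time constant
  `τ = RsRpCp/(Rs + Rp)`.
- **Active impedance monitoring (AIM)** — simulates the magnitude
  measurement (log-spaced 1 Hz–10 kHz test currents, 14-bit ADC on a
  3.3 V rail, 1000-sample averaging) and recovers `(Rs, Rp, Cp)` from
  the spectrum by asymptote estimation, 3-point cutoff regression and
  imaginary-component correction, iterated to a fixed point.
- **Charge balancing** — solves the cathodic pulse width from
  `Ineg·tneg = Vcap/(Rs+Rp) · τ·(1 − e^(−tpos/τ))` (capacitor-coupled)
  or plain area equality (biphasic), quantized to the 6.3 µA / 1 µs
  hardware grid, and audits the result by trapezoidal integration of
  the sampled waveform.
- **Transient oracle** — an RK4 integration of the full two-capacitor
  circuit (source capacitor + tissue capacitance) that measures, rather
  than assumes, the error of the closed-form discharge.
- **Closed loop** — a 30-minute monitor-and-rebalance cycle over a
  degrading electrode, with an explicit (invented, endpoint-calibrated)
  degradation law, reproducing the balanced-vs-unbalanced lifetime
  contrast.

## Worked example

Monitor a bench circuit (`Rs = 220 Ω`, `Rp = 510 Ω`, `Cp = 22 µF`),
fit the model to the noisy 14-bit measurement, then balance the
capacitor-coupled mode (0.1 µF source capacitor charged at 0.5 mA for
150 µs, 200 µs discharge, 0.5 mA cathodic phase) using the *estimated*
parameters and audit it against the *true* circuit:

```python
import stimbalance as sb

true = sb.ElectrodeTissueModel(r_s=220.0, r_p=510.0, c_p=22e-6)
spectrum = sb.synthesize_measurement(true, sb.MeasurementConfig(seed=1))
fit = sb.ImpedanceFit(spectrum).fit()
print(fit.summary())

settings = sb.StimulationSettings(
    mode="cap_coupled", i_pos=0.5e-3, i_neg=0.5e-3,
    t_pos=200e-6, t_neg=200e-6, period=1e-3,
    c_source=0.1e-6, t_charge=150e-6,
)
t_neg = sb.balance_cap_coupled(fit.as_model(), settings.v_cap(),
                               settings.t_pos, settings.i_neg)
audit = sb.verify_balance(true, settings.with_t_neg(t_neg))
print(f"balanced t_neg  = {t_neg * 1e6:.0f} us")
print(f"residual        = {audit.residual_pct:.2f} %")
```

prints

```
Electrode-tissue impedance fit
==============================
  Rs (electrode)         219.80 ohm
  Rp (tissue)            506.37 ohm
  Cp (tissue)            21.874 uF
  f_cutoff                14.37 Hz
  iterations                  4
  converged                True
balanced t_neg  = 401 us
residual        = 0.48 %
```

The fit recovers all three components to well under 1 % despite ADC
quantization, and the pulse width balanced from those noisy estimates
leaves a residual charge deviation of half a percent — far inside the
5 % design bound.

The same operations are available from a shell:

```sh
stimbalance simulate-spectrum --r-s 220 --r-p 510 --c-p 2.2e-6 --seed 1 --out spec.csv
stimbalance extract --spectrum spec.csv
stimbalance balance --mode cap_coupled --i-pos 0.5e-3 --i-neg 0.5e-3 \
    --t-pos 200e-6 --t-charge 150e-6 --c-source 0.1e-6 \
    --r-s 220 --r-p 510 --c-p 22e-6
stimbalance run-loop --config run.json --trace-out trace.csv
```

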