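"""Quantized stimulation waveforms and the transient circuit oracle.

Two stimulation modes are supported:

``biphasic``
    Cathodic (negative) square phase immediately followed by an anodic
    (positive) square phase, then rest until the end of the period.

``cap_coupled``
    Cathodic square phase during which an on-board source capacitor
    ``Csource`` is charged with a constant current; the anodic phase is
    the exponential discharge of that capacitor through the
    electrode-tissue load.

The hardware quantizes current amplitudes to 6.3 uA steps (clamped to
+/-1.6 mA) and switch timing to 1 us; both rules live here so every
other module inherits them.

The closed-form discharge (``discharge_current``) uses the initial
current ``Vcap / (Rs + Rp)`` decaying with the *tissue* time constant
``tau = Rs*Rp*Cp/(Rs+Rp)``.  A physical source-capacitor discharge also
drains ``Csource`` itself, which the closed form ignores;
``transient_oracle`` integrates the full two-capacitor network
numerically so the approximation error of the closed form can be
measured rather than assumed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .circuit import ElectrodeTissueModel

__all__ = [
    "CURRENT_STEP",
    "CURRENT_MAX",
    "TIME_STEP",
    "StimulationMode",
    "StimulationSettings",
    "CurrentWaveform",
    "TransientResult",
    "quantize_current",
    "quantize_time",
    "v_capacitor",
    "discharge_current",
    "build_waveform",
    "integrate_charge",
    "transient_oracle",
]

CURRENT_STEP = 6.3e-6  # A, DAC resolution
CURRENT_MAX = 1.6e-3  # A, DAC full scale
TIME_STEP = 1e-6  # s, switch-timing resolution


def _round_ties_toward_zero(x: float) -> int:
    """Nearest integer; exact .5 ties round toward zero."""
    return int(math.ceil(abs(x) - 0.5)) * (1 if x >= 0 else -1)


def quantize_current(i: float) -> float:
    """Snap a current (A) to the nearest 6.3 uA DAC step, clamped to +/-1.6 mA.

    Ties round toward zero so a quantized amplitude never exceeds the
    requested one; the clamp keeps the full-scale endpoint reachable.
    """
    if not math.isfinite(i):
        raise ValueError("current must be finite")
    n = _round_ties_toward_zero(abs(i) / CURRENT_STEP)
    value = min(n * CURRENT_STEP, CURRENT_MAX)
    return math.copysign(value, i) if i != 0 else 0.0


def quantize_time(t: float) -> float:
    """Snap a duration (s) to the nearest 1 us switch tick (ties toward zero)."""
    if t < 0:
        raise ValueError("duration must be non-negative")
    return _round_ties_toward_zero(t / TIME_STEP) * TIME_STEP


class StimulationMode(str, Enum):
    BIPHASIC = "biphasic"
    CAP_COUPLED = "cap_coupled"


@dataclass(frozen=True)
class StimulationSettings:
    """One stimulation period's worth of settings, quantized on construction.

    Currents are stored as positive magnitudes; the negative phase is
    applied with a minus sign.  In ``cap_coupled`` mode ``i_pos`` is the
    source-capacitor charging current and ``t_charge`` (default:
    ``t_neg``) the charging duration; charging is concurrent with the
    negative phase.
    """

    mode: StimulationMode
    i_pos: float
    i_neg: float
    t_pos: float
    t_neg: float
    period: float
    c_source: float | None = None
    t_charge: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", StimulationMode(self.mode))
        object.__setattr__(self, "i_pos", quantize_current(abs(self.i_pos)))
        object.__setattr__(self, "i_neg", quantize_current(abs(self.i_neg)))
        object.__setattr__(self, "t_pos", quantize_time(self.t_pos))
        object.__setattr__(self, "t_neg", quantize_time(self.t_neg))
        object.__setattr__(self, "period", quantize_time(self.period))
        if self.mode is StimulationMode.CAP_COUPLED:
            if self.c_source is None or self.c_source <= 0:
                raise ValueError("cap_coupled mode requires a positive c_source")
            t_charge = self.t_neg if self.t_charge is None else quantize_time(self.t_charge)
            if t_charge <= 0:
                raise ValueError("t_charge must be positive in cap_coupled mode")
            object.__setattr__(self, "t_charge", t_charge)
        if not 10e-6 <= self.period <= 10.0:
            raise ValueError("period must lie within [10 us, 10 s]")
        if self.t_pos < 0 or self.t_neg < 0:
            raise ValueError("phase durations must be non-negative")
        if self.t_pos + self.t_neg > self.period * (1 + 1e-12):
            raise ValueError("t_pos + t_neg must not exceed the period")

    def with_t_neg(self, t_neg: float) -> "StimulationSettings":
        """Copy with a new (re-balanced) negative pulse width."""
        return replace(self, t_neg=t_neg)

    def v_cap(self) -> float:
        """Source-capacitor voltage at the end of charging (cap_coupled only)."""
        if self.mode is not StimulationMode.CAP_COUPLED:
            raise ValueError("v_cap is only defined in cap_coupled mode")
        return v_capacitor(self.i_pos, self.t_charge, self.c_source)


@dataclass(frozen=True)
class CurrentWaveform:
    """Uniformly sampled current trace: sample ``k`` holds the value at ``t0 + k*dt``."""

    dt: float
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("samples must be a 1-D array with at least 2 points")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.samples.size)

    @property
    def t_end(self) -> float:
        return self.t0 + self.dt * (self.samples.size - 1)


def v_capacitor(i_charge: float, t_charge: float, c_source: float) -> float:
    """Voltage reached by a capacitor charged at constant current: ``I*t/C``."""
    if c_source <= 0:
        raise ValueError("c_source must be positive")
    if i_charge < 0 or t_charge < 0:
        raise ValueError("charging current and duration must be non-negative")
    return i_charge * t_charge / c_source


def discharge_current(model: ElectrodeTissueModel, v_cap: float, t) -> float | np.ndarray:
    """Closed-form discharge current ``Vcap/(Rs+Rp) * exp(-t/tau)``.

    ``tau`` is the tissue time constant of ``model``; see the module
    docstring for what this approximation leaves out.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    tau = model.time_constant
    out = v_cap / (model.r_s + model.r_p) * np.exp(-t_arr / tau)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def build_waveform(
    settings: StimulationSettings,
    model: ElectrodeTissueModel | None = None,
    dt: float = 1e-7,
) -> CurrentWaveform:
    """Sample one full stimulation period at resolution ``dt``.

    The negative square phase comes first, then the positive phase
    (square in ``biphasic`` mode, closed-form exponential discharge in
    ``cap_coupled`` mode), then rest at zero current.  Phases occupy
    half-open windows ``[start, end)`` on the sample grid.
    """
    if dt > TIME_STEP:
        raise ValueError("dt must not exceed the 1 us timing resolution")
    if settings.mode is StimulationMode.CAP_COUPLED and model is None:
        raise ValueError("cap_coupled waveforms need an electrode-tissue model")

    n = int(round(settings.period / dt))
    t = dt * np.arange(n + 1)
    samples = np.zeros(n + 1)

    b = int(round(settings.t_neg / dt))
    p = int(round(settings.t_pos / dt))
    samples[:b] = -settings.i_neg
    if settings.mode is StimulationMode.BIPHASIC:
        samples[b : b + p] = settings.i_pos
    else:
        t_rel = t[b : b + p] - settings.t_neg
        samples[b : b + p] = discharge_current(model, settings.v_cap(), t_rel)
    return CurrentWaveform(dt=dt, samples=samples)


def integrate_charge(
    waveform: CurrentWaveform,
    t_start: float | None = None,
    t_end: float | None = None,
) -> float:
    """Trapezoidal charge integral (coulomb) of a waveform over ``[t_start, t_end]``.

    Bounds default to the full trace; bounds strictly inside the trace
    that fall between samples are handled by linear interpolation.
    """
    t_start = waveform.t0 if t_start is None else t_start
    t_end = waveform.t_end if t_end is None else t_end
    tol = 1e-9 * waveform.dt
    if t_start >= t_end:
        raise ValueError("t_start must be strictly less than t_end")
    if t_start < waveform.t0 - tol or t_end > waveform.t_end + tol:
        raise ValueError("integration bounds must lie within the waveform")

    s = waveform.samples
    x0 = min(max((t_start - waveform.t0) / waveform.dt, 0.0), s.size - 1.0)
    x1 = min(max((t_end - waveform.t0) / waveform.dt, 0.0), s.size - 1.0)
    i0 = int(math.ceil(x0 - 1e-9))
    i1 = int(math.floor(x1 + 1e-9))
    q = 0.0
    if i1 > i0:
        q += float(np.trapezoid(s[i0 : i1 + 1], dx=waveform.dt))
    if x0 < i0 - 1e-9:  # partial leading segment
        v0 = s[i0 - 1] + (s[i0] - s[i0 - 1]) * (x0 - (i0 - 1))
        q += 0.5 * (v0 + s[i0]) * (i0 - x0) * waveform.dt
    if x1 > i1 + 1e-9:  # partial trailing segment
        v1 = s[i1] + (s[i1 + 1] - s[i1]) * (x1 - i1)
        q += 0.5 * (s[i1] + v1) * (x1 - i1) * waveform.dt
    return q


@dataclass(frozen=True)
class TransientResult:
    """Output of the two-capacitor transient oracle."""

    waveform: CurrentWaveform
    v_source: np.ndarray  # source-capacitor voltage trace, V
    v_tissue: np.ndarray  # tissue-capacitor (Cp) voltage trace, V

    @property
    def times(self) -> np.ndarray:
        return self.waveform.times


def transient_oracle(
    model: ElectrodeTissueModel,
    settings: StimulationSettings,
    dt: float = 1e-7,
) -> TransientResult:
    """Numerically integrate the full two-capacitor stimulation circuit.

    State: source-capacitor voltage ``v_s`` and tissue-capacitor voltage
    ``v_p``.  During the negative phase the electrode sees the constant
    current ``-i_neg`` while ``Csource`` charges at ``i_pos`` for
    ``t_charge``; during the positive phase ``Csource`` discharges
    through ``Rs`` into ``Rp || Cp`` (``i = (v_s - v_p)/Rs``); during
    rest the electrode is open and ``Cp`` relaxes through ``Rp``.

    Classic fixed-step RK4.  ``dt`` larger than a fiftieth of the
    fastest relevant time constant is rejected as unstable.
    """
    if settings.mode is not StimulationMode.CAP_COUPLED:
        raise ValueError("the transient oracle models the cap_coupled circuit")
    r_s, r_p, c_p = model.r_s, model.r_p, model.c_p
    c_s = settings.c_source
    fastest = min(model.time_constant, c_s * (r_s + r_p))
    if dt > fastest / 50.0:
        raise ValueError(
            f"dt = {dt:g} s too coarse for stability; need dt <= {fastest / 50.0:g} s"
        )

    n = int(round(settings.period / dt))
    t_neg, t_pos, t_charge = settings.t_neg, settings.t_pos, settings.t_charge
    i_neg, i_pos = settings.i_neg, settings.i_pos

    NEG, DIS, REST = range(3)

    def phase_at(t: float) -> int:
        """Half-open phase windows: the boundary sample belongs to the new phase."""
        if t < t_neg:
            return NEG
        if t < t_neg + t_pos:
            return DIS
        return REST

    def deriv(phase: int, charging: bool, v_s: float, v_p: float):
        """(dv_s/dt, dv_p/dt, electrode current) for a fixed switch state."""
        if phase == NEG:  # cathodic current source, concurrent charging
            i = -i_neg
            dv_s = i_pos / c_s if charging else 0.0
        elif phase == DIS:  # source capacitor discharges through Rs into Rp || Cp
            i = (v_s - v_p) / r_s
            dv_s = -i / c_s
        else:  # rest: electrode open
            i = 0.0
            dv_s = 0.0
        dv_p = (i - v_p / r_p) / c_p
        return dv_s, dv_p, i

    v_s = v_p = 0.0
    current = np.empty(n + 1)
    vs_trace = np.empty(n + 1)
    vp_trace = np.empty(n + 1)
    for k in range(n + 1):
        t = k * dt
        current[k] = deriv(phase_at(t), t < t_charge, v_s, v_p)[2]
        vs_trace[k] = v_s
        vp_trace[k] = v_p
        if k == n:
            break
        # freeze the switch state over the step (sampled at the midpoint) so a
        # step never straddles a phase boundary with mixed derivatives
        tm = t + dt / 2
        phase, charging = phase_at(tm), tm < t_charge
        k1s, k1p, _ = deriv(phase, charging, v_s, v_p)
        k2s, k2p, _ = deriv(phase, charging, v_s + dt / 2 * k1s, v_p + dt / 2 * k1p)
        k3s, k3p, _ = deriv(phase, charging, v_s + dt / 2 * k2s, v_p + dt / 2 * k2p)
        k4s, k4p, _ = deriv(phase, charging, v_s + dt * k3s, v_p + dt * k3p)
        v_s += dt / 6 * (k1s + 2 * k2s + 2 * k3s + k4s)
        v_p += dt / 6 * (k1p + 2 * k2p + 2 * k3p + k4p)

    return TransientResult(
        waveform=CurrentWaveform(dt=dt, samples=current),
        v_source=vs_trace,
        v_tissue=vp_trace,
    )
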