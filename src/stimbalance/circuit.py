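"""Electrode-tissue equivalent circuit.

The electrode-tissue interface is modelled as a series electrode
resistance ``Rs`` feeding a parallel RC pair: the tissue resistance
``Rp`` and tissue capacitance ``Cp``.  The complex impedance of the
network at angular frequency ``w = 2*pi*f`` is

    Z(f) = Rs + Rp / (1 + (w*Rp*Cp)**2) - j * w*Rp**2*Cp / (1 + (w*Rp*Cp)**2)

so the magnitude rolls off from the low-frequency asymptote ``Rs + Rp``
to the high-frequency asymptote ``Rs``, with a single pole at the
cutoff frequency ``1 / (2*pi*Rp*Cp)``.  At the cutoff the real part is
exactly ``Rs + Rp/2`` while the measured magnitude (which includes the
imaginary component) is ``sqrt((Rp/2)**2 + (Rs + Rp/2)**2)`` — the gap
between the two is what the imaginary-component correction in
:mod:`stimbalance.aim` removes.

All public frequencies are plain Hz; the ``2*pi`` conversion is
internal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MEASURABLE_RESISTANCE_RANGE",
    "ElectrodeTissueModel",
    "capacitance_from_cutoff",
    "electrode_surface_area",
]

#: Resistance window (ohm) the measurement chain can resolve before the
#: current source runs out of compliance voltage.  Values outside this
#: window are physically fine for the model itself, so construction only
#: warns.
MEASURABLE_RESISTANCE_RANGE = (16.0, 66e3)


@dataclass(frozen=True)
class ElectrodeTissueModel:
    """Series electrode resistance feeding a parallel tissue RC pair.

    Parameters
    ----------
    r_s : float
        Electrode (series) resistance in ohm.  Grows as the electrode
        degrades.
    r_p : float
        Tissue (parallel) resistance in ohm.  Essentially constant for a
        given preparation.
    c_p : float
        Tissue capacitance in farad.
    """

    r_s: float
    r_p: float
    c_p: float

    def __post_init__(self) -> None:
        for name, value in (("r_s", self.r_s), ("r_p", self.r_p), ("c_p", self.c_p)):
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be a positive finite number, got {value!r}")
        lo, hi = MEASURABLE_RESISTANCE_RANGE
        for name, value in (("r_s", self.r_s), ("r_p", self.r_p)):
            if not lo <= value <= hi:
                warnings.warn(
                    f"{name} = {value:g} ohm is outside the measurable range "
                    f"[{lo:g}, {hi:g}] ohm; impedance monitoring of this "
                    "circuit would be unreliable on hardware",
                    UserWarning,
                    stacklevel=2,
                )

    # ------------------------------------------------------------------
    # derived quantities
    # ------------------------------------------------------------------
    def impedance(self, f):
        """Complex impedance (ohm) at frequency ``f`` (Hz, scalar or array)."""
        f_arr = np.asarray(f, dtype=float)
        if np.any(f_arr < 0):
            raise ValueError("frequency must be non-negative")
        w = 2.0 * math.pi * f_arr
        x = w * self.r_p * self.c_p
        denom = 1.0 + x * x
        z = self.r_s + self.r_p / denom - 1j * x * self.r_p / denom
        if np.isscalar(f) or f_arr.ndim == 0:
            return complex(z)
        return z

    @property
    def time_constant(self) -> float:
        """Discharge time constant ``Rs*Rp*Cp / (Rs + Rp)`` in seconds.

        This is the time constant governing the exponential decay of a
        capacitor-coupled positive phase through the electrode-tissue load.
        """
        return self.r_s * self.r_p * self.c_p / (self.r_s + self.r_p)

    @property
    def cutoff_frequency(self) -> float:
        """Pole frequency ``1 / (2*pi*Rp*Cp)`` in Hz."""
        return 1.0 / (2.0 * math.pi * self.r_p * self.c_p)

    @property
    def magnitude_at_cutoff(self) -> float:
        """|Z| at the cutoff frequency: ``sqrt((Rp/2)^2 + (Rs + Rp/2)^2)``.

        Strictly larger than the real part ``Rs + Rp/2`` because the
        imaginary component peaks (at ``Rp/2``) exactly at the pole.
        """
        half = self.r_p / 2.0
        return math.hypot(half, self.r_s + half)

    @property
    def asymptotes(self) -> tuple[float, float]:
        """(low-frequency, high-frequency) magnitude asymptotes ``(Rs+Rp, Rs)``."""
        return (self.r_s + self.r_p, self.r_s)


def capacitance_from_cutoff(r_p: float, f_cutoff: float) -> float:
    """Invert the pole relation: ``Cp = 1 / (2*pi*Rp*f_cutoff)``.

    This is how the tissue capacitance is recovered once the cutoff
    frequency has been located on a measured magnitude spectrum.
    """
    if r_p <= 0 or f_cutoff <= 0:
        raise ValueError("r_p and f_cutoff must be positive")
    return 1.0 / (2.0 * math.pi * r_p * f_cutoff)


def electrode_surface_area(n_strands: int, diameter_m: float, length_m: float) -> float:
    """Geometric (lateral cylinder) surface area of a stranded wire electrode, in m^2.

    ``n_strands * pi * diameter * exposed_length`` — e.g. four 100 um
    strands with 1 cm exposed tip give 1.2566e-5 m^2 (12.57 mm^2).
    """
    if n_strands < 1 or diameter_m <= 0 or length_m <= 0:
        raise ValueError("strand count, diameter and length must be positive")
    return n_strands * math.pi * diameter_m * length_m
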