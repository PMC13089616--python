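"""Active impedance monitoring: measurement-chain simulation and parameter extraction.

The monitoring unit drives the electrode with a small test current at
log-spaced frequencies (default 1 Hz - 10 kHz, 8 points per decade),
records the resulting voltage with a 14-bit ADC referenced to 3.3 V
(averaging 1000 samples per frequency), and divides by the test current
to obtain a magnitude spectrum |Z|(f).

From that spectrum the three circuit parameters are recovered:

1. asymptotes — the mean of the two highest-frequency points estimates
   ``Rs``; the mean of the two lowest-frequency points estimates
   ``Rs + Rp``;
2. cutoff — the three points whose magnitude is closest to the expected
   value at the pole are fitted with a least-squares line of magnitude
   against log10(f); the crossing of that line with the target locates
   ``f_cutoff``, and ``Cp = 1/(2*pi*Rp*f_cutoff)``;
3. correction — the measured magnitude contains the imaginary
   component, which peaks at ``Rp/2`` at the pole; it is removed in
   quadrature (``Zreal = sqrt(Z^2 - Im(Z; Rp, Cp)^2)``) using the
   current estimates, after which steps 1-2 are repeated on the
   corrected spectrum (pole target ``Rs + Rp/2``) until the estimates
   settle.

The correction needs ``Rp`` and ``Cp``, which are only known after an
extraction — hence the fixed-point iteration in :class:`ImpedanceFit`.
The first pass works on the raw magnitudes with the magnitude-at-cutoff
target; every later pass works on the corrected spectrum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .circuit import ElectrodeTissueModel, capacitance_from_cutoff
from .waveform import quantize_current

__all__ = [
    "MeasurementConfig",
    "ImpedanceSpectrum",
    "ExtractionResult",
    "ExtractionError",
    "ComplianceError",
    "ImpedanceFit",
    "frequency_grid",
    "model_spectrum",
    "synthesize_measurement",
    "compliance_check",
    "correct_imaginary",
    "estimate_cutoff",
    "extract_parameters",
]


class ComplianceError(RuntimeError):
    """Predicted measurement voltage exceeds the supply rail (LED condition)."""


class ExtractionError(RuntimeError):
    """Parameter extraction failed (e.g. no pole present in the spectrum)."""


@dataclass(frozen=True)
class MeasurementConfig:
    """Settings of the impedance measurement chain.

    ``noise_sd`` is the per-ADC-sample Gaussian voltage noise; the
    default of one ADC step (v_ref / 2**adc_bits) reflects a chain whose
    noise floor sits at the quantizer resolution.  ``adc_bits = None``
    disables quantization (ideal ADC).
    """

    f_min: float = 1.0
    f_max: float = 10_000.0
    points_per_decade: int = 8
    i_stim: float = 0.1e-3
    adc_bits: int | None = 14
    v_ref: float = 3.3
    n_samples: int = 1000
    noise_sd: float | None = None  # None -> one ADC step
    bias_ohm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.f_min < self.f_max:
            raise ValueError("need 0 < f_min < f_max")
        if self.points_per_decade < 3:
            raise ValueError("points_per_decade must be at least 3")
        if self.n_samples < 1:
            raise ValueError("n_samples must be at least 1")
        if self.v_ref <= 0:
            raise ValueError("v_ref must be positive")
        object.__setattr__(self, "i_stim", quantize_current(self.i_stim))
        if self.i_stim <= 0:
            raise ValueError("i_stim must quantize to a positive current")

    @property
    def adc_step(self) -> float:
        """ADC resolution in volts (0 for an ideal ADC)."""
        if self.adc_bits is None:
            return 0.0
        return self.v_ref / 2**self.adc_bits

    @property
    def effective_noise_sd(self) -> float:
        return self.adc_step if self.noise_sd is None else self.noise_sd


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Magnitude spectrum |Z|(f): strictly increasing frequencies, positive ohms.

    ``kind`` records provenance: ``model`` (analytic), ``raw`` (simulated
    or loaded measurement) or ``corrected`` (imaginary component removed).
    """

    frequencies: np.ndarray
    magnitudes: np.ndarray
    kind: str = "raw"

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        z = np.asarray(self.magnitudes, dtype=float)
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "magnitudes", z)
        if self.kind not in ("raw", "corrected", "model"):
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if f.ndim != 1 or f.shape != z.shape:
            raise ValueError("frequencies and magnitudes must be 1-D and equal length")
        if f.size < 2:
            raise ValueError("a spectrum needs at least two points")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(z <= 0) or not np.all(np.isfinite(z)):
            raise ValueError("magnitudes must be positive and finite")

    def __len__(self) -> int:
        return self.frequencies.size


def frequency_grid(config: MeasurementConfig) -> np.ndarray:
    """Log-spaced grid 10**(k + i/ppd) from f_min through f_max inclusive.

    With the defaults (1 Hz - 10 kHz, 8 per decade) this is 33 points;
    f_max is appended if the log-spaced ladder does not land on it.
    """
    e0 = math.log10(config.f_min)
    e1 = math.log10(config.f_max)
    n_steps = int(math.floor((e1 - e0) * config.points_per_decade + 1e-9))
    exps = e0 + np.arange(n_steps + 1) / config.points_per_decade
    grid = 10.0**exps
    if grid[-1] < config.f_max * (1 - 1e-9):
        grid = np.append(grid, config.f_max)
    return grid


def model_spectrum(model: ElectrodeTissueModel, config: MeasurementConfig) -> ImpedanceSpectrum:
    """Noise-free analytic magnitude spectrum of ``model`` on the config grid."""
    f = frequency_grid(config)
    return ImpedanceSpectrum(f, np.abs(model.impedance(f)), kind="model")


def compliance_check(model: ElectrodeTissueModel, config: MeasurementConfig) -> bool:
    """True (indicator LED on) when the DC voltage ``(Rs+Rp)*i_stim`` exceeds v_ref."""
    return (model.r_s + model.r_p) * config.i_stim > config.v_ref


def synthesize_measurement(
    model: ElectrodeTissueModel, config: MeasurementConfig
) -> ImpedanceSpectrum:
    """Simulate one AIM sweep: test current, voltage noise, ADC, back to ohms.

    Per grid frequency the ideal reading is ``|Z(f)| * i_stim`` volts.
    Gaussian noise (sd ``noise_sd``) is averaged over ``n_samples``
    draws, the average is quantized by the ADC over [0, v_ref], divided
    by the test current and offset by ``bias_ohm``.
    """
    if compliance_check(model, config):
        raise ComplianceError(
            "measurement voltage would exceed the supply rail; "
            "reduce i_stim or the electrode impedance"
        )
    f = frequency_grid(config)
    v_ideal = np.abs(model.impedance(f)) * config.i_stim
    if np.any(v_ideal > config.v_ref):
        raise ComplianceError("measurement voltage would exceed the supply rail")

    rng = np.random.default_rng(config.seed)
    sd = config.effective_noise_sd
    if sd > 0:
        noise = rng.normal(0.0, sd, size=(f.size, config.n_samples)).mean(axis=1)
    else:
        noise = 0.0
    v = np.clip(v_ideal + noise, 0.0, config.v_ref)
    step = config.adc_step
    if step > 0:
        v = np.round(v / step) * step
    z = v / config.i_stim + config.bias_ohm
    return ImpedanceSpectrum(f, z, kind="raw")


def _modelled_imaginary(f: np.ndarray, r_p: float, c_p: float) -> np.ndarray:
    x = 2.0 * math.pi * f * r_p * c_p
    return x * r_p / (1.0 + x * x)


def correct_imaginary(
    spectrum: ImpedanceSpectrum, r_p_hat: float, c_p_hat: float
) -> ImpedanceSpectrum:
    """Remove the modelled imaginary component in quadrature.

    ``Zreal = sqrt(max(0, |Z|^2 - Im^2))`` with ``Im`` evaluated from the
    current (Rp, Cp) estimates.  The clamp guards noisy points whose
    magnitude dips below the modelled imaginary part.
    """
    if spectrum.kind != "raw":
        raise ValueError("correction applies to raw spectra")
    if r_p_hat <= 0 or c_p_hat <= 0:
        raise ValueError("estimates must be positive")
    im = _modelled_imaginary(spectrum.frequencies, r_p_hat, c_p_hat)
    corrected = np.sqrt(np.maximum(0.0, spectrum.magnitudes**2 - im**2))
    # keep magnitudes strictly positive for the container invariant
    corrected = np.maximum(corrected, np.finfo(float).tiny)
    return ImpedanceSpectrum(spectrum.frequencies, corrected, kind="corrected")


def estimate_cutoff(spectrum: ImpedanceSpectrum, z_target: float) -> float:
    """Locate the pole: regress the 3 points nearest ``z_target`` on log10(f).

    A least-squares line of magnitude against log10(frequency) through
    the three points whose magnitude is closest to the target; the
    returned frequency is where the line crosses the target.  A
    degenerate (flat) line falls back to the nearest point's frequency
    with a warning.
    """
    if len(spectrum) < 3:
        raise ValueError("need at least 3 points to locate the cutoff")
    dist = np.abs(spectrum.magnitudes - z_target)
    idx = np.argsort(dist, kind="stable")[:3]
    x = np.log10(spectrum.frequencies[idx])
    y = spectrum.magnitudes[idx]
    slope, intercept = np.polyfit(x, y, 1)
    y_span = max(y.max() - y.min(), abs(z_target), 1.0)
    if abs(slope) < 1e-12 * y_span:
        warnings.warn(
            "degenerate (flat) regression line; falling back to nearest point",
            UserWarning,
            stacklevel=2,
        )
        return float(spectrum.frequencies[idx[0]])
    return float(10.0 ** ((z_target - intercept) / slope))


@dataclass(frozen=True)
class ExtractionResult:
    """Fitted electrode-tissue parameters and fit diagnostics."""

    r_s_hat: float
    r_p_hat: float
    c_p_hat: float
    f_cutoff_hat: float
    n_iterations: int
    converged: bool

    def as_model(self) -> ElectrodeTissueModel:
        """The fitted equivalent circuit (warnings suppressed for edge fits)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return ElectrodeTissueModel(self.r_s_hat, self.r_p_hat, self.c_p_hat)

    def to_dict(self) -> dict:
        return {
            "r_s_hat": self.r_s_hat,
            "r_p_hat": self.r_p_hat,
            "c_p_hat": self.c_p_hat,
            "f_cutoff_hat": self.f_cutoff_hat,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
        }

    def summary(self) -> str:
        lines = [
            "Electrode-tissue impedance fit",
            "==============================",
            f"  Rs (electrode)   {self.r_s_hat:12.2f} ohm",
            f"  Rp (tissue)      {self.r_p_hat:12.2f} ohm",
            f"  Cp (tissue)      {self.c_p_hat * 1e6:12.3f} uF",
            f"  f_cutoff         {self.f_cutoff_hat:12.2f} Hz",
            f"  iterations       {self.n_iterations:12d}",
            f"  converged        {str(self.converged):>12s}",
        ]
        return "\n".join(lines)


class ImpedanceFit:
    """Fit the series-RC || C electrode-tissue model to a magnitude spectrum.

    Parameters
    ----------
    spectrum : ImpedanceSpectrum
        A raw (measured or simulated) magnitude spectrum covering at
        least two decades.
    config : MeasurementConfig, optional
        Only used for validation context; the fit itself is driven by
        the spectrum.

    Examples
    --------
    >>> res = ImpedanceFit(spectrum).fit()          # doctest: +SKIP
    >>> print(res.summary())                        # doctest: +SKIP
    """

    #: relative change below which the fixed point is declared converged
    tol = 1e-3
    max_iter = 10

    def __init__(self, spectrum: ImpedanceSpectrum, config: MeasurementConfig | None = None):
        if math.log10(spectrum.frequencies[-1] / spectrum.frequencies[0]) < 2 - 1e-9:
            raise ValueError("spectrum must cover at least two decades")
        self.spectrum = spectrum
        self.config = config

    @staticmethod
    def _asymptotes(z: np.ndarray) -> tuple[float, float]:
        """(Rs, Rp) from the means of the two extreme grid points."""
        r_s = float(np.mean(z[-2:]))
        r_p = float(np.mean(z[:2])) - r_s
        return r_s, r_p

    def fit(self) -> ExtractionResult:
        raw = self.spectrum
        r_s, r_p = self._asymptotes(raw.magnitudes)
        self._check_positive(r_s, r_p, stage="asymptote initialisation")

        # first pass: no Cp yet, so locate the pole on the raw magnitudes
        # using the magnitude-at-cutoff target (imaginary component included)
        z_target = math.hypot(r_p / 2.0, r_s + r_p / 2.0)
        f_cutoff = estimate_cutoff(raw, z_target)
        self._check_positive(f_cutoff, stage="cutoff regression")
        c_p = capacitance_from_cutoff(r_p, f_cutoff)

        converged = False
        n_iter = 1
        for n_iter in range(2, self.max_iter + 1):
            corrected = correct_imaginary(raw, r_p, c_p)
            r_s_new, r_p_new = self._asymptotes(corrected.magnitudes)
            self._check_positive(r_s_new, r_p_new, stage=f"iteration {n_iter}")
            f_cutoff = estimate_cutoff(corrected, r_s_new + r_p_new / 2.0)
            self._check_positive(f_cutoff, stage=f"iteration {n_iter} cutoff")
            c_p_new = capacitance_from_cutoff(r_p_new, f_cutoff)
            changes = (
                abs(r_s_new - r_s) / r_s,
                abs(r_p_new - r_p) / r_p,
                abs(c_p_new - c_p) / c_p,
            )
            r_s, r_p, c_p = r_s_new, r_p_new, c_p_new
            if max(changes) < self.tol:
                converged = True
                break

        return ExtractionResult(
            r_s_hat=r_s,
            r_p_hat=r_p,
            c_p_hat=c_p,
            f_cutoff_hat=f_cutoff,
            n_iterations=n_iter,
            converged=converged,
        )

    @staticmethod
    def _check_positive(*values: float, stage: str) -> None:
        if any(not (math.isfinite(v) and v > 0) for v in values):
            raise ExtractionError(
                f"non-positive intermediate estimate during {stage}: {values}; "
                "the spectrum may lack a resolvable pole (e.g. purely resistive load)"
            )


def extract_parameters(
    spectrum: ImpedanceSpectrum, config: MeasurementConfig | None = None
) -> ExtractionResult:
    """Functional wrapper around :class:`ImpedanceFit`."""
    return ImpedanceFit(spectrum, config).fit()
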