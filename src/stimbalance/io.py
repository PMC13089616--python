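"""File formats and run configuration.

All files use SI base units (A, s, F, ohm, Hz).  Spectra travel as CSV
with header ``frequency_hz,magnitude_ohm``; waveforms as
``time_s,current_a``; closed-loop traces as
``time_h,r_s_ohm,residual_pct,rebalanced,led_on``.  Run configurations
are JSON whose field names mirror the dataclasses one-to-one; unknown
keys are rejected by name.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .aim import ImpedanceSpectrum, MeasurementConfig
from .circuit import ElectrodeTissueModel
from .loop import DegradationParams
from .waveform import CurrentWaveform, StimulationSettings

__all__ = [
    "SPECTRUM_HEADER",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "write_waveform_csv",
    "RunConfig",
    "from_dict",
    "load_run_config",
]

SPECTRUM_HEADER = ["frequency_hz", "magnitude_ohm"]


class SpectrumParseError(ValueError):
    """Malformed spectrum CSV; message carries the offending line number."""


def read_spectrum_csv(path: str | Path, kind: str = "raw") -> ImpedanceSpectrum:
    """Read and validate a ``frequency_hz,magnitude_ohm`` CSV.

    Rows are sorted by frequency (with a warning if the file was
    unsorted); malformed rows and non-positive values raise with the
    1-based line number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise SpectrumParseError(f"{path}: empty file") from None
    if list(df.columns) != SPECTRUM_HEADER:
        raise SpectrumParseError(
            f"{path}, line 1: expected header {','.join(SPECTRUM_HEADER)!r}, "
            f"got {','.join(map(str, df.columns))!r}"
        )
    for col in SPECTRUM_HEADER:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise SpectrumParseError(f"{path}, line {line}: non-numeric value in {col}")
        nonpos = values <= 0
        if nonpos.any():
            line = int(nonpos.idxmax()) + 2
            raise SpectrumParseError(f"{path}, line {line}: {col} must be positive")
        df[col] = values
    f = df[SPECTRUM_HEADER[0]].to_numpy(float)
    z = df[SPECTRUM_HEADER[1]].to_numpy(float)
    if np.any(np.diff(f) < 0):
        warnings.warn(f"{path}: rows were not sorted by frequency; sorting", UserWarning)
        order = np.argsort(f, kind="stable")
        f, z = f[order], z[order]
    return ImpedanceSpectrum(f, z, kind=kind)


def write_spectrum_csv(spectrum: ImpedanceSpectrum, path: str | Path) -> None:
    # default (shortest round-trip) float formatting keeps read(write(s)) bit-exact
    pd.DataFrame(
        {SPECTRUM_HEADER[0]: spectrum.frequencies, SPECTRUM_HEADER[1]: spectrum.magnitudes}
    ).to_csv(path, index=False)


def write_waveform_csv(waveform: CurrentWaveform, path: str | Path) -> None:
    pd.DataFrame({"time_s": waveform.times, "current_a": waveform.samples}).to_csv(
        path, index=False, float_format="%.9g"
    )


def from_dict(cls, data: dict):
    """Build a dataclass from a plain dict, rejecting unknown keys by name."""
    if not isinstance(data, dict):
        raise ValueError(f"expected an object for {cls.__name__}, got {type(data).__name__}")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) for {cls.__name__}: {', '.join(sorted(unknown))}"
        )
    return cls(**data)


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration of a closed-loop run."""

    model: ElectrodeTissueModel
    settings: StimulationSettings
    duration_h: float
    rebalance: bool
    seed: int
    pulse_rate_hz: float = 1000.0
    measurement: MeasurementConfig | None = None
    degradation: DegradationParams | None = None


_SECTION_TYPES = {
    "model": ElectrodeTissueModel,
    "settings": StimulationSettings,
    "measurement": MeasurementConfig,
    "degradation": DegradationParams,
}


def load_run_config(path: str | Path) -> RunConfig:
    """Load a closed-loop run configuration from JSON, validating all sections."""
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise ValueError("run config must be a JSON object")
    scalar_keys = {"duration_h", "rebalance", "seed", "pulse_rate_hz"}
    unknown = set(raw) - scalar_keys - set(_SECTION_TYPES)
    if unknown:
        raise ValueError(f"unknown key(s) in run config: {', '.join(sorted(unknown))}")
    for required in ("model", "settings", "duration_h", "rebalance", "seed"):
        if required not in raw:
            raise ValueError(f"run config is missing required key: {required}")
    sections = {
        name: from_dict(cls, raw[name]) if name in raw else None
        for name, cls in _SECTION_TYPES.items()
    }
    return RunConfig(
        model=sections["model"],
        settings=sections["settings"],
        duration_h=float(raw["duration_h"]),
        rebalance=bool(raw["rebalance"]),
        seed=int(raw["seed"]),
        pulse_rate_hz=float(raw.get("pulse_rate_hz", 1000.0)),
        measurement=sections["measurement"],
        degradation=sections["degradation"],
    )
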