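"""Photodiode detectability under skin-safe illumination.

Converts simulated detected fractions to absolute watts at the maximum
permissible exposure (MPE) and compares them with the photodiode's minimum
detectable power

    P_min(lambda) = NEP * sqrt(BW) * S(lambda)/Smax,

with the relative sensitivity as a multiplier.  Because that convention
makes a *less* sensitive wavelength look easier to detect, a ``physical``
switch is provided that divides by S/Smax instead; the default keeps the
multiplicative convention.  All operations in this module are
deterministic and exactly linear.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, BandRangeError, InvalidParameterError

__all__ = ["PhotodiodeSpec", "ExposureSpec", "mpe_source_power",
           "min_detectable_power", "readout_to_watts", "detectability_margin",
           "synthetic_photodiode"]


@dataclass(frozen=True)
class PhotodiodeSpec:
    """NEP in W/sqrt(Hz), bandwidth in Hz, and a relative sensitivity curve
    S(lambda)/Smax on (0, 1] with peak value 1."""

    nep: float
    bandwidth: float
    sensitivity_wavelengths: np.ndarray
    sensitivity_values: np.ndarray

    def __post_init__(self) -> None:
        if self.nep <= 0 or self.bandwidth <= 0:
            raise InvalidParameterError("NEP and bandwidth must be > 0")
        s = np.asarray(self.sensitivity_values, dtype=float)
        if np.any(s <= 0) or not np.isclose(s.max(), 1.0):
            raise InvalidParameterError(
                "sensitivity curve must be positive with peak 1")

    def relative_sensitivity(self, wavelength_nm: float) -> float:
        w = np.asarray(self.sensitivity_wavelengths, dtype=float)
        if not w[0] <= wavelength_nm <= w[-1]:
            raise BandRangeError(
                f"{wavelength_nm} nm outside sensitivity curve "
                f"({w[0]}-{w[-1]} nm)")
        return float(np.interp(wavelength_nm, w, self.sensitivity_values))


@dataclass(frozen=True)
class ExposureSpec:
    """Skin-exposure limit (W/m^2) and illuminated source area (cm^2)."""

    irradiance_limit: float = 2000.0
    source_area: float = 0.16

    def __post_init__(self) -> None:
        if self.irradiance_limit <= 0 or self.source_area < 0:
            raise InvalidParameterError("exposure spec values must be positive")


def synthetic_photodiode(nep: float = 5e-14, bandwidth: float = 16.0
                         ) -> PhotodiodeSpec:
    """Broad-response silicon-photodiode stand-in (peak near 850 nm).

    The real SFH 2704 curve is not tabulated in public text form; this
    synthetic fixture mimics a wide sensing window and is replaceable by a
    measured two-column curve."""
    wl = np.arange(400.0, 1101.0, 10.0)
    s = np.exp(-0.5 * ((wl - 850.0) / 220.0) ** 2)
    return PhotodiodeSpec(nep=nep, bandwidth=bandwidth,
                          sensitivity_wavelengths=wl,
                          sensitivity_values=s / s.max())


def mpe_source_power(exposure: ExposureSpec) -> float:
    """Source power (W) at the exposure limit: irradiance x area."""
    return exposure.irradiance_limit * exposure.source_area * 1e-4


def min_detectable_power(pd: PhotodiodeSpec, wavelength_nm: float) -> float:
    """P_min = NEP * sqrt(BW) * S/Smax (multiplicative convention), W."""
    s = pd.relative_sensitivity(wavelength_nm)
    return pd.nep * math.sqrt(pd.bandwidth) * s


def min_detectable_power_physical(pd: PhotodiodeSpec,
                                  wavelength_nm: float) -> float:
    """Variant dividing by S/Smax (lower sensitivity -> higher P_min)."""
    s = pd.relative_sensitivity(wavelength_nm)
    return pd.nep * math.sqrt(pd.bandwidth) / s


def readout_to_watts(readout, source_power: float) -> np.ndarray:
    """Per-bin detected power (W): detected fraction x source power."""
    if source_power < 0:
        raise InvalidParameterError("source power must be >= 0")
    frac = getattr(readout, "spectrum", None)
    if frac is None:
        frac = readout.detected_fraction
    return np.asarray(frac, dtype=float) * source_power


def detectability_margin(wavelengths, power_w, pd: PhotodiodeSpec,
                         physical: bool = False) -> np.ndarray:
    """Per-bin margin power/P_min; margin > 1 means detectable there."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    power_w = np.asarray(power_w, dtype=float)
    if wavelengths.shape != power_w.shape:
        raise AlignmentError("wavelength and power grids must align")
    fn = min_detectable_power_physical if physical else min_detectable_power
    pmin = np.array([fn(pd, w) for w in wavelengths])
    return power_w / pmin
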