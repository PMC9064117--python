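"""Wavelength-resolved optical properties of skin layers, implant domains and dyes.

Skin-layer absorption is built from a chromophore mixture (whole blood split
into oxy/deoxy hemoglobin, water, melanosomes, fat, plus a generic "skin
baseline" assigned to the residual volume fraction) in the style of the
Jacques skin-optics parameterization used by the mcxyz/MCmatlab family.
Reduced scattering follows the power law mus'(lambda) = a * (lambda/500)**-b
with per-layer (a, b); mus = mus'/(1-g) with g = 0.90 everywhere and all
refractive indices matched at 1.40.

The chromophore tables below are compact approximations of the standard
compilations (hemoglobin molar extinction after Prahl; water after
Hale-Querry/Pope-Fry; fat after van Veen) sampled at 10 nm over 440-920 nm
and linearly interpolated.  They are deliberately overridable: any medium
can be replaced by a table loaded from a delimited property file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import BandRangeError, InvalidParameterError

__all__ = [
    "OpticalProperties",
    "MediumSpec",
    "LuminophoreSpec",
    "ImplantMedium",
    "ConstantMedium",
    "absorption_from_extinction",
    "skin_layer_properties",
    "skin_medium",
    "implant_domain_properties",
    "implant_medium",
    "default_tissue_media",
    "fluorophore",
    "FLUOROPHORES",
    "CHROMOPHORE_BAND",
]

# --------------------------------------------------------------------------
# chromophore data (440-920 nm, 10 nm steps)
# --------------------------------------------------------------------------

_WL = np.arange(440.0, 921.0, 10.0)

# molar extinction, 1/(M*cm)
_EPS_HBO2 = np.array([
    80700., 62816., 33209., 20932., 14550., 13560., 20862., 26650.,
    30880., 39956., 53236., 43016., 32613., 44600., 47000., 14000.,
    3200., 1506., 942., 610., 442., 368., 320., 294.,
    276., 276., 290., 314., 348., 390., 446., 518.,
    586., 650., 710., 767., 816., 864., 916., 966.,
    1022., 1058., 1092., 1128., 1154., 1178., 1198., 1216., 1232.,
])
_EPS_HB = np.array([
    353160., 103292., 23388., 16156., 14550., 15500., 20932., 23700.,
    27000., 35000., 44480., 52000., 53412., 47000., 37020., 23500.,
    14677., 9443., 6510., 5149., 4345., 3750., 3227., 2795.,
    2407., 2051., 1794., 1580., 1360., 1150., 1130., 1405.,
    1548., 1311., 1070., 900., 762., 740., 720., 710.,
    693., 691., 694., 700., 710., 722., 737., 752., 766.,
])
# absorption coefficient of pure water / pure fat, 1/cm
_MUA_WATER = np.array([
    6.4e-5, 9.2e-5, 1.1e-4, 1.4e-4, 1.6e-4, 2.0e-4, 2.5e-4, 3.6e-4,
    4.8e-4, 5.9e-4, 7.0e-4, 5.7e-4, 6.2e-4, 7.4e-4, 9.1e-4, 1.4e-3,
    2.22e-3, 2.76e-3, 3.1e-3, 3.4e-3, 3.7e-3, 3.75e-3, 3.8e-3, 4.2e-3,
    4.65e-3, 5.2e-3, 6.0e-3, 7.5e-3, 1.04e-2, 1.6e-2, 2.4e-2, 2.6e-2,
    2.55e-2, 2.4e-2, 2.26e-2, 2.13e-2, 2.04e-2, 2.2e-2, 2.46e-2, 2.9e-2,
    3.40e-2, 4.3e-2, 4.9e-2, 5.5e-2, 6.0e-2, 6.4e-2, 6.79e-2, 8.5e-2, 1.09e-1,
])
_MUA_FAT = np.array([
    1.3e-2, 1.15e-2, 1.0e-2, 8.7e-3, 7.5e-3, 6.6e-3, 5.8e-3, 5.1e-3,
    4.5e-3, 4.2e-3, 4.0e-3, 3.6e-3, 3.2e-3, 3.0e-3, 2.8e-3, 2.5e-3,
    2.2e-3, 2.0e-3, 1.8e-3, 1.6e-3, 1.4e-3, 1.2e-3, 1.1e-3, 1.05e-3,
    1.0e-3, 1.0e-3, 1.0e-3, 1.1e-3, 1.2e-3, 1.4e-3, 1.6e-3, 1.8e-3,
    1.9e-3, 2.0e-3, 2.0e-3, 2.05e-3, 2.1e-3, 2.3e-3, 2.6e-3, 3.0e-3,
    3.8e-3, 4.4e-3, 5.0e-3, 5.8e-3, 6.8e-3, 7.6e-3, 8.5e-3, 1.2e-2, 1.7e-2,
])

CHROMOPHORE_BAND = (float(_WL[0]), float(_WL[-1]))

#: hemoglobin content of whole blood, g/L, and its molar mass, g/mol
_HB_GPL = 150.0
_HB_MW = 64500.0


def _interp_band(wl: float, values: np.ndarray) -> float:
    lo, hi = CHROMOPHORE_BAND
    if not (lo <= wl <= hi):
        raise BandRangeError(
            f"wavelength {wl} nm outside tabulated chromophore band {lo}-{hi} nm"
        )
    return float(np.interp(wl, _WL, values))


def blood_mu_a(wavelength_nm: float, oxygen_saturation: float) -> float:
    """Absorption coefficient (1/cm) of whole blood at the given SO2."""
    eps = (oxygen_saturation * _interp_band(wavelength_nm, _EPS_HBO2)
           + (1.0 - oxygen_saturation) * _interp_band(wavelength_nm, _EPS_HB))
    return absorption_from_extinction(eps, _HB_GPL / _HB_MW)


def melanosome_mu_a(wavelength_nm: float) -> float:
    """Interior absorption coefficient (1/cm) of a cutaneous melanosome."""
    return 519.0 * (wavelength_nm / 500.0) ** (-3.5)


def skin_baseline_mu_a(wavelength_nm: float) -> float:
    """Generic bloodless, melanin-free skin baseline absorption (1/cm)."""
    return 0.244 + 85.3 * np.exp(-(wavelength_nm - 154.0) / 66.2)


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties at one wavelength.

    mu_a, mu_s in 1/cm; g dimensionless in [-1, 1]; refractive index n >= 1.
    """

    mu_a: float
    mu_s: float
    g: float
    n: float

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s < 0:
            raise InvalidParameterError("mu_a and mu_s must be nonnegative")
        if not -1.0 <= self.g <= 1.0:
            raise InvalidParameterError("anisotropy g must lie in [-1, 1]")
        if self.n < 1.0:
            raise InvalidParameterError("refractive index must be >= 1")


@dataclass(frozen=True)
class LuminophoreSpec:
    """Luminescence parameters of a dye or endogenous fluorophore.

    ``emission_wavelengths``/``emission_values`` hold the peak-normalized
    emission curve Em(lambda).  ``mode`` is 'singlet' (fluorescence) or
    'triplet' (phosphorescence); triplet species additionally carry a
    Stern-Volmer constant (1/uM) and natural lifetime tau0 (us).
    """

    quantum_yield: float
    emission_wavelengths: np.ndarray
    emission_values: np.ndarray
    mode: str = "singlet"
    ksv: float | None = None
    tau0: float | None = None
    extinction: float | None = None
    concentration: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.quantum_yield <= 1.0:
            raise InvalidParameterError("quantum yield must lie in [0, 1]")
        em = np.asarray(self.emission_values, dtype=float)
        if em.size == 0 or np.any(em < 0):
            raise InvalidParameterError("emission spectrum must be nonnegative")
        if not np.isclose(em.max(), 1.0):
            raise InvalidParameterError("emission spectrum must be peak-normalized")
        if self.mode not in ("singlet", "triplet"):
            raise InvalidParameterError("mode must be 'singlet' or 'triplet'")
        if self.mode == "triplet":
            if self.ksv is None or self.ksv < 0:
                raise InvalidParameterError("triplet mode requires ksv >= 0")
            if self.tau0 is None or self.tau0 <= 0:
                raise InvalidParameterError("triplet mode requires tau0 > 0")

    def emission_on(self, wavelengths: np.ndarray) -> np.ndarray:
        """Emission curve sampled at the given wavelengths (no extrapolation)."""
        w = np.asarray(wavelengths, dtype=float)
        return np.interp(w, self.emission_wavelengths, self.emission_values,
                         left=0.0, right=0.0)


class MediumSpec:
    """A named medium with a tabulated wavelength -> properties map.

    Queries outside the tabulated band raise :class:`BandRangeError` (the
    table is never extrapolated).  Tables round-trip bit-identically through
    :meth:`to_file`/:meth:`from_file`.
    """

    def __init__(self, name: str, wavelengths: np.ndarray, mu_a: np.ndarray,
                 mu_s: np.ndarray, g: np.ndarray, n: np.ndarray,
                 luminescence: LuminophoreSpec | None = None) -> None:
        self.name = name
        self.wavelengths = np.asarray(wavelengths, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.size < 2:
            raise InvalidParameterError("need at least two tabulated wavelengths")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise InvalidParameterError("wavelengths must be strictly increasing")
        self.mu_a = np.asarray(mu_a, dtype=float)
        self.mu_s = np.asarray(mu_s, dtype=float)
        self.g = np.asarray(g, dtype=float)
        self.n = np.asarray(n, dtype=float)
        for arr in (self.mu_a, self.mu_s, self.g, self.n):
            if arr.shape != self.wavelengths.shape:
                raise InvalidParameterError("property columns must match wavelengths")
        self.luminescence = luminescence

    @property
    def band(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def at(self, wavelength_nm: float) -> OpticalProperties:
        lo, hi = self.band
        if not (lo <= wavelength_nm <= hi):
            raise BandRangeError(
                f"{self.name}: {wavelength_nm} nm outside tabulated band {lo}-{hi} nm"
            )
        w = self.wavelengths
        return OpticalProperties(
            mu_a=float(np.interp(wavelength_nm, w, self.mu_a)),
            mu_s=float(np.interp(wavelength_nm, w, self.mu_s)),
            g=float(np.interp(wavelength_nm, w, self.g)),
            n=float(np.interp(wavelength_nm, w, self.n)),
        )

    @classmethod
    def from_function(cls, name: str,
                      fn: Callable[[float], OpticalProperties],
                      band: tuple[float, float], step: float = 2.0,
                      luminescence: LuminophoreSpec | None = None) -> "MediumSpec":
        wl = np.arange(band[0], band[1] + 0.5 * step, step)
        props = [fn(float(w)) for w in wl]
        return cls(name, wl,
                   np.array([p.mu_a for p in props]),
                   np.array([p.mu_s for p in props]),
                   np.array([p.g for p in props]),
                   np.array([p.n for p in props]),
                   luminescence=luminescence)

    # -- delimited property files: wavelength_nm, mu_a_percm, mu_s_percm, g, n
    def to_file(self, path) -> None:
        data = np.column_stack([self.wavelengths, self.mu_a, self.mu_s,
                                self.g, self.n])
        header = "wavelength_nm\tmu_a_percm\tmu_s_percm\tg\tn"
        np.savetxt(path, data, delimiter="\t", header=header, fmt="%.17g")

    @classmethod
    def from_file(cls, path, name: str | None = None) -> "MediumSpec":
        data = np.loadtxt(path, delimiter="\t")
        if data.ndim != 2 or data.shape[1] != 5:
            raise InvalidParameterError(f"{path}: expected 5 columns")
        import os
        nm = name or os.path.splitext(os.path.basename(str(path)))[0]
        return cls(nm, data[:, 0], data[:, 1], data[:, 2], data[:, 3], data[:, 4])


class ImplantMedium:
    """Implant assay domain: absorbing at its excitation wavelength, clear
    elsewhere, and non-scattering (the dye absorption dominates scattering
    by orders of magnitude).  Index-matched to tissue."""

    def __init__(self, name: str, mu_a_excitation: float, excitation_nm: float,
                 mu_a_emission: float = 0.0, window_nm: float = 2.0,
                 n: float = 1.40,
                 luminescence: LuminophoreSpec | None = None) -> None:
        if mu_a_excitation < 0 or mu_a_emission < 0:
            raise InvalidParameterError("absorption coefficients must be >= 0")
        self.name = name
        self.mu_a_excitation = mu_a_excitation
        self.excitation_nm = excitation_nm
        self.mu_a_emission = mu_a_emission
        self.window_nm = window_nm
        self.n = n
        self.luminescence = luminescence

    def at(self, wavelength_nm: float) -> OpticalProperties:
        inside = abs(wavelength_nm - self.excitation_nm) <= self.window_nm
        mu_a = self.mu_a_excitation if inside else self.mu_a_emission
        return OpticalProperties(mu_a=mu_a, mu_s=0.0, g=0.0, n=self.n)


class ConstantMedium:
    """Wavelength-independent medium (baseline validation media)."""

    def __init__(self, name: str, mu_a: float, mu_s: float, g: float = 0.9,
                 n: float = 1.40,
                 luminescence: LuminophoreSpec | None = None) -> None:
        self.name = name
        self._props = OpticalProperties(mu_a=mu_a, mu_s=mu_s, g=g, n=n)
        self.luminescence = luminescence

    def at(self, wavelength_nm: float) -> OpticalProperties:
        return self._props


# --------------------------------------------------------------------------
# skin layer parameterization
# --------------------------------------------------------------------------

#: per-layer chromophore volume fractions and mus' power-law coefficients
LAYER_DEFAULTS: dict[str, dict[str, float]] = {
    "epidermis": dict(B=0.0, S=0.75, W=0.75, F=0.0, a=46.0, b=1.421),
    "dermis": dict(B=0.002, S=0.67, W=0.65, F=0.0, a=46.0, b=1.421),
    "subcutis": dict(B=0.005, S=0.75, W=0.05, F=0.70, a=19.0, b=0.68),
}

#: epidermal absorption is reduced to 1/10 of the composite value (applied
#: to the full melanin+baseline mixture, including during melanosome sweeps)
EPIDERMAL_MU_A_FACTOR = 0.1

ANISOTROPY = 0.90
TISSUE_N = 1.40


def absorption_from_extinction(epsilon: float, concentration: float) -> float:
    """mu_a = 2.303 * epsilon * [C]  (epsilon in 1/(M*cm), [C] in M)."""
    if epsilon < 0 or concentration < 0:
        raise InvalidParameterError("extinction and concentration must be >= 0")
    return 2.303 * epsilon * concentration


def skin_layer_properties(layer: str, wavelength_nm: float,
                          melanosome_fraction: float = 0.03,
                          overrides: dict[str, float] | None = None
                          ) -> OpticalProperties:
    """Optical properties of one skin layer at one wavelength.

    ``melanosome_fraction`` only affects the epidermis (stratum-basale
    melanin content; 0.03/0.23/0.43 approximate Fitzpatrick tones I/IV/VI).
    """
    if layer not in LAYER_DEFAULTS:
        raise KeyError(f"unknown skin layer {layer!r}")
    if not 0.0 <= melanosome_fraction <= 1.0:
        raise InvalidParameterError("melanosome fraction must lie in [0, 1]")
    p = dict(LAYER_DEFAULTS[layer])
    if overrides:
        p.update(overrides)
    M = melanosome_fraction if layer == "epidermis" else 0.0
    base_frac = max(0.0, 1.0 - p["B"] - p["W"] - p["F"] - M)
    mu_a = (p["B"] * blood_mu_a(wavelength_nm, p["S"])
            + p["W"] * _interp_band(wavelength_nm, _MUA_WATER)
            + p["F"] * _interp_band(wavelength_nm, _MUA_FAT)
            + M * melanosome_mu_a(wavelength_nm)
            + base_frac * skin_baseline_mu_a(wavelength_nm))
    if layer == "epidermis":
        mu_a *= EPIDERMAL_MU_A_FACTOR
    musp = p["a"] * (wavelength_nm / 500.0) ** (-p["b"])
    mu_s = musp / (1.0 - ANISOTROPY)
    return OpticalProperties(mu_a=mu_a, mu_s=mu_s, g=ANISOTROPY, n=TISSUE_N)


def skin_medium(layer: str, melanosome_fraction: float = 0.03,
                band: tuple[float, float] = CHROMOPHORE_BAND,
                step: float = 2.0) -> MediumSpec:
    """Tabulated :class:`MediumSpec` for one skin layer."""
    return MediumSpec.from_function(
        layer, lambda w: skin_layer_properties(layer, w, melanosome_fraction),
        band=band, step=step)


# --------------------------------------------------------------------------
# fluorophore registry (excitation wavelength -> mu_a 1/cm, quantum yield)
# --------------------------------------------------------------------------

FLUOROPHORES: dict[str, dict[int, dict[str, float | None]]] = {
    "PdP": {450: dict(mu_a=0.0066, phi=0.068)},
    "TRITC-ConA": {450: dict(mu_a=0.001716, phi=0.1)},
    "APTS-MT": {450: dict(mu_a=None, phi=0.2)},
    "Collagen": {450: dict(mu_a=7.8131, phi=0.05)},
    "Vitamin A": {450: dict(mu_a=0.0207, phi=0.03)},
    "FAD": {450: dict(mu_a=0.3643, phi=0.033)},
    "PPIX": {450: dict(mu_a=0.1058, phi=0.085)},
    "Melanin": {450: dict(mu_a=14.24, phi=0.0005),
                680: dict(mu_a=1.03, phi=0.00056)},
    "Cy5.5-MT": {680: dict(mu_a=250.0, phi=0.2)},
    "Cy7-ConA": {680: dict(mu_a=None, phi=0.3)},
    "BMAP": {680: dict(mu_a=168.0, phi=0.21)},
    # directly excited Cy7 component of the far-red FRET assay
    "Cy7-direct": {680: dict(mu_a=42.5, phi=0.30)},
}


def fluorophore(name: str, excitation_nm: int) -> dict[str, float | None]:
    """Registry lookup; raises KeyError for unregistered combinations."""
    try:
        return FLUOROPHORES[name][excitation_nm]
    except KeyError:
        raise KeyError(
            f"no registered properties for {name!r} at {excitation_nm} nm"
        ) from None


def implant_domain_properties(assay: str, wavelength_nm: float
                              ) -> OpticalProperties:
    """Properties of an implant assay domain at its excitation wavelength."""
    rec = fluorophore(assay, int(round(wavelength_nm)))
    if rec["mu_a"] is None:
        raise KeyError(f"{assay!r} has no registered mu_a at {wavelength_nm} nm")
    return OpticalProperties(mu_a=float(rec["mu_a"]), mu_s=0.0, g=0.0,
                             n=TISSUE_N)


def implant_medium(assay: str, excitation_nm: int,
                   luminescence: LuminophoreSpec | None = None,
                   mu_a_emission: float = 0.0) -> ImplantMedium:
    """:class:`ImplantMedium` for a registered assay domain."""
    rec = fluorophore(assay, excitation_nm)
    if rec["mu_a"] is None:
        raise KeyError(f"{assay!r} has no registered mu_a at {excitation_nm} nm")
    return ImplantMedium(assay, float(rec["mu_a"]), float(excitation_nm),
                         mu_a_emission=mu_a_emission, luminescence=luminescence)


def default_tissue_media(melanosome_fraction: float = 0.03,
                         band: tuple[float, float] = CHROMOPHORE_BAND,
                         step: float = 2.0) -> dict[str, MediumSpec]:
    """The three default skin-layer media keyed by layer name."""
    return {layer: skin_medium(layer, melanosome_fraction, band, step)
            for layer in ("epidermis", "dermis", "subcutis")}
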