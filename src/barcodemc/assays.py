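"""Assay post-processing.

Everything here is deterministic arithmetic applied to simulated spectra:
Stern-Volmer collisional oxygen quenching of phosphorescence intensity and
lifetime, time-gated acquisition of the exponential decay, the ratiometric
FRET donor/acceptor combination, the additively combined directly-excited
Cy7 component of the far-red assay, and the relative-gradient quantum-yield
arithmetic used for melanin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, InvalidParameterError
from .fluorescence import FluorescenceSpectrum

__all__ = ["SternVolmerParams", "FretParams", "AssayReadout",
           "stern_volmer_intensity", "stern_volmer_lifetime",
           "time_gated_intensity", "fret_combine", "far_red_fret_total",
           "melanin_quantum_yield", "FRET_PRESETS"]


@dataclass(frozen=True)
class SternVolmerParams:
    """Stern-Volmer quenching: ksv in 1/uM, tau0 in us, oxygen [Q] in uM."""

    ksv: float
    tau0: float
    oxygen: float

    def __post_init__(self) -> None:
        if self.ksv < 0:
            raise InvalidParameterError("ksv must be >= 0")
        if self.tau0 <= 0:
            raise InvalidParameterError("tau0 must be > 0")
        if self.oxygen < 0:
            raise InvalidParameterError("oxygen concentration must be >= 0")

    @property
    def quench_factor(self) -> float:
        """1 + Ksv*[Q]; I0/I and tau0/tau both equal this."""
        return 1.0 + self.ksv * self.oxygen


@dataclass(frozen=True)
class FretParams:
    """Scalar factors of the donor/acceptor spectral combination.

    spectral_overlap (SO), efficiency (E), bound fractions of ConA and MT
    all lie in [0, 1]; kappa2 in [0, 4]; eps_ratio = epsD/epsA > 0.  The
    donor suppression factor 1 - SO*E*ConA*MT*kappa2 must stay >= 0.
    """

    spectral_overlap: float = 1.0
    efficiency: float = 1.0
    frac_bound_cona: float = 1.0
    frac_bound_mt: float = 1.0
    kappa2: float = 2.0 / 3.0
    eps_ratio: float = 1.0
    include_mt_in_acceptor: bool = False

    def __post_init__(self) -> None:
        for name in ("spectral_overlap", "efficiency", "frac_bound_cona",
                     "frac_bound_mt"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.kappa2 <= 4.0:
            raise InvalidParameterError("kappa2 must lie in [0, 4]")
        if self.eps_ratio <= 0:
            raise InvalidParameterError("eps_ratio must be > 0")
        if self.donor_factor < 0:
            raise InvalidParameterError("donor factor would be negative")

    @property
    def transfer_product(self) -> float:
        return (self.spectral_overlap * self.efficiency
                * self.frac_bound_cona * self.kappa2)

    @property
    def donor_factor(self) -> float:
        return 1.0 - self.transfer_product * self.frac_bound_mt

    @property
    def acceptor_factor(self) -> float:
        f = self.eps_ratio * self.transfer_product
        if self.include_mt_in_acceptor:
            f *= self.frac_bound_mt
        return f


#: named validation presets for the visible FRET assay (bound fractions are
#: not published; these are package defaults, configurable per run)
FRET_PRESETS: dict[str, FretParams] = {
    "1uM_TRITC-ConA_100nM_APTS-MT": FretParams(frac_bound_cona=0.65,
                                               frac_bound_mt=0.65),
    "500nM_TRITC-ConA_100nM_APTS-MT": FretParams(frac_bound_cona=0.40,
                                                 frac_bound_mt=0.40),
}


@dataclass
class AssayReadout:
    """Post-processed assay output as per-bin fractions of source power."""

    wavelengths: np.ndarray
    spectrum: np.ndarray
    mode: str  # 'fret' | 'phosphor'
    gate_trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.spectrum = np.asarray(self.spectrum, dtype=float)
        if self.wavelengths.shape != self.spectrum.shape:
            raise AlignmentError("wavelengths and spectrum must align")
        if np.any(self.spectrum < 0):
            raise InvalidParameterError("readout spectrum must be >= 0")

    @property
    def peak_wavelength(self) -> float:
        return float(self.wavelengths[int(np.argmax(self.spectrum))])


def stern_volmer_intensity(i0, sv: SternVolmerParams):
    """Quenched intensity I = I0 / (1 + Ksv*[Q]); bin-wise on arrays."""
    i0 = np.asarray(i0, dtype=float)
    if np.any(i0 < 0):
        raise InvalidParameterError("intensities must be >= 0")
    out = i0 / sv.quench_factor
    return float(out) if out.ndim == 0 else out


def stern_volmer_lifetime(sv: SternVolmerParams) -> float:
    """Quenched lifetime tau = tau0 / (1 + Ksv*[Q]), us."""
    return sv.tau0 / sv.quench_factor


def time_gated_intensity(spectrum, tau: float, gate: tuple[float, float]):
    """Fraction of an exponential decay collected in the gate window,
    applied bin-wise: factor = exp(-t_start/tau) - exp(-t_end/tau)."""
    t_start, t_end = gate
    if not (t_end > t_start >= 0):
        raise InvalidParameterError("gate must satisfy t_end > t_start >= 0")
    if tau <= 0:
        raise InvalidParameterError("lifetime must be > 0")
    factor = math.exp(-t_start / tau) - (0.0 if math.isinf(t_end)
                                         else math.exp(-t_end / tau))
    out = np.asarray(spectrum, dtype=float) * factor
    return float(out) if out.ndim == 0 else out


def _check_aligned(a: FluorescenceSpectrum | AssayReadout,
                   b: FluorescenceSpectrum | AssayReadout) -> None:
    if (a.wavelengths.shape != b.wavelengths.shape
            or not np.allclose(a.wavelengths, b.wavelengths)):
        raise AlignmentError("spectra are on different bin plans")


def fret_combine(flrd_donor: FluorescenceSpectrum,
                 flrd_acceptor: FluorescenceSpectrum,
                 p: FretParams) -> AssayReadout:
    """Ratiometric FRET combination of donor and acceptor detected spectra.

    Donor bins are suppressed by (1 - SO*E*ConA*MT*kappa2); acceptor bins
    are scaled by (epsD/epsA)*SO*E*ConA*kappa2 — the acceptor expression
    carries no MT factor by default (toggle ``include_mt_in_acceptor`` for
    the symmetric variant).  The readout is the bin-wise sum.
    """
    _check_aligned(flrd_donor, flrd_acceptor)
    combined = (flrd_donor.detected_fraction * p.donor_factor
                + flrd_acceptor.detected_fraction * p.acceptor_factor)
    return AssayReadout(flrd_donor.wavelengths, combined, mode="fret")


def far_red_fret_total(fret_readout: AssayReadout,
                       direct_cy7: FluorescenceSpectrum) -> AssayReadout:
    """Add the directly excited Cy7 emission to the FRET-combined spectrum."""
    _check_aligned(fret_readout, direct_cy7)
    return AssayReadout(fret_readout.wavelengths,
                        fret_readout.spectrum + direct_cy7.detected_fraction,
                        mode="fret")


def melanin_quantum_yield(gradient_sample: float, gradient_ref: float,
                          n_sample: float, n_ref: float,
                          phi_ref: float) -> float:
    """Relative quantum yield from absorbance-fluorescence gradients:
    Phi = Phi_ref * (grad_s/grad_ref) * (n_s^2/n_ref^2)."""
    if gradient_ref == 0:
        raise ZeroDivisionError("reference gradient must be nonzero")
    if gradient_sample < 0 or gradient_ref < 0:
        raise InvalidParameterError("gradients must be positive")
    if n_sample < 1 or n_ref < 1:
        raise InvalidParameterError("refractive indices must be >= 1")
    if not 0.0 < phi_ref <= 1.0:
        raise InvalidParameterError("phi_ref must lie in (0, 1]")
    return phi_ref * (gradient_sample / gradient_ref) * (n_sample**2 / n_ref**2)
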