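"""Two-stage luminescence cascade.

One excitation transport run fixes where source light is absorbed inside
the luminescent medium; that absorption map then acts as an isotropic
emission source for a series of per-bin emission runs, each at its own
emission wavelength with the grid's optical properties re-evaluated there.
Per-bin output is scaled by the absorbed-excitation fraction and by the
power yield, i.e. the modified quantum yield

    mPhi_bin = Phi * Em(bin) / sum_bins Em        (so sum mPhi = Phi)

times the wavelength ratio lambda_ex / lambda_em (energy rather than
photon bookkeeping).  Secondary re-absorption/re-emission is neglected:
the cascade is single-generation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, DegenerateSourceError, InvalidParameterError
from .geometry import VoxelGrid
from .optics import LuminophoreSpec
from .transport import (DetectorSpec, SourceSpec, TransportResult, propagate,
                        propagate_from_distribution)

log = logging.getLogger(__name__)

__all__ = ["EmissionBinPlan", "FluorescenceSpectrum", "modified_quantum_yield",
           "power_yield", "emission_source_distribution", "run_emission_bin",
           "simulate_emission_spectrum", "VISIBLE_EMISSION_BAND",
           "FAR_RED_EMISSION_BAND"]

#: default emission bands (nm): visible-assay and far-red-assay windows
VISIBLE_EMISSION_BAND = (493.0, 700.0)
FAR_RED_EMISSION_BAND = (700.0, 900.0)


@dataclass(frozen=True)
class EmissionBinPlan:
    """An emission band split into n_bins equal wavelength bins."""

    band: tuple[float, float]
    n_bins: int = 80

    def __post_init__(self) -> None:
        lo, hi = self.band
        if hi <= lo:
            raise InvalidParameterError("emission band must have hi > lo")
        if self.n_bins < 1:
            raise InvalidParameterError("need at least one emission bin")

    @property
    def resolution(self) -> float:
        lo, hi = self.band
        return (hi - lo) / self.n_bins

    @property
    def centers(self) -> np.ndarray:
        lo, hi = self.band
        edges = np.linspace(lo, hi, self.n_bins + 1)
        return 0.5 * (edges[:-1] + edges[1:])


@dataclass
class FluorescenceSpectrum:
    """Per-bin fraction of incident source power reaching the detector."""

    wavelengths: np.ndarray
    detected_fraction: np.ndarray
    absorbed_excitation_fraction: float

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.detected_fraction = np.asarray(self.detected_fraction, dtype=float)
        if self.wavelengths.shape != self.detected_fraction.shape:
            raise AlignmentError("wavelengths and fractions must align")
        if np.any(self.detected_fraction < 0):
            raise InvalidParameterError("detected fractions must be >= 0")

    @property
    def total(self) -> float:
        return float(self.detected_fraction.sum())

    def scaled(self, factor) -> "FluorescenceSpectrum":
        return FluorescenceSpectrum(self.wavelengths,
                                    self.detected_fraction * factor,
                                    self.absorbed_excitation_fraction)


def modified_quantum_yield(phi: float, emission_values: np.ndarray
                           ) -> np.ndarray:
    """Apportion the quantum yield over the emission bins: Phi * Em / sum Em."""
    if not 0.0 <= phi <= 1.0:
        raise InvalidParameterError("quantum yield must lie in [0, 1]")
    em = np.asarray(emission_values, dtype=float)
    total = em.sum()
    if total <= 0.0:
        raise InvalidParameterError("emission spectrum sums to zero on the plan")
    return phi * em / total


def power_yield(m_phi, lambda_ex: float, lambda_em) -> np.ndarray | float:
    """Convert modified quantum yield to power yield: mPhi * l_ex / l_em."""
    if lambda_ex <= 0 or np.any(np.asarray(lambda_em) <= 0):
        raise InvalidParameterError("wavelengths must be > 0")
    if np.any(np.asarray(lambda_em) < lambda_ex):
        log.warning("emission below excitation wavelength (anti-Stokes bins)")
    return m_phi * (lambda_ex / np.asarray(lambda_em, dtype=float))


def emission_source_distribution(excitation: TransportResult,
                                 grid: VoxelGrid, label_names) -> tuple:
    """Normalized per-voxel emission probability over the luminescent labels.

    Returns (probs 3-D array summing to 1, absorbed_excitation_fraction).
    """
    if isinstance(label_names, str):
        label_names = [label_names]
    mask = np.isin(grid.labels, grid.labels_of(label_names))
    src = np.where(mask, excitation.absorbed, 0.0)
    total = float(src.sum())
    if total <= 0.0:
        raise DegenerateSourceError(
            f"no excitation weight absorbed in {list(label_names)!r}")
    return src / total, total


def run_emission_bin(grid: VoxelGrid, wavelength_em: float,
                     source_probs: np.ndarray,
                     detector: DetectorSpec | None = None,
                     n_photons: int = 10**5, seed: int = 0) -> float:
    """Raw detected fraction of isotropically emitted photons at one bin
    (before scaling by absorbed fraction and power yield)."""
    res = propagate_from_distribution(grid, wavelength_em, source_probs,
                                      detector=detector,
                                      n_photons=n_photons, seed=seed)
    return res.detected_fraction


def _bin_seed(master_seed: int, bin_index: int) -> int:
    # bin_index -1 tags the excitation run
    return int(np.random.SeedSequence([int(master_seed),
                                       int(bin_index) + 1]).generate_state(1)[0])


def simulate_emission_spectrum(grid: VoxelGrid, label_names,
                               luminophore: LuminophoreSpec,
                               plan: EmissionBinPlan,
                               source: SourceSpec,
                               detector: DetectorSpec | None = None,
                               emission_grid: VoxelGrid | None = None,
                               n_photons_excitation: int = 10**6,
                               n_photons_per_bin: int = 10**5,
                               seed: int = 0,
                               excitation: TransportResult | None = None
                               ) -> FluorescenceSpectrum:
    """Full cascade: one excitation run plus plan.n_bins emission runs.

    ``emission_grid`` lets the emission stage run on a different grid than
    the excitation stage (for example, endogenous-fluorophore models where
    the absorption substitution applies to the excitation run only).  The
    per-bin seeds are derived from (seed, bin index), so runs are
    reproducible and bins are independent.
    """
    if excitation is None:
        excitation = propagate(grid, source, detector,
                               n_photons=n_photons_excitation,
                               seed=_bin_seed(seed, -1))
    probs, absorbed_frac = emission_source_distribution(excitation, grid,
                                                        label_names)
    em_grid = emission_grid if emission_grid is not None else grid
    centers = plan.centers
    em = luminophore.emission_on(centers)
    m_phi = modified_quantum_yield(luminophore.quantum_yield, em)
    py = power_yield(m_phi, source.wavelength, centers)
    detected = np.empty(plan.n_bins)
    for b in range(plan.n_bins):
        if py[b] == 0.0:
            detected[b] = 0.0
            continue
        raw = run_emission_bin(em_grid, float(centers[b]), probs, detector,
                               n_photons=n_photons_per_bin,
                               seed=_bin_seed(seed, b))
        detected[b] = raw * absorbed_frac * py[b]
    return FluorescenceSpectrum(centers, detected, absorbed_frac)
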