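"""Endogenous-fluorophore models and combined tissue autofluorescence.

Each endogenous fluorophore gets its own three-layer model in which the
host (sub-)layer's absorption coefficient is replaced by the registered
fluorophore value while the scattering of the original layer is kept, and
all absorption in that region is attributed to the fluorophore.  Placement:
FAD occupies the epidermis below the stratum corneum, melanin the stratum
basale (modeled as the bottom 20% of the epidermis), collagen and vitamin A
the dermis.  NADH is not excited at 450 nm and porphyrins not at 680 nm,
so the default fluorophore sets honor those exclusions (PPIX is registered
but excluded from the default 450 nm set).

Emission runs use the unmodified skin grid: the absorption substitution
describes where excitation light is captured, not how emitted light
travels.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .config import ENDOGENOUS_SPECTRA, generate_synthetic_spectrum
from .errors import GeometryError
from .fluorescence import (EmissionBinPlan, FluorescenceSpectrum,
                           simulate_emission_spectrum)
from .geometry import LayerStack, VoxelGrid, build_grid
from .optics import LuminophoreSpec, fluorophore, default_tissue_media
from .transport import DetectorSpec, SourceSpec

__all__ = ["EndogenousFluorophore", "ENDOGENOUS", "DEFAULT_SETS",
           "STRATUM_CORNEUM_THICKNESS", "build_autofluorescence_grid",
           "autofluorescence_spectrum", "endogenous_luminophore"]

#: stratum corneum thickness, cm (top sub-layer of the 0.010 cm epidermis)
STRATUM_CORNEUM_THICKNESS = 0.002
#: stratum basale modeled as the bottom fraction of the epidermis
BASALE_FRACTION = 0.2


@dataclass(frozen=True)
class EndogenousFluorophore:
    """Registry entry: host layer plus sub-layer placement within it."""

    name: str
    host_layer: str
    placement: str  # 'full' | 'below_corneum' | 'basale'


ENDOGENOUS: dict[str, EndogenousFluorophore] = {
    "FAD": EndogenousFluorophore("FAD", "epidermis", "below_corneum"),
    "Melanin": EndogenousFluorophore("Melanin", "epidermis", "basale"),
    "Collagen": EndogenousFluorophore("Collagen", "dermis", "full"),
    "Vitamin A": EndogenousFluorophore("Vitamin A", "dermis", "full"),
    "PPIX": EndogenousFluorophore("PPIX", "epidermis", "below_corneum"),
}

#: default fluorophore sets per excitation wavelength
DEFAULT_SETS: dict[int, tuple[str, ...]] = {
    450: ("FAD", "Collagen", "Vitamin A", "Melanin"),
    680: ("Melanin",),
}


class _FluorophoreLayerMedium:
    """Host-layer medium with its absorption replaced by the fluorophore
    value (scattering, anisotropy and index follow the base layer)."""

    def __init__(self, name: str, base, mu_a: float):
        self.name = name
        self.base = base
        self.mu_a = float(mu_a)
        self.luminescence = None

    def at(self, wavelength_nm: float):
        import dataclasses
        return dataclasses.replace(self.base.at(wavelength_nm), mu_a=self.mu_a)


def endogenous_luminophore(name: str, excitation_nm: int) -> LuminophoreSpec:
    """LuminophoreSpec for an endogenous fluorophore with the registered
    quantum yield and the synthetic stand-in emission curve."""
    rec = fluorophore(name, excitation_nm)
    key = f"{name}@{excitation_nm}" if f"{name}@{excitation_nm}" in \
        ENDOGENOUS_SPECTRA else name
    wl, em = generate_synthetic_spectrum(ENDOGENOUS_SPECTRA[key])
    return LuminophoreSpec(quantum_yield=float(rec["phi"]),
                           emission_wavelengths=wl, emission_values=em)


def build_autofluorescence_grid(name: str, excitation_nm: int,
                                stack: LayerStack | None = None,
                                melanosome_fraction: float = 0.03,
                                voxel_size: float = 0.005,
                                axial_voxel_size: float = 0.002,
                                lateral_extent: float = 1.5,
                                layer_mu_a: float | None = None,
                                media: dict | None = None
                                ) -> tuple[VoxelGrid, VoxelGrid, str]:
    """Build (excitation grid, emission/base grid, fluorescent label name).

    The excitation grid carries the fluorophore-substituted sub-layer; the
    base grid is the unmodified three-layer model on the same voxelization.
    ``layer_mu_a`` overrides the registered absorption (e.g. the melanin
    layer at 680 nm representative of a 3% melanosome individual).
    """
    ef = ENDOGENOUS[name]
    stack = stack or LayerStack()
    if media is None:
        media = default_tissue_media(melanosome_fraction)
    base = build_grid(stack=stack, implant=None, media=media,
                      voxel_size=voxel_size,
                      axial_voxel_size=axial_voxel_size,
                      lateral_extent=lateral_extent)
    mu_a = layer_mu_a if layer_mu_a is not None else \
        float(fluorophore(name, excitation_nm)["mu_a"])

    # host layer z-extent
    z = 0.0
    host_range = None
    for lname, t in stack.layers:
        if lname == ef.host_layer:
            host_range = (z, z + t)
            break
        z += t
    if host_range is None:
        raise GeometryError(f"host layer {ef.host_layer!r} not in stack")
    z_lo, z_hi = host_range
    if ef.placement == "below_corneum":
        z_lo = z_lo + STRATUM_CORNEUM_THICKNESS
    elif ef.placement == "basale":
        z_lo = z_hi - BASALE_FRACTION * (z_hi - host_range[0])
    if z_lo >= z_hi:
        raise GeometryError(
            f"{name}: sub-layer placement thicker than host layer")

    dz = base.dz
    iz0 = int(round(z_lo / dz))
    iz1 = int(round(z_hi / dz))
    if abs(iz0 * dz - z_lo) > 1e-9 or abs(iz1 * dz - z_hi) > 1e-9:
        raise GeometryError(
            f"{name}: sub-layer bounds ({z_lo}-{z_hi} cm) do not land on "
            f"voxel faces (dz={dz} cm)")

    label_name = f"{name} layer"
    host_label = base.label_of(ef.host_layer)
    labels = base.labels.copy()
    new_label = len(base.media)
    region = labels[:, :, iz0:iz1]
    region[region == host_label] = new_label
    labels[:, :, iz0:iz1] = region
    fmed = _FluorophoreLayerMedium(label_name, media[ef.host_layer], mu_a)
    grid = VoxelGrid(labels, list(base.media) + [fmed], base.dx, base.dz)
    return grid, base, label_name


def _fluor_seed(master_seed: int, name: str) -> int:
    return int(np.random.SeedSequence(
        [int(master_seed), zlib.crc32(name.encode())]).generate_state(1)[0])


def default_plan(excitation_nm: int, resolution: float = 5.0
                 ) -> EmissionBinPlan:
    """Emission bin plan at <= ``resolution`` nm for an excitation line."""
    band = (493.0, 700.0) if excitation_nm < 600 else (685.0, 820.0)
    n_bins = int(np.ceil((band[1] - band[0]) / resolution))
    return EmissionBinPlan(band=band, n_bins=n_bins)


def autofluorescence_spectrum(names, excitation_nm: int,
                              plan: EmissionBinPlan | None = None,
                              source: SourceSpec | None = None,
                              detector: DetectorSpec | None = None,
                              n_photons_excitation: int = 10**6,
                              n_photons_per_bin: int = 10**5,
                              seed: int = 0,
                              **grid_kwargs) -> FluorescenceSpectrum:
    """Combined autofluorescence: independent per-fluorophore cascades,
    summed bin-wise.  Per-fluorophore seeds depend only on (seed, name), so
    the combined spectrum equals the sum of single-fluorophore runs."""
    plan = plan or default_plan(excitation_nm)
    source = source or SourceSpec(wavelength=float(excitation_nm))
    detector = detector or DetectorSpec()
    total = np.zeros(plan.n_bins)
    absorbed = 0.0
    for name in names:
        grid, base, label = build_autofluorescence_grid(
            name, excitation_nm, **grid_kwargs)
        lum = endogenous_luminophore(name, excitation_nm)
        spec = simulate_emission_spectrum(
            grid, label, lum, plan, source, detector, emission_grid=base,
            n_photons_excitation=n_photons_excitation,
            n_photons_per_bin=n_photons_per_bin,
            seed=_fluor_seed(seed, name))
        total += spec.detected_fraction
        absorbed += spec.absorbed_excitation_fraction
    return FluorescenceSpectrum(plan.centers, total, absorbed)
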