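"""Orchestrated experiments: convergence analysis, depth and melanosome
sweeps, absorbed-fraction and irradiance-ratio reports, full barcode runs.

Every study derives all of its randomness from one master seed (reported in
the StudyReport), so a rerun with the same arguments reproduces the same
numbers bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .fluorescence import (EmissionBinPlan, FAR_RED_EMISSION_BAND,
                           VISIBLE_EMISSION_BAND, emission_source_distribution,
                           modified_quantum_yield, run_emission_bin)
from .geometry import BarcodeImplant, LayerStack, VoxelGrid, build_grid
from .optics import ImplantMedium, default_tissue_media, fluorophore, \
    implant_medium
from .transport import (DetectorSpec, SourceSpec, TransportResult,
                        fluence_at_depth, propagate)
from .config import DYE_SPECTRA, generate_synthetic_spectrum

__all__ = ["StudyReport", "assay_media", "barcode_grid", "peak_detected_power",
           "convergence_study", "depth_sweep", "melanin_sweep",
           "absorbed_fraction_report", "irradiance_ratio",
           "FITZPATRICK_LABELS", "PEAK_EMISSION_NM"]

#: melanosome volume fraction -> approximate Fitzpatrick skin tone
FITZPATRICK_LABELS = {0.03: "I", 0.23: "IV", 0.43: "VI"}

#: sweep metric wavelengths: peak emission of the far-red FRET and
#: phosphorescence-lifetime assays
PEAK_EMISSION_NM = {"fret": 778.0, "phosphor": 810.0}

#: assay dyes backing each barcode domain per excitation regime
_DOMAIN_DYES = {
    680: {"phosphor": "BMAP", "fret": "Cy5.5-MT"},
    450: {"phosphor": "PdP", "fret": "TRITC-ConA"},
}


@dataclass
class StudyReport:
    """Parameter sweep result: one row per parameter value, with replicate
    statistics (mean, SD, COV = SD/mean) where replicates were run."""

    parameter: str
    table: pd.DataFrame
    seed: int
    meta: dict = field(default_factory=dict)


def _seed(master: int, *tags: int) -> int:
    return int(np.random.SeedSequence([int(master), *map(int, tags)]
                                      ).generate_state(1)[0])


def assay_media(excitation_nm: int = 680, melanosome_fraction: float = 0.03,
                mu_a_override: float | None = None) -> dict:
    """Tissue media plus the two barcode-domain media for one excitation
    regime.  ``mu_a_override`` forces a single absorption value on both
    domains (the convergence-study scenario)."""
    media = default_tissue_media(melanosome_fraction)
    dyes = _DOMAIN_DYES[excitation_nm]
    for domain, dye in dyes.items():
        if mu_a_override is not None:
            media[domain] = ImplantMedium(domain, mu_a_override,
                                          float(excitation_nm))
        else:
            med = implant_medium(dye, excitation_nm)
            med.name = domain
            media[domain] = med
    return media


def barcode_grid(excitation_nm: int = 680, center_depth: float = 0.20,
                 melanosome_fraction: float = 0.03,
                 mu_a_override: float | None = None,
                 voxel_size: float = 0.005,
                 lateral_extent: float = 1.5) -> VoxelGrid:
    """Default three-layer grid with the barcode implant."""
    return build_grid(
        stack=LayerStack(),
        implant=BarcodeImplant(center_depth=center_depth),
        media=assay_media(excitation_nm, melanosome_fraction, mu_a_override),
        voxel_size=voxel_size, lateral_extent=lateral_extent)


def peak_detected_power(grid: VoxelGrid, assay: str, excitation_nm: int,
                        emission_nm: float, power_yield_peak: float,
                        source: SourceSpec | None = None,
                        detector: DetectorSpec | None = None,
                        n_photons: int = 10**6, seed: int = 0) -> float:
    """Detected power (W) at one emission wavelength for one assay label:
    excitation run -> emission run at ``emission_nm`` scaled by the
    absorbed-excitation fraction, the per-bin power yield and the source
    power."""
    source = source or SourceSpec(wavelength=float(excitation_nm))
    detector = detector or DetectorSpec()
    exc = propagate(grid, source, detector, n_photons=n_photons,
                    seed=_seed(seed, 0))
    probs, absorbed_frac = emission_source_distribution(exc, grid, assay)
    raw = run_emission_bin(grid, emission_nm, probs, detector,
                           n_photons=n_photons, seed=_seed(seed, 1))
    return raw * absorbed_frac * power_yield_peak * source.power


def _peak_power_yield(assay: str, excitation_nm: int,
                      plan: EmissionBinPlan, emission_nm: float) -> float:
    """Per-bin power yield of the assay dye at the bin nearest the peak."""
    dye = _DOMAIN_DYES[excitation_nm][assay]
    phi = float(fluorophore(dye, excitation_nm)["phi"])
    wl, em = generate_synthetic_spectrum(DYE_SPECTRA[dye])
    em_bins = np.interp(plan.centers, wl, em, left=0.0, right=0.0)
    m_phi = modified_quantum_yield(phi, em_bins)
    b = int(np.argmin(np.abs(plan.centers - emission_nm)))
    return float(m_phi[b] * excitation_nm / plan.centers[b])


def convergence_study(photon_counts, excitation_nm: int = 680,
                      replicates: int = 3, seed: int = 0,
                      mu_a: float = 0.001, power_yield: float = 0.001,
                      emission_nm: float | None = None,
                      voxel_size: float = 0.005,
                      lateral_extent: float = 1.5) -> StudyReport:
    """Photon-count convergence on the low-absorption scenario: the barcode
    domains carry mu_a = 0.001 1/cm and a power yield of 0.001, constant
    over the emission band.  Reports the detected magnitude (light reaching
    the photodetector per unit source power) at each count, the percent
    difference between consecutive counts, and the replicate COV."""
    counts = list(photon_counts)
    if any(b <= a for a, b in zip(counts, counts[1:])):
        raise InvalidParameterError("photon counts must be ascending")
    band = FAR_RED_EMISSION_BAND if excitation_nm >= 600 else \
        VISIBLE_EMISSION_BAND
    em_nm = emission_nm if emission_nm is not None else 0.5 * sum(band)
    grid = barcode_grid(excitation_nm, mu_a_override=mu_a,
                        voxel_size=voxel_size, lateral_extent=lateral_extent)
    source = SourceSpec(wavelength=float(excitation_nm))
    detector = DetectorSpec()
    rows = []
    prev_mean = None
    for ci, n in enumerate(counts):
        vals = []
        for r in range(replicates):
            exc = propagate(grid, source, detector, n_photons=n,
                            seed=_seed(seed, ci, r, 0))
            probs, absorbed_frac = emission_source_distribution(
                exc, grid, ["fret", "phosphor"])
            raw = run_emission_bin(grid, em_nm, probs, detector,
                                   n_photons=n, seed=_seed(seed, ci, r, 1))
            vals.append(raw * absorbed_frac * power_yield)
        vals = np.asarray(vals)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        pct_diff = (abs(mean - prev_mean) / prev_mean * 100.0
                    if prev_mean else np.nan)
        rows.append(dict(n_photons=n, detected=mean, sd=sd,
                         cov_pct=100.0 * sd / mean if mean else np.nan,
                         pct_diff_prev=pct_diff))
        prev_mean = mean
    return StudyReport("n_photons", pd.DataFrame(rows), seed,
                       meta=dict(mu_a=mu_a, power_yield=power_yield,
                                 excitation_nm=excitation_nm,
                                 emission_nm=em_nm, replicates=replicates))


def depth_sweep(depths, assay: str = "fret", excitation_nm: int = 680,
                replicates: int = 3, n_photons: int = 10**6, seed: int = 0,
                plan: EmissionBinPlan | None = None,
                voxel_size: float = 0.005,
                lateral_extent: float = 1.5) -> StudyReport:
    """Peak-bin detected power versus implant center depth, in replicate."""
    plan = plan or EmissionBinPlan(FAR_RED_EMISSION_BAND)
    em_nm = PEAK_EMISSION_NM[assay]
    py = _peak_power_yield(assay, excitation_nm, plan, em_nm)
    rows = []
    for di, depth in enumerate(depths):
        grid = barcode_grid(excitation_nm, center_depth=depth,
                            voxel_size=voxel_size,
                            lateral_extent=lateral_extent)
        vals = [peak_detected_power(grid, assay, excitation_nm, em_nm, py,
                                    n_photons=n_photons,
                                    seed=_seed(seed, di, r))
                for r in range(replicates)]
        vals = np.asarray(vals)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append(dict(depth_cm=depth, power_w=mean, sd=sd,
                         cov_pct=100.0 * sd / mean if mean else np.nan))
    return StudyReport("depth_cm", pd.DataFrame(rows), seed,
                       meta=dict(assay=assay, emission_nm=em_nm,
                                 n_photons=n_photons, replicates=replicates))


def melanin_sweep(fractions=(0.03, 0.23, 0.43), assay: str = "fret",
                  excitation_nm: int = 680, replicates: int = 3,
                  n_photons: int = 10**6, seed: int = 0,
                  plan: EmissionBinPlan | None = None,
                  voxel_size: float = 0.005,
                  lateral_extent: float = 1.5) -> StudyReport:
    """Peak-bin detected power versus epidermal melanosome volume fraction
    (0.03/0.23/0.43 approximate Fitzpatrick tones I/IV/VI)."""
    plan = plan or EmissionBinPlan(FAR_RED_EMISSION_BAND)
    em_nm = PEAK_EMISSION_NM[assay]
    py = _peak_power_yield(assay, excitation_nm, plan, em_nm)
    rows = []
    for fi, f in enumerate(fractions):
        if not 0.0 <= f <= 1.0:
            raise InvalidParameterError("melanosome fraction must be in [0,1]")
        grid = barcode_grid(excitation_nm, melanosome_fraction=f,
                            voxel_size=voxel_size,
                            lateral_extent=lateral_extent)
        vals = [peak_detected_power(grid, assay, excitation_nm, em_nm, py,
                                    n_photons=n_photons,
                                    seed=_seed(seed, fi, r))
                for r in range(replicates)]
        vals = np.asarray(vals)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append(dict(melanosome_fraction=f,
                         fitzpatrick=FITZPATRICK_LABELS.get(f, ""),
                         power_w=mean, sd=sd,
                         cov_pct=100.0 * sd / mean if mean else np.nan))
    return StudyReport("melanosome_fraction", pd.DataFrame(rows), seed,
                       meta=dict(assay=assay, emission_nm=em_nm,
                                 n_photons=n_photons, replicates=replicates))


def absorbed_fraction_report(result: TransportResult, grid: VoxelGrid,
                             label_names) -> dict[str, float]:
    """Fractions of incident light, and of all absorbed light, captured by
    the given labels (combined)."""
    if isinstance(label_names, str):
        label_names = [label_names]
    in_labels = float(sum(result.absorbed_by_medium[n] for n in label_names))
    total = result.absorbed_total
    return dict(fraction_of_incident=in_labels,
                fraction_of_absorbed=in_labels / total if total else np.nan,
                total_absorbed=total)


def irradiance_ratio(depth: float = 0.20, wavelength_a: float = 680.0,
                     wavelength_b: float = 450.0, n_photons: int = 10**6,
                     seed: int = 0, replicates: int = 1,
                     voxel_size: float = 0.005,
                     lateral_extent: float = 1.5) -> StudyReport:
    """Fold-ratio of fluence at ``depth`` under the beam between two
    excitation wavelengths on the bare three-layer model."""
    grid = build_grid(stack=LayerStack(), implant=None,
                      media=default_tissue_media(),
                      voxel_size=voxel_size, lateral_extent=lateral_extent)
    detector = DetectorSpec()
    rows = []
    for r in range(replicates):
        fl = []
        for wl in (wavelength_a, wavelength_b):
            # seed keyed by the wavelength itself: equal wavelengths share
            # the photon stream, so their ratio is exactly 1
            res = propagate(grid, SourceSpec(wavelength=wl), detector,
                            n_photons=n_photons,
                            seed=_seed(seed, r, int(round(wl * 1000))))
            fl.append(fluence_at_depth(res, depth))
        if fl[1] == 0.0:
            raise ZeroDivisionError("zero fluence at the reference wavelength")
        rows.append(dict(replicate=r, fluence_a=fl[0], fluence_b=fl[1],
                         ratio=fl[0] / fl[1]))
    df = pd.DataFrame(rows)
    return StudyReport("replicate", df, seed,
                       meta=dict(depth_cm=depth, wavelength_a=wavelength_a,
                                 wavelength_b=wavelength_b,
                                 n_photons=n_photons,
                                 ratio_mean=float(df["ratio"].mean()),
                                 ratio_sd=float(df["ratio"].std(ddof=1))
                                 if replicates > 1 else 0.0))
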