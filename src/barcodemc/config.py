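"""Run configuration, synthetic emission-spectrum fixtures, and result I/O.

The dye and endogenous-fluorophore emission curves used by default are
synthetic stand-ins: two-sided (skewed) Gaussians with configurable peak,
FWHM and skew, peak-normalized to 1.  Their peak positions come from the
wavelengths the framework's assays are built around; the widths are fixture
parameters and are not authoritative.  Users supply measured curves as
two-column delimited files to replace them.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigError, InvalidParameterError

log = logging.getLogger("barcodemc")

__all__ = ["SyntheticSpectrum", "generate_synthetic_spectrum", "DYE_SPECTRA",
           "ENDOGENOUS_SPECTRA", "RunConfig", "load_config", "dump_config",
           "write_results", "load_spectrum_file"]


# --------------------------------------------------------------------------
# synthetic emission spectra
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticSpectrum:
    """Skewed-Gaussian emission curve: peak and FWHM in nm, skew in (-1, 1)
    (negative skew widens the blue side, positive the red side)."""

    peak: float
    fwhm: float
    skew: float = 0.0
    band: tuple[float, float] = (400.0, 1000.0)

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not lo < self.peak < hi:
            raise InvalidParameterError("band must contain the peak")
        if self.fwhm <= 0:
            raise InvalidParameterError("FWHM must be > 0")
        if not -1.0 < self.skew < 1.0:
            raise InvalidParameterError("skew must lie in (-1, 1)")


def generate_synthetic_spectrum(spec: SyntheticSpectrum, n_points: int = 512):
    """Deterministic peak-normalized emission curve on the spec's band.

    The two half-widths are sigma*(1 -/+ skew), so the value at the peak is
    exactly 1 and the FWHM equals the requested value for any skew.
    Returns (wavelengths, values).
    """
    if n_points < 3:
        raise InvalidParameterError("need at least 3 points")
    lo, hi = spec.band
    wl = np.linspace(lo, hi, n_points)
    sigma = spec.fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    s_left = sigma * (1.0 - spec.skew)
    s_right = sigma * (1.0 + spec.skew)
    d = wl - spec.peak
    s = np.where(d < 0, s_left, s_right)
    values = np.exp(-0.5 * (d / s) ** 2)
    return wl, values / values.max()


#: default dye fixtures; peaks follow the assay emission wavelengths the
#: framework targets, widths/skews are non-authoritative fixture values
DYE_SPECTRA: dict[str, SyntheticSpectrum] = {
    "PdP": SyntheticSpectrum(peak=700.0, fwhm=40.0, skew=0.25,
                             band=(493.0, 800.0)),
    "TRITC-ConA": SyntheticSpectrum(peak=580.0, fwhm=45.0, skew=0.3,
                                    band=(493.0, 760.0)),
    "APTS-MT": SyntheticSpectrum(peak=520.0, fwhm=50.0, skew=0.3,
                                 band=(460.0, 720.0)),
    "BMAP": SyntheticSpectrum(peak=807.0, fwhm=45.0, skew=0.2,
                              band=(700.0, 950.0)),
    "Cy5.5-MT": SyntheticSpectrum(peak=710.0, fwhm=40.0, skew=0.35,
                                  band=(680.0, 900.0)),
    "Cy7-ConA": SyntheticSpectrum(peak=779.0, fwhm=45.0, skew=0.3,
                                  band=(700.0, 950.0)),
    "Cy7-direct": SyntheticSpectrum(peak=779.0, fwhm=45.0, skew=0.3,
                                    band=(700.0, 950.0)),
}

#: endogenous-fluorophore fixtures (literature-shaped stand-ins)
ENDOGENOUS_SPECTRA: dict[str, SyntheticSpectrum] = {
    "Collagen": SyntheticSpectrum(peak=520.0, fwhm=90.0, skew=0.3,
                                  band=(460.0, 720.0)),
    "FAD": SyntheticSpectrum(peak=535.0, fwhm=85.0, skew=0.3,
                             band=(470.0, 720.0)),
    "Vitamin A": SyntheticSpectrum(peak=500.0, fwhm=80.0, skew=0.25,
                                   band=(460.0, 700.0)),
    "Melanin": SyntheticSpectrum(peak=550.0, fwhm=120.0, skew=0.3,
                                 band=(470.0, 750.0)),
    "Melanin@680": SyntheticSpectrum(peak=695.0, fwhm=50.0, skew=0.45,
                                     band=(682.0, 820.0)),
    "PPIX": SyntheticSpectrum(peak=635.0, fwhm=35.0, skew=0.3,
                              band=(560.0, 750.0)),
}


def load_spectrum_file(path):
    """Two-column delimited spectrum file -> (wavelength nm, relative value),
    peak-normalized."""
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ConfigError(f"{path}: expected two columns")
    values = data[:, 1]
    if values.max() <= 0:
        raise ConfigError(f"{path}: spectrum has no positive values")
    return data[:, 0], values / values.max()


# --------------------------------------------------------------------------
# run configuration (strict schema; unknown keys rejected)
# --------------------------------------------------------------------------


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    layers: list[tuple[str, float]] = [("epidermis", 0.010), ("dermis", 0.15),
                                       ("subcutis", 0.24)]
    voxel_size: float = Field(0.005, gt=0)
    axial_voxel_size: float | None = Field(None, gt=0)
    lateral_extent: float = Field(1.5, gt=0)
    implant_depth: float = Field(0.20, gt=0)
    implant_length_x: float = Field(0.40, gt=0)
    implant_width_y: float = Field(0.10, gt=0)
    implant_height_z: float = Field(0.10, gt=0)
    implant_domains: list[tuple[str, float]] = [("fret", 0.10),
                                                ("phosphor", 0.10),
                                                ("fret", 0.10),
                                                ("phosphor", 0.10)]
    include_implant: bool = True
    melanosome_fraction: float = Field(0.03, ge=0, le=1)


class SourceConfig(_Strict):
    wavelength: float = Field(680.0, gt=0)
    width_x: float = Field(0.40, ge=0)
    width_y: float = Field(0.40, ge=0)
    half_angle: float = Field(math.pi / 8.0, ge=0, le=math.pi / 2)
    power: float = Field(0.032, ge=0)


class DetectorConfig(_Strict):
    numerical_aperture: float = Field(0.4, gt=0, le=1)
    diameter: float = Field(0.17, gt=0)
    n_ambient: float = Field(1.0, ge=1)


class AssayConfig(_Strict):
    mode: str = "fret"
    phosphor_name: str = "BMAP"
    donor_name: str = "Cy5.5-MT"
    acceptor_name: str = "Cy7-ConA"
    ksv: float = Field(0.03, ge=0)
    tau0: float = Field(588.0, gt=0)
    oxygen: float = Field(100.0, ge=0)
    gate: tuple[float, float] = (0.0, math.inf)
    spectral_overlap: float = Field(1.0, ge=0, le=1)
    efficiency: float = Field(1.0, ge=0, le=1)
    frac_bound_cona: float = Field(1.0, ge=0, le=1)
    frac_bound_mt: float = Field(1.0, ge=0, le=1)
    kappa2: float = Field(2.0 / 3.0, ge=0, le=4)
    eps_ratio: float = Field(1.0, gt=0)
    emission_band: tuple[float, float] = (700.0, 900.0)
    n_bins: int = Field(80, ge=1)


class StudyConfig(_Strict):
    depths: list[float] = [0.20, 0.30, 0.40, 0.50]
    melanosome_fractions: list[float] = [0.03, 0.23, 0.43]
    photon_counts: list[int] = [10**5, 10**6, 10**7]
    replicates: int = Field(3, ge=1)


class RunConfig(_Strict):
    geometry: GeometryConfig = GeometryConfig()
    source: SourceConfig = SourceConfig()
    detector: DetectorConfig = DetectorConfig()
    assay: AssayConfig = AssayConfig()
    study: StudyConfig = StudyConfig()
    n_photons: int = Field(10**6, ge=1)
    seed: int = Field(0, ge=0)
    out_dir: str = "results"
    property_files: dict[str, str] = {}
    spectrum_files: dict[str, str] = {}

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; all schema violations
    are reported together."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        cfg = RunConfig.model_validate(raw)
    except ValidationError as e:
        msgs = "; ".join(f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
                         for err in e.errors())
        raise ConfigError(f"{path}: {msgs}") from None
    log.info("loaded config %s (hash %s)", path, cfg.config_hash())
    return cfg


def dump_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(mode="json"), fh, sort_keys=True)


# --------------------------------------------------------------------------
# result writing
# --------------------------------------------------------------------------


def write_results(out_dir, *, spectra: dict | None = None,
                  tallies: dict | None = None, report=None,
                  metadata: dict | None = None) -> list[Path]:
    """Write spectra (TSV), transport tallies (npz), study reports (TSV)
    and a metadata JSON into ``out_dir``; returns the files written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, spec in (spectra or {}).items():
        p = out / f"{name}.tsv"
        np.savetxt(p, np.column_stack([spec.wavelengths,
                                       getattr(spec, "detected_fraction",
                                               getattr(spec, "spectrum", None))]),
                   delimiter="\t", header="bin_center_nm\tdetected_fraction",
                   fmt="%.17g")
        written.append(p)
    for name, res in (tallies or {}).items():
        p = out / f"{name}.npz"
        res.save(p)
        written.append(p)
    if report is not None:
        p = out / "report.tsv"
        report.table.to_csv(p, sep="\t", index=False)
        written.append(p)
    meta = dict(metadata or {})
    meta.setdefault("package", "barcodemc")
    p = out / "metadata.json"
    with open(p, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
    written.append(p)
    for w in written:
        log.info("wrote %s", w)
    return written
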