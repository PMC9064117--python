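"""Voxelized three-layer forearm model with an embedded barcode implant.

Coordinates: x and y span the lateral extent centered on the beam axis,
z runs downward from the skin surface (z = 0).  Voxels may be anisotropic
(one lateral size for x/y, one axial size for z) so that thin epidermal
sub-layers can be resolved without refining the whole grid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import DiscretizationError, GeometryError, InvalidParameterError

__all__ = ["LayerStack", "BarcodeImplant", "VoxelGrid", "build_grid",
           "move_implant", "default_stack", "default_implant"]

#: default layer thicknesses, cm (epidermis / dermis / subcutis)
DEFAULT_THICKNESSES = (("epidermis", 0.010), ("dermis", 0.15),
                       ("subcutis", 0.24))
#: default implant: grain-of-rice bar, 0.10 x 0.10 cm cross-section,
#: 0.40 cm long, four alternating 0.10 cm barcode domains
DEFAULT_DOMAIN_SEQUENCE = (("fret", 0.10), ("phosphor", 0.10),
                           ("fret", 0.10), ("phosphor", 0.10))


@dataclass(frozen=True)
class LayerStack:
    """Ordered top-down list of (medium name, thickness cm)."""

    layers: tuple[tuple[str, float], ...] = DEFAULT_THICKNESSES

    def __post_init__(self) -> None:
        if not self.layers:
            raise InvalidParameterError("layer stack must not be empty")
        for name, t in self.layers:
            if t <= 0:
                raise InvalidParameterError(f"layer {name!r} thickness must be > 0")

    @property
    def total_depth(self) -> float:
        return float(sum(t for _, t in self.layers))

    def boundaries(self) -> list[float]:
        """Depths of the layer interfaces, surface included."""
        z = [0.0]
        for _, t in self.layers:
            z.append(z[-1] + t)
        return z


@dataclass(frozen=True)
class BarcodeImplant:
    """Rectangular barcode implant, long axis along x, centered on the beam."""

    center_depth: float = 0.20
    length_x: float = 0.40
    width_y: float = 0.10
    height_z: float = 0.10
    domain_sequence: tuple[tuple[str, float], ...] = DEFAULT_DOMAIN_SEQUENCE

    def __post_init__(self) -> None:
        for v in (self.center_depth, self.length_x, self.width_y, self.height_z):
            if v <= 0:
                raise GeometryError("implant dimensions and depth must be > 0")
        total = sum(l for _, l in self.domain_sequence)
        if not np.isclose(total, self.length_x, rtol=0, atol=1e-9):
            raise GeometryError(
                f"domains ({total} cm) must tile the implant length "
                f"({self.length_x} cm) exactly")

    @property
    def z_top(self) -> float:
        return self.center_depth - 0.5 * self.height_z

    @property
    def z_bottom(self) -> float:
        return self.center_depth + 0.5 * self.height_z


class VoxelGrid:
    """Labeled voxel domain: uint8 labels over an (nx, ny, nz) array plus a
    label -> medium map.  Media are any objects with ``name`` and
    ``at(wavelength) -> OpticalProperties``."""

    def __init__(self, labels: np.ndarray, media: list, dx: float, dz: float):
        self.labels = np.ascontiguousarray(labels, dtype=np.uint8)
        self.media = list(media)
        self.dx = float(dx)   # lateral voxel size (x and y), cm
        self.dz = float(dz)   # axial voxel size, cm
        if self.labels.max(initial=0) >= len(self.media):
            raise GeometryError("every label must map to a registered medium")
        self.name_to_label = {m.name: i for i, m in enumerate(self.media)}

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def extent(self) -> tuple[float, float, float]:
        nx, ny, nz = self.labels.shape
        return nx * self.dx, ny * self.dx, nz * self.dz

    @property
    def voxel_volume(self) -> float:
        return self.dx * self.dx * self.dz

    def label_of(self, name: str) -> int:
        return self.name_to_label[name]

    def labels_of(self, names) -> list[int]:
        return [self.name_to_label[n] for n in names]

    def volume_of(self, name: str) -> float:
        """Total voxel volume carrying the named medium, cm^3."""
        return float(np.count_nonzero(self.labels == self.label_of(name))
                     ) * self.voxel_volume

    def props_arrays(self, wavelength_nm: float):
        """Per-label (mu_a, mu_s, g, n) arrays at one wavelength."""
        mu_a = np.empty(len(self.media))
        mu_s = np.empty(len(self.media))
        g = np.empty(len(self.media))
        n = np.empty(len(self.media))
        for i, m in enumerate(self.media):
            p = m.at(wavelength_nm)
            mu_a[i], mu_s[i], g[i], n[i] = p.mu_a, p.mu_s, p.g, p.n
        return mu_a, mu_s, g, n

    def centroid_depth_of(self, name: str) -> float:
        """Volume centroid depth (cm) of the named medium's voxels."""
        iz = np.nonzero(self.labels == self.label_of(name))[2]
        if iz.size == 0:
            raise GeometryError(f"no voxels labeled {name!r}")
        return float((iz.mean() + 0.5) * self.dz)


def _n_voxels(length: float, step: float, what: str) -> int:
    n = length / step
    if abs(n - round(n)) > 1e-6:
        raise DiscretizationError(
            f"{what} ({length} cm) is not an integer multiple of the "
            f"voxel size ({step} cm)")
    return int(round(n))


def build_grid(stack: LayerStack | None = None,
               implant: BarcodeImplant | None = None,
               media: dict | None = None,
               voxel_size: float = 0.005,
               axial_voxel_size: float | None = None,
               lateral_extent: float = 1.5) -> VoxelGrid:
    """Build the voxel grid: layers top-down, implant voxels overwriting.

    ``media`` maps every layer and implant-domain name to a medium object;
    if omitted, the default skin media are built (implant domains must then
    be absent).  Layer boundaries and implant faces must land on voxel
    faces, otherwise a :class:`DiscretizationError` is raised.
    """
    from .optics import default_tissue_media

    stack = stack or LayerStack()
    dx = float(voxel_size)
    dz = float(axial_voxel_size) if axial_voxel_size else dx
    if media is None:
        media = default_tissue_media()

    nx = _n_voxels(lateral_extent, dx, "lateral extent")
    ny = nx
    nz = _n_voxels(stack.total_depth, dz, "total stack depth")

    media_list = []
    name_to_label: dict[str, int] = {}

    def register(name: str) -> int:
        if name not in name_to_label:
            if name not in media:
                raise GeometryError(f"no medium registered for {name!r}")
            name_to_label[name] = len(media_list)
            media_list.append(media[name])
        return name_to_label[name]

    labels = np.zeros((nx, ny, nz), dtype=np.uint8)
    z0 = 0
    for name, t in stack.layers:
        nlay = _n_voxels(t, dz, f"layer {name!r} thickness")
        labels[:, :, z0:z0 + nlay] = register(name)
        z0 += nlay

    if implant is not None:
        if implant.z_top < 0 or implant.z_bottom > stack.total_depth:
            raise GeometryError("implant extends beyond the tissue stack")
        if implant.length_x > lateral_extent or implant.width_y > lateral_extent:
            raise GeometryError("implant extends beyond the lateral extent")
        iz0 = _n_voxels(implant.z_top, dz, "implant top depth")
        izn = _n_voxels(implant.height_z, dz, "implant height")
        iy0 = _n_voxels((lateral_extent - implant.width_y) / 2.0, dx,
                        "implant y offset")
        iyn = _n_voxels(implant.width_y, dx, "implant width")
        ix = _n_voxels((lateral_extent - implant.length_x) / 2.0, dx,
                       "implant x offset")
        for name, length in implant.domain_sequence:
            ixn = _n_voxels(length, dx, f"domain {name!r} length")
            labels[ix:ix + ixn, iy0:iy0 + iyn, iz0:iz0 + izn] = register(name)
            ix += ixn

    return VoxelGrid(labels, media_list, dx, dz)


def move_implant(stack: LayerStack, implant: BarcodeImplant,
                 new_center_depth: float, **build_kwargs) -> VoxelGrid:
    """Rebuild the grid with the implant recentered at ``new_center_depth``."""
    moved = dataclasses.replace(implant, center_depth=new_center_depth)
    return build_grid(stack=stack, implant=moved, **build_kwargs)


def default_stack() -> LayerStack:
    return LayerStack()


def default_implant(center_depth: float = 0.20) -> BarcodeImplant:
    return BarcodeImplant(center_depth=center_depth)
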