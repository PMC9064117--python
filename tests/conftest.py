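import numpy as np
import pytest

from barcodemc.geometry import LayerStack, build_grid
from barcodemc.optics import ConstantMedium
from barcodemc.studies import barcode_grid
from barcodemc.transport import SourceSpec, propagate


@pytest.fixture(scope="session")
def warm_kernel():
    """Compile the transport kernel once for the whole session."""
    media = {"m": ConstantMedium("m", mu_a=1.0, mu_s=0.0, g=0.0)}
    grid = build_grid(stack=LayerStack((("m", 0.1),)), media=media,
                      voxel_size=0.01, lateral_extent=0.1)
    propagate(grid, SourceSpec(wavelength=500.0), n_photons=10, seed=0)
    return True


@pytest.fixture(scope="session")
def coarse_barcode_grid(warm_kernel):
    """Far-red barcode grid at reduced resolution for fast tests."""
    return barcode_grid(680, voxel_size=0.01, lateral_extent=1.0)


@pytest.fixture(scope="session")
def absorbing_slab():
    """Non-scattering absorbing slab, mu_a = 10/cm, 0.2 cm thick."""
    media = {"abs": ConstantMedium("abs", mu_a=10.0, mu_s=0.0, g=0.0)}
    return build_grid(stack=LayerStack((("abs", 0.2),)), media=media,
                      voxel_size=0.01, lateral_extent=0.5)


@pytest.fixture
def pencil_source():
    return SourceSpec(wavelength=500.0, width_x=0.0, width_y=0.0,
                      half_angle=0.0)
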