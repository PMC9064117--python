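import math

import numpy as np
import pytest

from barcodemc.errors import (DegenerateSourceError, InvalidParameterError)
from barcodemc.fluorescence import (EmissionBinPlan, FluorescenceSpectrum,
                                    emission_source_distribution,
                                    modified_quantum_yield, power_yield,
                                    run_emission_bin,
                                    simulate_emission_spectrum)
from barcodemc.geometry import LayerStack, build_grid
from barcodemc.optics import ConstantMedium, LuminophoreSpec
from barcodemc.transport import DetectorSpec, SourceSpec, propagate


class TestBinPlan:
    def test_default_band_resolutions(self):
        # 80 bins over the default bands: 1.8-2.6 nm resolution
        assert 1.8 <= EmissionBinPlan((493.0, 700.0)).resolution <= 2.6
        assert 1.8 <= EmissionBinPlan((700.0, 900.0)).resolution <= 2.6

    def test_centers_inside_band(self):
        plan = EmissionBinPlan((700.0, 900.0), 10)
        assert plan.centers[0] == 710.0 and plan.centers[-1] == 890.0


class TestModifiedQuantumYield:
    def test_uniform_spectrum_splits_evenly(self):
        m = modified_quantum_yield(0.068, np.ones(80))
        assert np.allclose(m, 8.5e-4)

    def test_sum_equals_phi_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            em = rng.random(37)
            m = modified_quantum_yield(0.41, em)
            assert m.sum() == pytest.approx(0.41, rel=1e-14)

    def test_two_bin_hand_example(self):
        m = modified_quantum_yield(0.2, np.array([0.75, 0.25]))
        assert np.allclose(m, [0.15, 0.05])

    def test_zero_spectrum_is_an_error(self):
        with pytest.raises(InvalidParameterError):
            modified_quantum_yield(0.1, np.zeros(10))


class TestPowerYield:
    def test_identity_at_equal_wavelengths(self):
        assert power_yield(0.37, 600.0, 600.0) == pytest.approx(0.37)

    def test_hand_example(self):
        assert power_yield(0.01, 680.0, 850.0) == pytest.approx(0.008)

    def test_zero_m_phi_gives_zero(self):
        assert power_yield(0.0, 680.0, 850.0) == 0.0


def _uniform_grid(mu_a_implant=1.0):
    media = {
        "tissue": ConstantMedium("tissue", mu_a=0.1, mu_s=100.0, g=0.9),
        "lum": ConstantMedium("lum", mu_a=mu_a_implant, mu_s=0.0, g=0.0),
    }
    from barcodemc.geometry import BarcodeImplant
    implant = BarcodeImplant(domain_sequence=(("lum", 0.40),))
    return build_grid(stack=LayerStack((("tissue", 0.40),)), implant=implant,
                      media=media, voxel_size=0.01, lateral_extent=1.0)


class TestEmissionSource:
    def test_absorbed_fraction_matches_tally(self, warm_kernel):
        grid = _uniform_grid()
        res = propagate(grid, SourceSpec(wavelength=680.0),
                        n_photons=50_000, seed=31)
        probs, frac = emission_source_distribution(res, grid, "lum")
        assert frac == pytest.approx(res.absorbed_by_medium["lum"], rel=1e-12)
        assert probs.sum() == pytest.approx(1.0, rel=1e-12)
        # emission only from labeled voxels
        assert probs[grid.labels != grid.label_of("lum")].max() == 0.0

    def test_zero_absorption_degenerate(self, warm_kernel):
        grid = _uniform_grid(mu_a_implant=0.0)
        res = propagate(grid, SourceSpec(wavelength=680.0),
                        n_photons=5_000, seed=32)
        with pytest.raises(DegenerateSourceError):
            emission_source_distribution(res, grid, "lum")

    def test_single_voxel_source(self, warm_kernel):
        grid = _uniform_grid()
        probs = np.zeros(grid.shape)
        probs[50, 50, 20] = 1.0
        # all emission originates from that voxel: with zero-mu_a media the
        # photon's first tallied voxel is the source voxel itself
        media = {"vac": ConstantMedium("vac", mu_a=0.0, mu_s=0.0, g=0.0,
                                       n=1.0)}
        vac = build_grid(stack=LayerStack((("vac", 0.40),)), media=media,
                         voxel_size=0.01, lateral_extent=1.0)
        from barcodemc.transport import propagate_from_distribution
        res = propagate_from_distribution(vac, 800.0, probs,
                                          n_photons=5_000, seed=33)
        assert res.fluence[50, 50, 20] > 0
        assert res.escaped_total == pytest.approx(1.0, abs=1e-12)


class TestRunEmissionBin:
    def test_vacuum_solid_angle_capture(self, warm_kernel):
        """Detected fraction of an isotropic point-like emitter under the
        detector equals the geometric capture fraction (numeric oracle)."""
        media = {"vac": ConstantMedium("vac", mu_a=0.0, mu_s=0.0, g=0.0,
                                       n=1.0)}
        grid = build_grid(stack=LayerStack((("vac", 0.40),)), media=media,
                          voxel_size=0.005, lateral_extent=0.5)
        probs = np.zeros(grid.shape)
        iz = int(0.30 / 0.005)
        probs[50, 50, iz] = 1.0  # voxel centered on the beam axis
        det = DetectorSpec()
        n = 400_000
        got = run_emission_bin(grid, 800.0, probs, det, n_photons=n, seed=34)

        # oracle: sample emitter positions in the voxel and directions
        # uniformly on the sphere, apply the acceptance test analytically
        rng = np.random.default_rng(99)
        m = 2_000_000
        x = -0.25 + (50 + rng.random(m)) * 0.005
        y = -0.25 + (50 + rng.random(m)) * 0.005
        z = (iz + rng.random(m)) * 0.005
        uz = 2 * rng.random(m) - 1
        up = uz < 0  # heading to the surface
        t = z[up] / (-uz[up])
        sint = np.sqrt(1 - uz[up]**2)
        phi = 2 * math.pi * rng.random(up.sum())
        xs = x[up] + sint * np.cos(phi) * t
        ys = y[up] + sint * np.sin(phi) * t
        ok = (xs**2 + ys**2 <= det.radius**2) & (-uz[up] >= det.cos_acceptance)
        expected = ok.sum() / m
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(got - expected) < 3 * se + 3 * math.sqrt(
            expected * (1 - expected) / m)

    def test_doubling_power_yield_doubles_output(self):
        spec = FluorescenceSpectrum(np.array([800.0]), np.array([1e-4]), 0.1)
        assert spec.scaled(2.0).detected_fraction[0] == pytest.approx(2e-4)


class TestSimulateEmissionSpectrum:
    def test_single_nonzero_bin_and_energy_bound(self, warm_kernel):
        grid = _uniform_grid()
        plan = EmissionBinPlan((700.0, 900.0), 5)
        em_wl = np.array([799.0, 800.0, 800.5, 801.0])  # spike at 800 nm
        em = np.array([0.0, 1.0, 1.0, 0.0])
        lum = LuminophoreSpec(quantum_yield=0.2, emission_wavelengths=em_wl,
                              emission_values=em)
        spec = simulate_emission_spectrum(
            grid, "lum", lum, plan, SourceSpec(wavelength=680.0),
            n_photons_excitation=20_000, n_photons_per_bin=5_000, seed=35)
        nz = spec.detected_fraction > 0
        assert nz.sum() == 1  # only the bin containing 790 nm
        assert spec.total <= 0.2 * spec.absorbed_excitation_fraction

    def test_detected_scales_linearly_with_quantum_yield(self, warm_kernel):
        grid = _uniform_grid()
        plan = EmissionBinPlan((700.0, 900.0), 3)
        wl = np.linspace(700, 900, 21)
        em = np.exp(-0.5 * ((wl - 800) / 40) ** 2)
        em /= em.max()
        out = []
        for phi in (0.1, 0.2):
            lum = LuminophoreSpec(quantum_yield=phi, emission_wavelengths=wl,
                                  emission_values=em)
            spec = simulate_emission_spectrum(
                grid, "lum", lum, plan, SourceSpec(wavelength=680.0),
                n_photons_excitation=10_000, n_photons_per_bin=4_000, seed=36)
            out.append(spec.detected_fraction)
        assert np.allclose(out[1], 2.0 * out[0], rtol=1e-12)
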