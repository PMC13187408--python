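"""Fourier-optics core: pupils, PSFs, MTFs and their oracles."""

import numpy as np
import pytest

from metascope.optics import (make_pupil, defocus_phase, mtf_radial,
                              psf_pixel_pitch_um, psf_stack, pupil_to_psf)
from metascope.planner import OpticalConfig


@pytest.fixture(scope="module")
def fine_grid():
    """Heavily padded grid for near-continuum diffraction checks."""
    return make_pupil(512, 1.0, 64.0)


class TestMakePupil:
    def test_mask_area_matches_disk(self):
        g = make_pupil(256, 1.0, 128.0)
        expected = np.pi * 64.0 ** 2
        assert g.mask.sum() == pytest.approx(expected, rel=0.015)

    def test_mask_rotation_symmetry(self, small_grid):
        # rotate about the optical centre (index n//2): use the odd subgrid
        sub = small_grid.mask[1:, 1:]
        np.testing.assert_array_equal(sub, np.rot90(sub))

    def test_rho_is_one_at_aperture_edge(self, small_grid):
        c = small_grid.n // 2
        edge = int(small_grid.aperture_radius_px)
        assert small_grid.rho[c, c + edge] == pytest.approx(1.0)
        assert small_grid.rho[c, c] == 0.0

    def test_pupil_larger_than_grid_rejected(self):
        with pytest.raises(ValueError, match="n\\*ds"):
            make_pupil(64, 1.0, 64.0)
        with pytest.raises(ValueError):
            make_pupil(8, 1.0, 4.0)


class TestDefocusPhase:
    def test_center_zero_edge_psi(self, small_grid):
        phase = defocus_phase(small_grid, 7.3)
        c = small_grid.n // 2
        assert phase[c, c] == 0.0
        edge = int(small_grid.aperture_radius_px)
        assert phase[c, c + edge] == pytest.approx(7.3)

    def test_additivity(self, small_grid):
        np.testing.assert_allclose(
            defocus_phase(small_grid, 1.2) + defocus_phase(small_grid, 2.5),
            defocus_phase(small_grid, 3.7), rtol=1e-12)

    def test_nonfinite_rejected(self, small_grid):
        with pytest.raises(ValueError):
            defocus_phase(small_grid, np.nan)


class TestPupilToPsf:
    def test_unaberrated_peak_at_center_and_unit_sum(self, small_grid):
        psf = pupil_to_psf(small_grid, np.zeros((64, 64)))
        assert psf.sum() == pytest.approx(1.0, rel=1e-12)
        assert np.unravel_index(psf.argmax(), psf.shape) == (32, 32)

    def test_unit_sum_for_any_phase(self, small_grid, rng):
        psf = pupil_to_psf(small_grid, rng.normal(0, 2, (64, 64)))
        assert psf.sum() == pytest.approx(1.0, rel=1e-12)
        assert psf.min() >= 0

    def test_shift_theorem(self, small_grid, rng):
        """One grid-frequency unit of linear ramp circularly shifts the PSF."""
        phase = rng.normal(0, 0.5, (64, 64))
        coords = np.arange(64) - 32
        ramp = 2 * np.pi * coords[None, :] / 64
        psf0 = pupil_to_psf(small_grid, phase)
        psf1 = pupil_to_psf(small_grid, phase + ramp)
        assert np.abs(np.roll(psf0, 1, axis=1) - psf1).max() < 1e-10

    def test_energy_conservation_phase_only(self, small_grid, rng):
        """Unnormalized PSF energy is independent of phase-only modulation."""

        def energy(phase):
            field = np.fft.ifftshift(small_grid.mask * np.exp(1j * phase))
            return float((np.abs(np.fft.fft2(field)) ** 2).sum())

        e0 = energy(np.zeros((64, 64)))
        e1 = energy(rng.normal(0, 3, (64, 64)))
        assert abs(e1 - e0) / e0 < 1e-8

    def test_empty_mask_rejected(self, small_grid):
        import dataclasses
        broken = dataclasses.replace(small_grid,
                                     mask=np.zeros_like(small_grid.mask))
        with pytest.raises(ValueError, match="degenerate"):
            pupil_to_psf(broken, np.zeros((64, 64)))

    def test_fwhm_matches_airy_oracle(self, fine_grid):
        """Unaberrated lateral FWHM ≈ 0.51 λ/NA within 3 %."""
        psf = pupil_to_psf(fine_grid, np.zeros((512, 512)))
        lam_nm, na = 521.0, 0.8
        pitch = psf_pixel_pitch_um(fine_grid, lam_nm, na)
        prof = psf[256]
        half = prof.max() / 2
        above = np.where(prof >= half)[0]
        lo, hi = above[0], above[-1]

        def crossing(i0, i1):
            y0, y1 = prof[i0], prof[i1]
            return i0 + (half - y0) / (y1 - y0) * (i1 - i0)

        fwhm = (crossing(hi, hi + 1) - crossing(lo, lo - 1)) * pitch
        assert fwhm == pytest.approx(0.51 * lam_nm / 1e3 / na, rel=0.03)


class TestMtfRadial:
    def test_dc_bin_is_one(self, small_grid, rng):
        psf = pupil_to_psf(small_grid, rng.normal(0, 1, (64, 64)))
        prof = mtf_radial(psf, small_grid)
        assert prof.values[0] == pytest.approx(1.0, rel=1e-12)
        assert np.all(prof.values >= 0)

    def test_vanishes_beyond_incoherent_cutoff(self, fine_grid):
        """Oracle: the unaberrated MTF is the pupil autocorrelation, which is
        identically zero beyond ρ = 1."""
        psf = pupil_to_psf(fine_grid, np.zeros((512, 512)))
        prof = mtf_radial(psf, fine_grid)
        beyond = prof.values[prof.rho > 1.0 + 1.0 / (2 * fine_grid.aperture_radius_px)]
        assert beyond.max() < 1e-3

    def test_unaberrated_profile_nonincreasing(self, fine_grid):
        psf = pupil_to_psf(fine_grid, np.zeros((512, 512)))
        prof = mtf_radial(psf, fine_grid)
        inside = prof.values[prof.rho <= 1.0]
        assert np.all(np.diff(inside) <= 1.0 / (2 * fine_grid.aperture_radius_px))

    def test_shift_invariance(self, small_grid, rng):
        psf = pupil_to_psf(small_grid, rng.normal(0, 1, (64, 64)))
        shifted = np.roll(psf, (3, -2), axis=(0, 1))
        a = mtf_radial(psf, small_grid).values
        b = mtf_radial(shifted, small_grid).values
        assert np.abs(a - b).max() < 1e-10

    def test_zero_energy_rejected(self, small_grid):
        with pytest.raises(ValueError):
            mtf_radial(np.zeros((64, 64)), small_grid)


@pytest.fixture(scope="module")
def config():
    return OpticalConfig(numerical_aperture=0.8,
                         wavelengths_nm=(521.0, 681.0),
                         pupil_diameter_mm=1.6, nominal_focus_um=3000.0,
                         magnification=40.0, sensor_pitch_um=6.5,
                         sensor_counts=(64, 64), target_dof_um=50.0)


class TestPsfStack:

    def test_zero_modulation_at_focus_is_unaberrated(self, config, small_grid):
        grid = make_pupil(64, 40.0, 1600.0)
        stack = psf_stack(lambda lam: np.zeros((64, 64)), config,
                          [3000.0], grid)
        for il in range(2):
            expected = pupil_to_psf(grid, np.zeros((64, 64)))
            np.testing.assert_allclose(stack.values[0, il], expected,
                                       rtol=1e-12)

    def test_slices_unit_sum_and_defocus_spreads_energy(self, config):
        grid = make_pupil(64, 40.0, 1600.0)
        stack = psf_stack(lambda lam: np.zeros((64, 64)), config,
                          [2975.0, 3000.0, 3025.0], grid)
        sums = stack.values.sum(axis=(2, 3))
        np.testing.assert_allclose(sums, 1.0, rtol=1e-12)
        c = 32
        for il in range(2):
            assert stack.values[1, il, c, c] > stack.values[0, il, c, c]
            assert stack.values[1, il, c, c] > stack.values[2, il, c, c]

    def test_deterministic(self, config):
        grid = make_pupil(64, 40.0, 1600.0)
        a = psf_stack(lambda lam: np.zeros((64, 64)), config, [2980.0], grid)
        b = psf_stack(lambda lam: np.zeros((64, 64)), config, [2980.0], grid)
        assert np.array_equal(a.values, b.values)
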