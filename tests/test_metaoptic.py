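"""Meta-optic parameterization: library, lookup, replication, gradients."""

import numpy as np
import pytest

from metascope.autodiff import Tensor
from metascope.metaoptic import (MetaOpticDesign, flat_pi_widths, load_library,
                                 metaoptic_phase, radial_map, save_library,
                                 surrogate_library, width_to_phase)
from metascope.optics import psf_slice_tensor


class TestSurrogateLibrary:
    def test_zero_width_zero_phase(self, full_library):
        assert np.all(full_library.phases[:, 0] == 0.0)

    def test_phase_strictly_increasing_in_width(self, full_library):
        assert np.all(np.diff(full_library.phases, axis=1) > 0)

    def test_spans_two_pi_at_each_wavelength(self, full_library):
        span = full_library.phases.max(axis=1) - full_library.phases.min(axis=1)
        assert np.all(span >= 2 * np.pi)

    def test_width_outside_period_rejected(self):
        with pytest.raises(ValueError):
            surrogate_library(widths_nm=np.array([0.0, 400.0]),
                              period_nm=350.0)


class TestLibraryIO:
    def test_save_load_round_trip(self, tmp_path, full_library):
        path = tmp_path / "lib.csv"
        save_library(full_library, path)
        loaded = load_library(path)
        np.testing.assert_array_equal(loaded.widths_nm, full_library.widths_nm)
        np.testing.assert_array_equal(loaded.phases, full_library.phases)

    def test_missing_wavelength_column_named(self, tmp_path, full_library):
        path = tmp_path / "lib.csv"
        save_library(full_library, path)
        with pytest.raises(ValueError, match="phase_550"):
            load_library(path, wavelengths_nm=[550.0])

    def test_duplicate_width_rows_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("width_nm, phase_521\n10.0, 0.1\n10.0, 0.2\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_library(path)

    def test_ragged_and_non_numeric_rows_flag_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("width_nm, phase_521\n10.0, 0.1\n20.0\n")
        with pytest.raises(ValueError, match=":3"):
            load_library(path)
        path.write_text("width_nm, phase_521\n10.0, abc\n")
        with pytest.raises(ValueError, match="non-numeric"):
            load_library(path)


class TestWidthToPhase:
    def test_node_and_midpoint_values(self, toy_library):
        lam = 521.0
        w = toy_library.widths_nm
        p = toy_library.phase_row(lam)
        assert width_to_phase(toy_library, np.array([w[3]]), lam)[0] \
            == pytest.approx(p[3], rel=1e-14)
        mid = 0.5 * (w[3] + w[4])
        assert width_to_phase(toy_library, np.array([mid]), lam)[0] \
            == pytest.approx(0.5 * (p[3] + p[4]), rel=1e-12)

    def test_gradient_matches_finite_differences(self, toy_library, rng):
        lam = 681.0
        g0 = rng.uniform(30.0, 320.0, 10)
        t = Tensor(g0.copy(), requires_grad=True)
        width_to_phase(toy_library, t, lam).sum().backward()
        h = 1e-4
        for i in range(10):
            gp, gm = g0.copy(), g0.copy()
            gp[i] += h
            gm[i] -= h
            fd = (width_to_phase(toy_library, gp, lam).sum()
                  - width_to_phase(toy_library, gm, lam).sum()) / (2 * h)
            assert t.grad[i] == pytest.approx(fd, rel=1e-6)


class TestRadialMap:
    def test_constant_vector_constant_map(self, small_grid):
        gamma = np.full(21, 137.0)
        mapped = radial_map(gamma, small_grid)
        assert np.all(mapped[small_grid.mask > 0] == 137.0)

    def test_rotational_symmetry(self, small_grid, rng):
        mapped = radial_map(rng.uniform(50, 300, 21), small_grid)
        masked = mapped * small_grid.mask
        # rotate about the optical centre (index n//2): use the odd subgrid
        sub = masked[1:, 1:]
        np.testing.assert_array_equal(sub, np.rot90(sub))

    def test_linearity(self, small_grid, rng):
        g1 = rng.uniform(0, 1, 21)
        g2 = rng.uniform(0, 1, 21)
        np.testing.assert_allclose(
            radial_map(2.0 * g1 + 3.0 * g2, small_grid),
            2.0 * radial_map(g1, small_grid) + 3.0 * radial_map(g2, small_grid),
            rtol=1e-12)

    def test_perturbation_is_annulus_local(self, small_grid):
        gamma = np.zeros(21)
        base = radial_map(gamma, small_grid)
        gamma2 = gamma.copy()
        gamma2[7] = 1.0
        changed = radial_map(gamma2, small_grid) != base
        bins = small_grid.radial_bin_count(21)
        np.testing.assert_array_equal(changed, bins == 7)


class TestDesign:
    def test_flat_pi_initialization_contract(self, toy_library):
        design = MetaOpticDesign.initialize(21, toy_library, 521.0)
        phi = width_to_phase(toy_library, design.gamma_init, 521.0)
        quantum = np.max(np.abs(np.diff(toy_library.phase_row(521.0))))
        assert np.all(np.abs(phi - np.pi) <= quantum + 1e-9)

    def test_clamping_contract(self, toy_library):
        design = MetaOpticDesign.initialize(21, toy_library, 521.0)
        design.delta_gamma.data[:] = 1e5   # absurd optimizer excursion
        lo, hi = design.width_bounds
        w = design.effective_widths_array()
        assert np.all((w >= lo) & (w <= hi))

    def test_zero_delta_uses_gamma_init(self, toy_library, small_grid):
        design = MetaOpticDesign.initialize(21, toy_library, 521.0)
        phase = metaoptic_phase(design, toy_library, 521.0, small_grid,
                                differentiable=False)
        expected = width_to_phase(
            toy_library, radial_map(design.gamma_init, small_grid), 521.0)
        np.testing.assert_array_equal(phase, expected)

    def test_dispersion_same_widths_different_phase(self, toy_library,
                                                    small_grid):
        design = MetaOpticDesign.initialize(21, toy_library, 521.0)
        p1 = metaoptic_phase(design, toy_library, 521.0, small_grid, False)
        p2 = metaoptic_phase(design, toy_library, 681.0, small_grid, False)
        assert np.abs(p1 - p2).max() > 0.1

    def test_end_to_end_psf_gradient_finite_differences(self, toy_library,
                                                        small_grid, rng):
        """∂(scalar of PSF)/∂Δγ matches central differences on an 8-bin toy."""
        design = MetaOpticDesign.initialize(8, toy_library, 521.0)
        design.delta_gamma.data[:] = rng.normal(0, 1.0, 8)
        w = rng.normal(0, 1, (64, 64))

        def scalar():
            phase = metaoptic_phase(design, toy_library, 521.0, small_grid,
                                    differentiable=True) * small_grid.mask
            return (psf_slice_tensor(phase, small_grid) * Tensor(w)).sum()

        loss = scalar()
        loss.backward()
        g = design.delta_gamma.grad.copy()
        h = 1e-3
        for i in range(8):
            d0 = design.delta_gamma.data.copy()
            design.delta_gamma.data[i] += h
            lp = scalar().item()
            design.delta_gamma.data[...] = d0
            design.delta_gamma.data[i] -= h
            lm = scalar().item()
            design.delta_gamma.data[...] = d0
            fd = (lp - lm) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-12)
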