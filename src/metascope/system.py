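"""Bundle of optical state shared by training and evaluation.

An :class:`ImagingSystem` ties together the optical configuration, the
pupil grid, the unit-cell library and (optionally) a meta-optic design, and
produces depth/wavelength-indexed PSFs either as plain arrays (evaluation)
or as autodiff tensors whose gradients reach the design's Δγ (training).
A system with ``design=None`` is the conventional microscope (zero
modulation phase).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .autodiff import Tensor
from .forward import NoiseConfig
from .metaoptic import MetaOpticDesign, UnitCellLibrary, metaoptic_phase
from .optics import PupilGrid, defocus_phase, psf_slice_tensor, pupil_to_psf
from .planner import OpticalConfig, defocus_coefficient

__all__ = ["ImagingSystem"]


@dataclass
class ImagingSystem:
    config: OpticalConfig
    grid: PupilGrid
    library: UnitCellLibrary
    design: MetaOpticDesign | None
    noise: NoiseConfig
    out_size: int = 512

    def modulation_phase(self, wavelength_nm: float, differentiable: bool):
        if self.design is None:
            zeros = np.zeros((self.grid.n, self.grid.n))
            return Tensor(zeros) if differentiable else zeros
        return metaoptic_phase(self.design, self.library, wavelength_nm,
                               self.grid, differentiable=differentiable)

    def _total_phase(self, z_um: float, wavelength_nm: float,
                     differentiable: bool):
        psi = defocus_coefficient(z_um, self.config.nominal_focus_um,
                                  wavelength_nm, self.config.pupil_diameter_mm)
        df = defocus_phase(self.grid, psi)
        phi_m = self.modulation_phase(wavelength_nm, differentiable)
        if differentiable:
            return phi_m * self.grid.mask + Tensor(df)
        return phi_m * self.grid.mask + df

    def psfs_at_depth(self, z_um: float) -> np.ndarray:
        """(C, n, n) unit-sum PSFs for the current design state (no grads)."""
        return np.stack([
            pupil_to_psf(self.grid, self._total_phase(z_um, lam, False))
            for lam in self.config.wavelengths_nm])

    def psf_tensors_at_depth(self, z_um: float) -> list:
        """Per-channel differentiable PSF tensors at one depth."""
        return [psf_slice_tensor(self._total_phase(z_um, lam, True), self.grid)
                for lam in self.config.wavelengths_nm]

    def conventional(self) -> "ImagingSystem":
        """The same system with the meta-optic removed."""
        return replace(self, design=None)
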