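"""Scalar Fourier-optics core: pupil grids, defocus phase, PSFs and MTFs.

The pupil is sampled on an ``n × n`` grid with pitch ``ds`` (μm).  A pupil
phase ``φ`` maps to an incoherent point spread function through a single
centred discrete Fourier transform, ``PSF ∝ |F{mask · exp(iφ)}|²``, the
standard scalar realization of the wave-optics image-formation model.  The
defocus contribution is the quadratic ``ψ_z ρ²`` with ρ the radius normalized
to 1 at the aperture edge, so the phase at the edge equals the defocus
coefficient ψ_z exactly.

Conventions
-----------
* grid centre at index ``n // 2`` (fftshift convention);
* PSF slices are normalized to unit sum;
* the radial MTF coordinate ρ is normalized to the incoherent cutoff
  ``2 NA / λ``, which on the discrete grid corresponds to a frequency radius
  of twice the aperture radius in samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, psf_intensity
from .planner import OpticalConfig, defocus_coefficient

__all__ = ["PupilGrid", "PSFStack", "MTFProfile", "make_pupil", "defocus_phase",
           "pupil_to_psf", "psf_stack", "mtf_radial", "mtf_bin_rho",
           "psf_slice_tensor", "psf_pixel_pitch_um"]


@dataclass(frozen=True)
class PupilGrid:
    """Discretized circular pupil.

    ``rho`` is the per-pixel radius normalized so that ρ = 1 at the aperture
    edge; ``mask`` is 1 inside the physical aperture (radius ≤ D/2).
    """

    n: int
    ds_um: float
    pupil_diameter_um: float
    rho: np.ndarray = field(repr=False, default=None)
    mask: np.ndarray = field(repr=False, default=None)

    @property
    def aperture_radius_um(self) -> float:
        return self.pupil_diameter_um / 2.0

    @property
    def aperture_radius_px(self) -> float:
        return self.aperture_radius_um / self.ds_um

    def radial_bin_count(self, n_bins: int) -> np.ndarray:
        """Nearest-bin index into a length-``n_bins`` radial vector, per pixel."""
        idx = np.rint(self.rho * (n_bins - 1)).astype(int)
        return np.clip(idx, 0, n_bins - 1)


def make_pupil(n: int, ds_um: float, pupil_diameter_um: float) -> PupilGrid:
    """Build an ``n × n`` pupil grid with sample pitch ``ds`` (μm).

    The pupil must fit inside the grid: ``n · ds > D``.
    """
    if n < 16:
        raise ValueError("grid size n must be >= 16")
    if ds_um <= 0:
        raise ValueError("ds must be positive")
    if pupil_diameter_um >= n * ds_um:
        raise ValueError(
            f"pupil does not fit the grid: require n*ds > D, got "
            f"{n}*{ds_um} = {n * ds_um} <= {pupil_diameter_um}")
    c = n // 2
    coords = (np.arange(n) - c) * ds_um
    xx, yy = np.meshgrid(coords, coords, indexing="xy")
    r = np.hypot(xx, yy)
    half_d = pupil_diameter_um / 2.0
    return PupilGrid(n=n, ds_um=ds_um, pupil_diameter_um=pupil_diameter_um,
                     rho=r / half_d, mask=(r <= half_d).astype(np.float64))


def defocus_phase(grid: PupilGrid, psi_z: float) -> np.ndarray:
    """Quadratic defocus phase ``ψ_z ρ²`` inside the mask, zero outside."""
    if not np.isfinite(psi_z):
        raise ValueError("psi_z must be finite")
    return psi_z * grid.rho ** 2 * grid.mask


def pupil_to_psf(grid: PupilGrid, phase: np.ndarray) -> np.ndarray:
    """Incoherent PSF of a pupil phase: ``|F{mask e^{iφ}}|²``, unit sum.

    The output is zero-frequency-centred on the same ``n × n`` grid.
    """
    if grid.mask.sum() == 0:
        raise ValueError("degenerate pupil: empty aperture mask")
    field_c = np.fft.ifftshift(grid.mask * np.exp(1j * phase))
    amp = np.fft.fft2(field_c)
    intensity = np.fft.fftshift((amp * amp.conj()).real)
    return intensity / intensity.sum()


def psf_pixel_pitch_um(grid: PupilGrid, wavelength_nm: float,
                       numerical_aperture: float) -> float:
    """Object-space PSF pixel pitch from the transform conjugate-grid relation.

    The aperture radius in samples maps to the coherent cutoff NA/λ, so one
    PSF-plane sample spans ``R_px · λ / (n · NA)``.
    """
    lam_um = wavelength_nm / 1e3
    return grid.aperture_radius_px * lam_um / (grid.n * numerical_aperture)


@dataclass
class PSFStack:
    """Depth- and wavelength-indexed PSF stack, each slice unit-sum."""

    values: np.ndarray          # [depth, wavelength, y, x]
    depths_um: list
    wavelengths_nm: list
    pixel_pitch_um: float

    def slice(self, iz: int, il: int) -> np.ndarray:
        return self.values[iz, il]


def psf_stack(phase_provider, config: OpticalConfig, depths_um,
              grid: PupilGrid) -> PSFStack:
    """Simulate PSFs over depths × wavelengths.

    ``phase_provider(wavelength_nm) -> 2-D modulation phase`` supplies the
    meta-optic phase φ^M per wavelength (zero array for a conventional
    system); the depth-dependent defocus ``ψ_z ρ²`` is added per slice.
    """
    depths_um = list(depths_um)
    wavelengths = list(config.wavelengths_nm)
    out = np.empty((len(depths_um), len(wavelengths), grid.n, grid.n))
    for il, lam in enumerate(wavelengths):
        phi_m = phase_provider(lam)
        for iz, z in enumerate(depths_um):
            psi = defocus_coefficient(z, config.nominal_focus_um, lam,
                                      config.pupil_diameter_mm)
            out[iz, il] = pupil_to_psf(grid, defocus_phase(grid, psi) + phi_m)
    pitch = psf_pixel_pitch_um(grid, wavelengths[0], config.numerical_aperture)
    return PSFStack(values=out, depths_um=depths_um,
                    wavelengths_nm=wavelengths, pixel_pitch_um=pitch)


@dataclass
class MTFProfile:
    """DC-normalized radial modulation-transfer profile.

    ``rho`` holds the bin centres in units of the incoherent cutoff 2NA/λ
    (bin width = one transform-frequency sample); values at ρ > 1 are kept so
    that out-of-band leakage can be inspected.
    """

    rho: np.ndarray
    values: np.ndarray


def mtf_bin_rho(grid: PupilGrid) -> tuple:
    """Radial-bin index map and bin centres for the MTF of this grid.

    Frequency-sample radius ``r`` maps to ``ρ = r / (2 R_px)`` where R_px is
    the aperture radius in samples (incoherent cutoff = 2 R_px samples).
    """
    n = grid.n
    f = np.fft.fftfreq(n) * n            # frequency samples, unshifted layout
    fx, fy = np.meshgrid(f, f, indexing="xy")
    r = np.hypot(fx, fy)
    bin_idx = np.rint(r).astype(int)
    n_bins = int(bin_idx.max()) + 1
    rho = np.arange(n_bins) / (2.0 * grid.aperture_radius_px)
    return bin_idx, rho


def mtf_radial(psf_slice: np.ndarray, grid: PupilGrid) -> MTFProfile:
    """Azimuthally averaged, DC-normalized MTF of a unit-sum PSF slice."""
    total = psf_slice.sum()
    if total <= 0:
        raise ValueError("PSF slice has zero total energy")
    otf = np.fft.fft2(np.fft.ifftshift(psf_slice))
    mtf = np.abs(otf) / np.abs(otf[0, 0])
    bin_idx, rho = mtf_bin_rho(grid)
    counts = np.bincount(bin_idx.ravel())
    sums = np.bincount(bin_idx.ravel(), weights=mtf.ravel())
    return MTFProfile(rho=rho, values=sums / counts)


def psf_slice_tensor(phase: Tensor, grid: PupilGrid) -> Tensor:
    """Differentiable unit-sum PSF from a pupil-phase tensor."""
    if grid.mask.sum() == 0:
        raise ValueError("degenerate pupil: empty aperture mask")
    intensity = psf_intensity(phase, grid.mask)
    return intensity / intensity.sum()
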