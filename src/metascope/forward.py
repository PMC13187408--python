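"""Sensor-image synthesis: ``SI_{z,λ} = GT_λ ∗ PSF_{z,λ} + η``.

The ground-truth scene is depth independent; each channel is convolved
(full linear convolution) with the unit-sum PSF of its wavelength at the
assigned depth, centre-cropped to the output size to suppress boundary
artifacts, and sensor noise is added.  Depth schedules are uniform in
diopters (reciprocal distance), matching the linearity of the defocus phase
in 1/z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .autodiff import Tensor, conv_full2d

__all__ = ["ScenePatch", "SensorImage", "NoiseConfig", "render_sensor",
           "render_sensor_tensor", "sample_depths", "add_noise", "center_crop"]


@dataclass
class ScenePatch:
    """Multichannel ground-truth patch, values in [0, 1], shape (C, H, W)."""

    values: np.ndarray
    wavelengths_nm: tuple
    pixel_pitch_um: float = 0.1

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("scene patch must be (channels, H, W)")
        if len(self.wavelengths_nm) != self.values.shape[0]:
            raise ValueError("channel count must match configured wavelengths")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("scene values must lie in [0, 1]")


@dataclass
class SensorImage:
    """Simulated measurement at one depth, same geometry as the scene crop."""

    values: np.ndarray
    wavelengths_nm: tuple
    depth_um: float
    noise: dict = field(default_factory=dict)


@dataclass
class NoiseConfig:
    """Sensor-noise model η.

    ``gaussian``: additive zero-mean Gaussian with std ``sigma`` (normalized
    units).  ``poisson_gaussian``: Poisson shot noise at ``photons`` per unit
    intensity plus the Gaussian read floor.  ``none`` disables noise.
    """

    model: str = "gaussian"
    sigma: float = 0.01
    photons: float = 1000.0
    clip: bool = False

    def __post_init__(self):
        if self.model not in ("none", "gaussian", "poisson_gaussian"):
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def center_crop(img: np.ndarray, size: int) -> np.ndarray:
    h, w = img.shape[-2:]
    if h < size or w < size:
        raise ValueError("image smaller than requested crop")
    top, left = (h - size) // 2, (w - size) // 2
    return img[..., top:top + size, left:left + size]


def add_noise(img: np.ndarray, noise: NoiseConfig,
              rng: np.random.Generator) -> np.ndarray:
    """Seeded, reproducible noise injection; zero-mean models preserve the
    expectation of the clean image."""
    if noise.model == "none" or (noise.model == "gaussian" and noise.sigma == 0):
        out = img.copy()
    elif noise.model == "gaussian":
        out = img + rng.normal(0.0, noise.sigma, img.shape)
    else:  # poisson_gaussian
        counts = rng.poisson(np.maximum(img, 0.0) * noise.photons)
        out = counts / noise.photons + rng.normal(0.0, noise.sigma, img.shape)
    if noise.clip:
        out = np.clip(out, 0.0, 1.0)
    return out


def render_sensor(gt: ScenePatch, psfs: np.ndarray, depth_um: float,
                  out_size: int, noise: NoiseConfig | None = None,
                  rng: np.random.Generator | None = None) -> SensorImage:
    """Render the sensor image of a scene at one depth.

    ``psfs`` is (C, n, n): one unit-sum PSF per channel at this depth.  The
    scene must be at least ``out_size`` on each side; the full convolution is
    centre-cropped to ``out_size``.
    """
    if psfs.shape[0] != gt.values.shape[0]:
        raise ValueError("channel/PSF wavelength mismatch")
    if gt.values.shape[-1] < out_size or gt.values.shape[-2] < out_size:
        raise ValueError("ground truth smaller than requested sensor size")
    chans = [fftconvolve(gt.values[c], psfs[c], mode="full")
             for c in range(psfs.shape[0])]
    img = center_crop(np.stack(chans), out_size)
    meta = {}
    if noise is not None and noise.model != "none":
        if rng is None:
            raise ValueError("noise requested but no rng supplied")
        img = add_noise(img, noise, rng)
        meta = {"model": noise.model, "sigma": noise.sigma}
    return SensorImage(values=img, wavelengths_nm=gt.wavelengths_nm,
                       depth_um=depth_um, noise=meta)


def render_sensor_tensor(gt: np.ndarray, psf_tensors, out_size: int,
                         noise_field: np.ndarray | None = None) -> Tensor:
    """Differentiable render: gradients flow into the per-channel PSF tensors.

    ``gt`` is a fixed (C, H, W) array; ``psf_tensors`` a list of C PSF
    Tensors.  A pre-drawn ``noise_field`` (same shape as the crop) may be
    added so the stochastic part stays outside the graph.
    """
    chans = []
    for c, psf in enumerate(psf_tensors):
        full = conv_full2d(Tensor(gt[c]), psf)
        h = full.shape[0]
        top = (h - out_size) // 2
        chans.append(full[top:top + out_size, top:top + out_size]
                     .reshape(1, out_size, out_size))
    out = concat_channels(chans)
    if noise_field is not None:
        out = out + Tensor(noise_field)
    return out


def concat_channels(chans):
    from .autodiff import concat
    return concat(chans, axis=0)


def sample_depths(k_depths: int, z0_um: float, dof_halfwidth_um: float,
                  mode: str = "grid",
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Depths whose reciprocals are uniform over the target range.

    ``grid``: K reciprocal-space points including both endpoints (K = 1 gives
    the nominal focus); ``random``: K i.i.d. uniform draws in 1/z.
    """
    if k_depths < 1:
        raise ValueError("need at least one depth")
    if dof_halfwidth_um >= z0_um:
        raise ValueError("dof halfwidth must be smaller than nominal focus")
    lo, hi = 1.0 / (z0_um + dof_halfwidth_um), 1.0 / (z0_um - dof_halfwidth_um)
    if mode == "grid":
        if k_depths == 1:
            inv = np.array([1.0 / z0_um])
        else:
            inv = np.linspace(lo, hi, k_depths)
    elif mode == "random":
        if rng is None:
            raise ValueError("random mode requires an rng")
        inv = rng.uniform(lo, hi, k_depths)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return 1.0 / inv
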