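"""Synthetic multispectral fluorescence phantoms and dataset plumbing.

Real training data for this kind of system is a mixed set of multichannel
fluorescence micrographs (epithelial cells labelled for nuclei, cytoskeleton
and membranes) plus a few hyperspectral natural images.  This module
generates structural stand-ins so every stage of the pipeline runs without
downloads: each channel gets a distinct archetype —

* ``nuclei``: soft-edged elliptical blobs,
* ``filaments``: smooth curvilinear networks (high gradient energy),
* ``membranes``: ring/outline structures,
* ``puncta``: sparse bright spots,

all in [0, 1] and deterministic given a seed.  The phantoms reproduce the
*structure* of fluorescence channels, not the photometric statistics of any
real dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .forward import ScenePatch

__all__ = ["PhantomRecipe", "generate_phantom", "band_select", "make_splits",
           "augment", "phantom_stats"]

ARCHETYPES = ("nuclei", "filaments", "membranes", "puncta")


@dataclass
class PhantomRecipe:
    """Recipe for one multichannel phantom patch.

    ``kind='mixed'`` assigns archetype i to channel i (cycling); a single
    archetype name gives every channel that structure.  Densities are object
    counts scaled to a 512×512 reference patch.
    """

    kind: str = "mixed"
    size: int = 512
    channels: int = 4
    wavelengths_nm: tuple = (433.0, 521.0, 601.0, 681.0)
    density: float = 1.0
    contrast: float = 0.9
    seed: int = 0
    background: float = 0.03

    def __post_init__(self):
        if self.kind not in ARCHETYPES + ("mixed",):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if len(self.wavelengths_nm) != self.channels:
            raise ValueError("wavelength list must match channel count")


def _area_scale(size: int) -> float:
    return (size / 512.0) ** 2


def _nuclei(size: int, density: float, rng) -> tuple:
    n_obj = max(1, rng.poisson(25 * density * _area_scale(size)))
    img = np.zeros((size, size))
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(n_obj):
        cy, cx = rng.uniform(0, size, 2)
        a = rng.uniform(0.02, 0.045) * size
        b = a * rng.uniform(0.6, 1.0)
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        r2 = (u / a) ** 2 + (v / b) ** 2
        img += rng.uniform(0.5, 1.0) * np.exp(-r2 ** 2)   # soft plateau edge
    return img, n_obj


def _filaments(size: int, density: float, rng) -> tuple:
    n_obj = max(1, rng.poisson(14 * density * np.sqrt(_area_scale(size))))
    img = np.zeros((size, size))
    n_steps = int(size * 1.5)
    for _ in range(n_obj):
        pos = rng.uniform(0, size, 2)
        heading = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.5, 1.0)
        for _ in range(n_steps):
            heading += rng.normal(0, 0.15)
            pos = pos + np.array([np.cos(heading), np.sin(heading)])
            iy, ix = int(pos[1]) % size, int(pos[0]) % size
            img[iy, ix] = max(img[iy, ix], amp)
    img = gaussian_filter(img, sigma=max(0.8, size / 512.0))
    return img, n_obj


def _membranes(size: int, density: float, rng) -> tuple:
    n_obj = max(1, rng.poisson(12 * density * _area_scale(size)))
    img = np.zeros((size, size))
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(n_obj):
        cy, cx = rng.uniform(0, size, 2)
        r0 = rng.uniform(0.04, 0.10) * size
        width = rng.uniform(0.012, 0.02) * size
        r = np.hypot(xx - cx, yy - cy)
        img += rng.uniform(0.5, 1.0) * np.exp(-((r - r0) / width) ** 2)
    return img, n_obj


def _puncta(size: int, density: float, rng) -> tuple:
    n_obj = max(1, rng.poisson(120 * density * _area_scale(size)))
    img = np.zeros((size, size))
    ys = rng.integers(0, size, n_obj)
    xs = rng.integers(0, size, n_obj)
    img[ys, xs] = rng.uniform(0.5, 1.0, n_obj)
    img = gaussian_filter(img, sigma=1.2)
    if img.max() > 0:
        img = img / img.max()
    return img, n_obj


_GENERATORS = {"nuclei": _nuclei, "filaments": _filaments,
               "membranes": _membranes, "puncta": _puncta}


def generate_phantom(recipe: PhantomRecipe,
                     rng: np.random.Generator | None = None) -> tuple:
    """Generate a phantom patch and per-channel summary statistics.

    Returns ``(ScenePatch, stats)`` where ``stats`` is a list of dicts with
    the archetype, object count, mean intensity and gradient energy of each
    channel.
    """
    rng = rng if rng is not None else np.random.default_rng(recipe.seed)
    chans, stats = [], []
    for c in range(recipe.channels):
        kind = (recipe.kind if recipe.kind != "mixed"
                else ARCHETYPES[c % len(ARCHETYPES)])
        raw, n_obj = _GENERATORS[kind](recipe.size, recipe.density, rng)
        if raw.max() > 0:
            raw = raw / raw.max()
        chan = recipe.background + recipe.contrast * raw
        chan = np.clip(chan, 0.0, 1.0)
        gy, gx = np.gradient(chan)
        stats.append({"archetype": kind, "object_count": int(n_obj),
                      "mean_intensity": float(chan.mean()),
                      "gradient_energy": float(np.mean(gy ** 2 + gx ** 2))})
        chans.append(chan)
    patch = ScenePatch(values=np.stack(chans),
                       wavelengths_nm=tuple(recipe.wavelengths_nm))
    return patch, stats


def phantom_stats(patch: ScenePatch) -> list:
    out = []
    for chan in patch.values:
        gy, gx = np.gradient(chan)
        out.append({"mean_intensity": float(chan.mean()),
                    "gradient_energy": float(np.mean(gy ** 2 + gx ** 2))})
    return out


def band_select(cube: np.ndarray, band_centers_nm,
                target_wavelengths_nm) -> np.ndarray:
    """Pick the hyperspectral band closest to each target wavelength.

    Ties (equidistant bands) break toward the shorter wavelength.  ``cube``
    is (bands, H, W); the result is (len(targets), H, W).
    """
    centers = np.asarray(band_centers_nm, dtype=np.float64)
    if centers.size == 0 or cube.shape[0] != centers.size:
        raise ValueError("cube must have one band per listed center")
    order = np.argsort(centers, kind="stable")
    centers_sorted = centers[order]
    picks = []
    for target in target_wavelengths_nm:
        dist = np.abs(centers_sorted - target)
        picks.append(order[int(np.argmin(dist))])   # argmin: first = shorter λ
    return cube[picks]


def make_splits(n: int, ratios=(0.8, 0.1, 0.1), seed: int = 0) -> tuple:
    """Disjoint, exhaustive index splits by seeded shuffle.

    Sizes follow a floor-then-distribute-remainder rule: each split gets
    ``floor(n * ratio)`` items and the remainder goes to the splits with the
    largest fractional parts (earlier splits win ties).
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    if n < len(ratios):
        raise ValueError("fewer items than splits")
    raw = np.asarray(ratios) * n
    sizes = np.floor(raw).astype(int)
    frac = raw - sizes
    for i in np.argsort(-frac, kind="stable")[: n - sizes.sum()]:
        sizes[i] += 1
    perm = np.random.default_rng(seed).permutation(n)
    out, start = [], 0
    for s in sizes:
        out.append(np.sort(perm[start:start + s]))
        start += s
    return tuple(out)


def augment(patch: np.ndarray, rng: np.random.Generator,
            rotate: bool = True, flip: bool = True,
            brightness: bool = True,
            brightness_range=(0.8, 1.25)) -> np.ndarray:
    """Right-angle rotations, flips and multiplicative brightness jitter.

    Geometric operations are applied identically to every channel so the
    channels never desynchronize; brightness-scaled values are re-clamped to
    [0, 1].
    """
    out = np.asarray(patch)
    if rotate:
        out = np.rot90(out, k=int(rng.integers(0, 4)), axes=(-2, -1))
    if flip:
        if rng.random() < 0.5:
            out = out[..., ::-1]
        if rng.random() < 0.5:
            out = out[..., ::-1, :]
    if brightness:
        out = np.clip(out * rng.uniform(*brightness_range), 0.0, 1.0)
    return np.ascontiguousarray(out)
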