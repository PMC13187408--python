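"""Meta-optic parameterization: nanopillar widths and the spectral lookup.

The meta-optic is a rotationally symmetric array of square dielectric
nanopillars.  Its learnable state is a radial width vector
``γ = γ_init + Δγ`` (nm); a fixed linear replication operator expands γ to
the full 2-D width map, and a differentiable piecewise-linear lookup into a
unit-cell library converts widths to per-wavelength phase delays
``φ^M_λ = Interp(U_γ, U_φλ, γ)``.

The bundled :func:`surrogate_library` is a smooth, monotone effective-index
model of a TiO₂-like pillar (phase ``(2π/λ) h (n_eff(w, λ) − 1)``); users
with electromagnetic unit-cell simulations load their own table with
:func:`load_library`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, gather, interp_lookup
from .optics import PupilGrid

__all__ = ["UnitCellLibrary", "MetaOpticDesign", "surrogate_library",
           "load_library", "save_library", "width_to_phase", "radial_map",
           "metaoptic_phase", "flat_pi_widths"]


@dataclass
class UnitCellLibrary:
    """Tabulated width → per-wavelength phase delays.

    ``widths_nm`` is strictly increasing; ``phases`` has shape
    ``(n_wavelengths, n_widths)`` in radians (unwrapped).
    """

    widths_nm: np.ndarray
    wavelengths_nm: np.ndarray
    phases: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.widths_nm = np.asarray(self.widths_nm, dtype=np.float64)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=np.float64)
        self.phases = np.asarray(self.phases, dtype=np.float64)
        if self.widths_nm.ndim != 1 or len(self.widths_nm) < 2:
            raise ValueError("library needs at least two width entries")
        if np.any(np.diff(self.widths_nm) <= 0):
            raise ValueError("widths must be strictly increasing (no duplicates)")
        if self.phases.shape != (len(self.wavelengths_nm), len(self.widths_nm)):
            raise ValueError("phase table shape must be (n_wavelengths, n_widths)")
        if not (np.all(np.isfinite(self.widths_nm))
                and np.all(np.isfinite(self.phases))):
            raise ValueError("library contains non-finite entries")

    def phase_row(self, wavelength_nm: float) -> np.ndarray:
        match = np.isclose(self.wavelengths_nm, wavelength_nm)
        if not match.any():
            raise KeyError(f"wavelength {wavelength_nm} nm not in library "
                           f"(has {self.wavelengths_nm.tolist()})")
        return self.phases[int(np.argmax(match))]

    @property
    def width_bounds(self) -> tuple:
        return float(self.widths_nm[0]), float(self.widths_nm[-1])


def surrogate_library(widths_nm=None, height_nm: float = 600.0,
                      wavelengths_nm=(433.0, 521.0, 601.0, 681.0),
                      period_nm: float = 350.0,
                      index_a: float = 2.35, index_b_nm2: float = 2.0e4
                      ) -> UnitCellLibrary:
    """Smooth monotone stand-in for an electromagnetic unit-cell sweep.

    The pillar material follows a Cauchy dispersion
    ``n(λ) = A + B/λ²`` (defaults TiO₂-like), and the effective index
    interpolates between air and pillar with a smoothstep in the fill
    fraction ``f = w / period``:

    ``n_eff(w, λ) = 1 + (n(λ) − 1) · f²(3 − 2f)``,
    ``φ(w, λ) = (2π/λ) · h · (n_eff(w, λ) − 1)``.

    Phase is therefore 0 at w = 0 (no pillar) and strictly increasing in w,
    spanning more than 2π at each default wavelength for the default height.
    """
    if widths_nm is None:
        widths_nm = np.linspace(0.0, period_nm, 64)
    widths_nm = np.asarray(widths_nm, dtype=np.float64)
    if np.any(widths_nm < 0) or np.any(widths_nm > period_nm):
        raise ValueError("widths must lie within [0, period]")
    if height_nm <= 0:
        raise ValueError("height must be positive")
    wavelengths_nm = np.asarray(wavelengths_nm, dtype=np.float64)
    f = widths_nm / period_nm
    smooth = f ** 2 * (3.0 - 2.0 * f)
    n_pillar = index_a + index_b_nm2 / wavelengths_nm ** 2
    n_eff = 1.0 + np.outer(n_pillar - 1.0, smooth)
    phases = (2.0 * np.pi / wavelengths_nm)[:, None] * height_nm * (n_eff - 1.0)
    return UnitCellLibrary(widths_nm=widths_nm, wavelengths_nm=wavelengths_nm,
                           phases=phases,
                           metadata={"height_nm": height_nm,
                                     "period_nm": period_nm,
                                     "material": "TiO2-like surrogate"})


def save_library(lib: UnitCellLibrary, path) -> None:
    """Write a library as delimited text: ``width_nm, phase_<λ>, ...``."""
    header = "width_nm, " + ", ".join(
        f"phase_{int(round(w))}" for w in lib.wavelengths_nm)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for i, w in enumerate(lib.widths_nm):
            row = [repr(float(w))] + [repr(float(p)) for p in lib.phases[:, i]]
            fh.write(", ".join(row) + "\n")


def load_library(path, wavelengths_nm=None) -> UnitCellLibrary:
    """Parse a delimited-text unit-cell table written by :func:`save_library`.

    Errors (ragged rows, non-numeric cells, unsorted or duplicate widths,
    missing wavelength columns) are reported with the offending line number.
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    lines = [(i + 1, ln) for i, ln in enumerate(lines) if ln]
    if not lines:
        raise ValueError(f"{path}: empty library file")
    _, header = lines[0]
    cols = [c.strip() for c in header.split(",")]
    if cols[0] != "width_nm":
        raise ValueError(f"{path}:1: first column must be 'width_nm'")
    try:
        file_wavelengths = [float(c.removeprefix("phase_")) for c in cols[1:]]
    except ValueError as exc:
        raise ValueError(f"{path}:1: malformed phase column header") from exc
    if wavelengths_nm is not None:
        for target in wavelengths_nm:
            if not any(abs(target - w) < 0.5 for w in file_wavelengths):
                raise ValueError(
                    f"{path}: missing wavelength column phase_{int(target)}")
    widths, rows = [], []
    for lineno, ln in lines[1:]:
        cells = [c.strip() for c in ln.split(",")]
        if len(cells) != len(cols):
            raise ValueError(f"{path}:{lineno}: expected {len(cols)} cells, "
                             f"got {len(cells)}")
        try:
            vals = [float(c) for c in cells]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric cell") from exc
        widths.append(vals[0])
        rows.append(vals[1:])
    widths = np.asarray(widths)
    if np.any(np.diff(widths) == 0):
        lineno = int(np.argmax(np.diff(widths) == 0)) + 3
        raise ValueError(f"{path}:{lineno}: duplicate width row")
    if np.any(np.diff(widths) < 0):
        lineno = int(np.argmax(np.diff(widths) < 0)) + 3
        raise ValueError(f"{path}:{lineno}: widths not sorted ascending")
    return UnitCellLibrary(widths_nm=widths,
                           wavelengths_nm=np.asarray(file_wavelengths),
                           phases=np.asarray(rows).T)


def width_to_phase(lib: UnitCellLibrary, gamma, wavelength_nm: float):
    """Differentiable spectral lookup: widths (nm) → phases (radians).

    Piecewise-linear interpolation of the library's phase row over its width
    grid; the gradient with respect to γ is the local segment slope.  Accepts
    a numpy array (returns numpy) or a :class:`Tensor` (returns Tensor).
    """
    fp = lib.phase_row(wavelength_nm)
    if isinstance(gamma, Tensor):
        return interp_lookup(gamma, lib.widths_nm, fp)
    return np.interp(np.asarray(gamma, dtype=np.float64), lib.widths_nm, fp)


def radial_map(gamma, grid: PupilGrid, k_rot: int = 1):
    """Expand a radial vector to the full 2-D map (fixed linear operator).

    Every pixel inside the aperture receives the γ entry of its nearest
    radial bin, yielding a rotationally symmetric map; ``k_rot`` is the
    azimuthal replication count, which for a pure radius vector leaves the
    map unchanged and is kept for interface compatibility.  Pixels outside
    the mask receive the innermost entry (they are masked away downstream).
    """
    n_bins = gamma.shape[0] if isinstance(gamma, Tensor) else len(gamma)
    if k_rot < 1:
        raise ValueError("k_rot must be >= 1")
    idx = grid.radial_bin_count(n_bins)
    if isinstance(gamma, Tensor):
        return gather(gamma, idx)
    return np.asarray(gamma)[idx]


@dataclass
class MetaOpticDesign:
    """Learnable meta-optic state: ``γ = clamp(γ_init + Δγ)``.

    ``gamma_init`` is the fixed radial initialization (nm); ``delta_gamma``
    is the learnable perturbation (a :class:`Tensor` with gradients).  Widths
    are clamped to ``width_bounds`` before the lookup so out-of-range values
    never occur, while gradients stay defined during optimization.
    """

    gamma_init: np.ndarray
    delta_gamma: Tensor
    width_bounds: tuple
    k_rot: int = 1

    @classmethod
    def initialize(cls, n_radial: int, lib: UnitCellLibrary,
                   reference_wavelength_nm: float,
                   k_rot: int = 1) -> "MetaOpticDesign":
        """Flat π-phase initialization at the reference wavelength."""
        w_pi = flat_pi_widths(lib, reference_wavelength_nm)
        gamma_init = np.full(n_radial, w_pi)
        # the initialization must sit within one lookup quantum of π phase
        phi = width_to_phase(lib, gamma_init, reference_wavelength_nm)
        quantum = np.max(np.abs(np.diff(lib.phase_row(reference_wavelength_nm))))
        assert np.all(np.abs(phi - np.pi) <= quantum + 1e-9), \
            "flat-pi initialization outside one lookup quantum of pi"
        return cls(gamma_init=gamma_init,
                   delta_gamma=Tensor(np.zeros(n_radial), requires_grad=True),
                   width_bounds=lib.width_bounds, k_rot=k_rot)

    def effective_widths(self) -> Tensor:
        lo, hi = self.width_bounds
        return (self.delta_gamma + self.gamma_init).clamp(lo, hi)

    def effective_widths_array(self) -> np.ndarray:
        lo, hi = self.width_bounds
        return np.clip(self.gamma_init + self.delta_gamma.data, lo, hi)


def flat_pi_widths(lib: UnitCellLibrary, wavelength_nm: float) -> float:
    """Width whose lookup phase is closest to π at the given wavelength."""
    row = lib.phase_row(wavelength_nm)
    fine = np.linspace(lib.widths_nm[0], lib.widths_nm[-1], 4096)
    phi = np.interp(fine, lib.widths_nm, row)
    return float(fine[np.argmin(np.abs(phi - np.pi))])


def metaoptic_phase(design: MetaOpticDesign, lib: UnitCellLibrary,
                    wavelength_nm: float, grid: PupilGrid,
                    differentiable: bool = True):
    """Meta-optic modulation phase φ^M_λ on the pupil grid.

    Composition of clamp(γ_init + Δγ) → radial replication → spectral
    lookup; with ``differentiable=True`` the result is a :class:`Tensor`
    whose gradient flows back to Δγ, otherwise a plain array of the current
    design state.
    """
    if differentiable:
        widths = design.effective_widths()
    else:
        widths = design.effective_widths_array()
    full = radial_map(widths, grid, design.k_rot)
    return width_to_phase(lib, full, wavelength_nm)
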