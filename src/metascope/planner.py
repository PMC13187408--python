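"""Space-bandwidth and Fourier-plane sampling planner.

Before any wave-optics simulation is run, the pupil-plane grid has to be
sized.  Two constraints drive it:

* the space-bandwidth product (SBP) the sensor/objective combination passes,
  ``SBP(λ) = (2 L_x f_pass)(2 L_y f_pass)`` with
  ``f_pass = min(2 NA / λ, M / (2 p))`` — the incoherent cutoff or the camera
  Nyquist frequency mapped to object space, whichever is smaller;
* a phase-sampling bound set by the worst defocus over the target depth range
  at the shortest wavelength: the defocus coefficient
  ``ψ_z = (π/λ)(1/z − 1/z0)(D/2)²`` grows toward the near edge of the range,
  and the critical Fourier-plane pitch is ``Δs_crit = π (D/2) / (8 ψ_max)``.

The planner oversamples the critical pitch by a configurable factor α
(``Δs = Δs_crit / α``) and reports everything in a :class:`SamplingPlan`.

Units: wavelengths in nm, axial distances in μm, pupil diameter in mm,
sensor pitch in μm.  All conversions happen here, once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

__all__ = ["OpticalConfig", "SamplingPlan", "space_bandwidth",
           "defocus_coefficient", "plan_sampling", "fit_defocus_model",
           "default_depth_count"]

NM_PER_UM = 1e3
UM_PER_MM = 1e3


@dataclass(frozen=True)
class OpticalConfig:
    """Physical description of the microscope + meta-optic relay.

    Attributes
    ----------
    numerical_aperture : float
        NA of the objective (dimensionless).
    wavelengths_nm : tuple of float
        Emission channel centers, sorted ascending, in nm.
    pupil_diameter_mm : float
        Entrance-pupil diameter D at the (relayed) Fourier plane, in mm.
    nominal_focus_um : float
        Nominal focus distance z0, in μm (same axial space in which the
        defocus coefficient is evaluated).
    magnification : float
        Total magnification M from object to sensor.
    sensor_pitch_um : float
        Physical sensor pixel pitch p, in μm.
    sensor_counts : (int, int)
        Sensor pixel counts (N_x, N_y).
    immersion_index : float
        Refractive index of the immersion medium.
    target_dof_um : float
        Full target depth-of-field range (symmetric about z0), in μm.
    """

    numerical_aperture: float
    wavelengths_nm: tuple
    pupil_diameter_mm: float
    nominal_focus_um: float
    magnification: float
    sensor_pitch_um: float
    sensor_counts: tuple = (512, 512)
    immersion_index: float = 1.33
    target_dof_um: float = 50.0

    def __post_init__(self):
        object.__setattr__(self, "wavelengths_nm",
                           tuple(float(w) for w in self.wavelengths_nm))
        object.__setattr__(self, "sensor_counts",
                           tuple(int(n) for n in self.sensor_counts))
        if self.numerical_aperture <= 0:
            raise ValueError("numerical_aperture must be > 0")
        if any(w <= 0 for w in self.wavelengths_nm):
            raise ValueError("wavelengths must be positive")
        if list(self.wavelengths_nm) != sorted(self.wavelengths_nm):
            raise ValueError("wavelengths must be sorted ascending")
        if self.pupil_diameter_mm <= 0:
            raise ValueError("pupil_diameter_mm must be > 0")
        if self.sensor_pitch_um <= 0:
            raise ValueError("sensor_pitch_um must be > 0")
        if any(n < 1 for n in self.sensor_counts):
            raise ValueError("sensor counts must be >= 1")
        if self.nominal_focus_um <= self.target_dof_um / 2:
            raise ValueError("nominal focus must exceed half the target DoF "
                             "(defocus coefficient finite across the range)")

    @classmethod
    def from_yaml(cls, path) -> "OpticalConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SamplingPlan:
    """Result of :func:`plan_sampling`."""

    psi_max: float                       # radians, worst defocus over the range
    ds_crit_um: float                    # critical Fourier-plane pitch
    ds_um: float                         # chosen pitch = ds_crit / alpha
    alpha_oversample: float
    sbp_per_wavelength: list = field(default_factory=list)
    sbp_total: float = 0.0
    alpha_sbp_ratio: float = 0.0         # diagnostic: SBP_total / SBP(λ_min)
    threefold_margin: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def space_bandwidth(config: OpticalConfig, wavelength_nm: float) -> float:
    """Space-bandwidth product passed by the system at one wavelength.

    ``SBP = (2 L_x f_pass)(2 L_y f_pass)`` with the passed bandwidth
    ``f_pass = min(f_c, f_Nyq,obj)``, ``f_c = 2 NA / λ`` the incoherent cutoff
    and ``f_Nyq,obj = M / (2 p)`` the camera Nyquist frequency mapped to
    object space; ``L_{x,y} = N_{x,y} p / M`` is the object-space field of view.
    """
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    lam_um = wavelength_nm / NM_PER_UM
    f_c = 2.0 * config.numerical_aperture / lam_um           # cycles/μm
    f_nyq = config.magnification / (2.0 * config.sensor_pitch_um)
    f_pass = min(f_c, f_nyq)
    L = (np.asarray(config.sensor_counts, dtype=float)
         * config.sensor_pitch_um / config.magnification)     # μm
    return float((2.0 * L[0] * f_pass) * (2.0 * L[1] * f_pass))


def defocus_coefficient(z_um: float, z0_um: float, wavelength_nm: float,
                        pupil_diameter_mm: float) -> float:
    """Quadratic pupil-phase defocus coefficient ψ_z (radians).

    ``ψ_z = (π/λ)(1/z − 1/z0)(D/2)²``.  The sign is preserved: depths beyond
    the nominal focus give negative ψ.
    """
    if z_um == 0:
        raise ValueError("invalid depth z = 0")
    if z_um < 0 or z0_um <= 0:
        raise ValueError("depths must be positive")
    lam_um = wavelength_nm / NM_PER_UM
    half_d_um = pupil_diameter_mm * UM_PER_MM / 2.0
    return float(np.pi / lam_um * (1.0 / z_um - 1.0 / z0_um) * half_d_um ** 2)


def plan_sampling(config: OpticalConfig, dof_halfwidth_um: float,
                  alpha_oversample: float = 4.0) -> SamplingPlan:
    """Size the Fourier-plane grid for a symmetric depth range z0 ± Δ.

    The worst-case defocus ψ_max is taken as the larger of |ψ| at the two
    range edges, evaluated at the shortest wavelength (where ψ is largest);
    the critical pitch ``Δs_crit = π (D/2) / (8 ψ_max)`` is then oversampled
    by α.  α is an independent configuration scalar; the ratio
    ``SBP_total / SBP(λ_min)`` it nominally corresponds to is reported as a
    diagnostic only.
    """
    z0 = config.nominal_focus_um
    if dof_halfwidth_um >= z0:
        raise ValueError("dof_halfwidth must be smaller than the nominal focus")
    if alpha_oversample < 1:
        raise ValueError("alpha_oversample must be >= 1")
    lam_min = min(config.wavelengths_nm)
    psi_near = defocus_coefficient(z0 - dof_halfwidth_um, z0, lam_min,
                                   config.pupil_diameter_mm)
    psi_far = defocus_coefficient(z0 + dof_halfwidth_um, z0, lam_min,
                                  config.pupil_diameter_mm)
    psi_max = max(abs(psi_near), abs(psi_far))
    half_d_um = config.pupil_diameter_mm * UM_PER_MM / 2.0
    ds_crit = np.pi * half_d_um / (8.0 * psi_max)
    ds = ds_crit / alpha_oversample
    sbp = [space_bandwidth(config, w) for w in config.wavelengths_nm]
    total = float(sum(sbp))
    ratio = total / sbp[0]
    return SamplingPlan(psi_max=float(psi_max), ds_crit_um=float(ds_crit),
                        ds_um=float(ds), alpha_oversample=float(alpha_oversample),
                        sbp_per_wavelength=sbp, sbp_total=total,
                        alpha_sbp_ratio=float(ratio),
                        threefold_margin=bool(alpha_oversample > 3.0))


def fit_defocus_model(pairs: Sequence[tuple]) -> tuple:
    """Recover (z0, C) of ``ψ_max(Δ) = C Δ / (z0 (z0 − Δ))`` from two pairs.

    The worst case over a symmetric range z0 ± Δ sits at the near edge
    z = z0 − Δ, where ``ψ = C (1/(z0−Δ) − 1/z0) = C Δ / (z0 (z0 − Δ))`` with
    ``C = (π/λ)(D/2)²``.  Two (Δ, ψ_max) pairs with distinct Δ determine the
    model uniquely; forward re-evaluation reproduces the inputs to machine
    precision.

    Returns
    -------
    (z0, C) : floats
        Nominal focus (same length unit as Δ) and curvature constant
        (dimensionless · length).
    """
    if len(pairs) != 2:
        raise ValueError("exactly two (halfwidth, psi_max) pairs required")
    (d1, p1), (d2, p2) = pairs
    if d1 == d2:
        raise ValueError("degenerate system: equal half-widths")
    if p1 <= 0 or p2 <= 0 or d1 <= 0 or d2 <= 0:
        raise ValueError("degenerate system: non-positive entries")
    r = p1 / p2
    denom = r * d2 - d1
    if denom == 0:
        raise ValueError("degenerate system: inconsistent pairs")
    z0 = d1 * d2 * (r - 1.0) / denom
    if z0 <= max(d1, d2):
        raise ValueError("degenerate system: recovered focus inside the range")
    C = p1 * z0 * (z0 - d1) / d1
    return float(z0), float(C)


def eval_defocus_model(z0: float, C: float, halfwidth) -> float:
    """Forward model of :func:`fit_defocus_model`: worst-case ψ at z0 − Δ."""
    hw = np.asarray(halfwidth, dtype=float)
    return C * hw / (z0 * (z0 - hw))


def default_depth_count(target_dof_um: float) -> int:
    """Number of discrete training depths for a target depth-of-field range.

    Five depths suffice up to 50 μm targets; 75 μm targets use seven — a few
    well-spaced planes already cover the intermediate depths, and denser
    sampling only adds redundant targets.
    """
    return 5 if target_dof_um <= 50.0 else 7
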