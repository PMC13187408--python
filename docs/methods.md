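# Methods

This note records the modelling assumptions, parameter choices and numerical
conventions behind `metascope`, and what the desk-scale benchmark does and
does not demonstrate.

## Optical model and its assumptions

The simulator is a scalar Fourier-optics model: a single discrete Fourier
transform maps the complex pupil field `mask · exp(iφ)` to the incoherent
PSF `|F{·}|²`, normalized to unit sum per (depth, wavelength) slice. This
carries the standard assumptions of wavefront-coding analyses:

* **Scalar diffraction.** Vectorial high-NA effects (polarization mixing,
  apodization of the marginal rays) are not modelled; the pupil phase is
  the only degree of freedom.
* **Shift invariance.** One PSF per (z, λ) describes the whole field of
  view; field-dependent aberrations are out of scope.
* **Incoherent, depth-independent scenes.** A fluorescent plane at depth z
  is blurred by `PSF_{z,λ}`; the ground truth itself does not change with
  z (thin-object approximation at each assigned depth).
* **Defocus as a quadratic pupil phase.** `ψ_z ρ²` with
  `ψ_z = (π/λ)(1/z − 1/z0)(D/2)²` and ρ = 1 at the aperture edge, so the
  edge phase equals the defocus coefficient exactly. The worst case over a
  symmetric range z0 ± Δ sits at the near edge z0 − Δ, and a target "DoF of
  50 μm" always means the symmetric range z0 ± 25 μm.

Grid conventions: the pupil centre sits at index `n//2` (fftshift
convention); rotational-symmetry statements therefore refer to rotation
about that pixel, which on an even grid is the odd subgrid `[1:, 1:]`. The
PSF-plane pixel pitch follows the conjugate-grid relation
`R_px · λ / (n · NA)` with `R_px` the aperture radius in samples, and the
radial MTF coordinate is normalized so that the incoherent cutoff `2NA/λ`
corresponds to a frequency radius of `2 R_px` samples. Radial MTF bins are
one frequency sample wide, azimuthally averaged over annuli; bins beyond
ρ = 1 are retained so out-of-band leakage can be checked.

## Sampling planner

Two printed-table reconciliations are built in as design choices rather
than derived outputs:

* The oversampling factor α is an **independent configuration scalar**
  (default 4). Its nominal definition `SBP_total / SBP(λ_min)` evaluates to
  ≈ 2.96 for the reference configuration, which contradicts the stated
  operating point α = 4; the ratio is therefore exposed only as the
  diagnostic `alpha_sbp_ratio`, and the `threefold_margin` flag simply
  records α > 3.
* Published Δs values for different DoF targets are mutually inconsistent
  with a single pupil diameter under `Δs = Δs_crit/α` (they appear snapped
  to a fabrication pitch); the planner always reports its own computed Δs.

`fit_defocus_model` inverts the worst-case law `ψ_max(Δ) = CΔ/(z0(z0−Δ))`
from exactly two (Δ, ψ_max) pairs in closed form. Whether the axial
distances live in object space or relayed image space is absorbed into the
fitted (z0, C) and never needs to be resolved.

## Meta-optic parameterization

The design state is a radial width vector (nm) with fixed initialization
and learnable perturbation, `γ = clamp(γ_init + Δγ)`; clamping (not
erroring) keeps gradients defined when the optimizer momentarily leaves the
library's width span. The 2-D width map assigns each pupil pixel the γ
entry of its nearest radial bin — a fixed linear operator, fully
rotationally symmetric. An azimuthally sectorized (K-fold, non-symmetric)
replication would be a straightforward variant but is deliberately not
implemented; the radius-vector parameterization makes the rotationally
symmetric reading the natural one.

The width → phase lookup is **piecewise linear**: the simplest
interpolation whose gradient is exact (the local segment slope), which
keeps the finite-difference checks tight. Phases are kept unwrapped so the
lookup stays smooth; 2π-wrapping would only matter when exporting a
fabrication mask.

The bundled surrogate unit-cell library uses a Cauchy-dispersive TiO₂-like
pillar index `n(λ) = 2.35 + 2·10⁴/λ²` (λ in nm), height 600 nm, period
350 nm, and a smoothstep fill-factor effective-index model
`n_eff = 1 + (n(λ) − 1)·f²(3 − 2f)`, `f = w/period`. These values were
chosen so that the phase span exceeds 2π at every emission channel
(433–681 nm) with zero phase at zero width — the qualitative shape of an
electromagnetic unit-cell sweep, not a replacement for one. Users with
real sweeps load them as delimited text (`width_nm, phase_<λ>, …`).

The flat-π initialization picks the width whose lookup phase at the
reference (shortest) wavelength is closest to π; construction asserts the
result is within one lookup quantum of π at every radius. A cubic-phase
initialization is intentionally not offered as a default: under defocus
coefficients of order 10²–10³ rad it produces sensor images too blurred to
carry gradient signal.

## EDoF pre-optimization

Per wavelength, depth errors `‖M_λ(·,z) − T‖₁` (bin-averaged, so the loss
scale is grid-independent) are pooled as
`(1/β) log Σ_z exp(α·err_z)`; α appears inside the exponent and 1/β outside
to match the printed operator, with α = β by default so the pooling is a
standard soft-max. Channel pooling adds weight λ_focus on the current
worst channel. Defaults — ρ_cut = 0.5, α = β = 50, η = 10,
λ_focus = 0.5, 30 epochs, Adam on Δγ with lr 2 nm — are declared choices
(no published values exist for them); α = β = 50 puts the depth pooling
firmly in its worst-case-depth regime for errors of order 0.1–1.

## Forward model and noise

Sensor rendering is a full linear convolution with the unit-sum PSF,
centre-cropped so boundary artifacts never reach the network (ground-truth
patches are generated larger than the sensor crop by the PSF support).
Sensor noise η has no published distribution; the default is additive
Gaussian with σ = 0.01 in normalized intensity units, with an optional
Poisson–Gaussian mode (configurable photon scaling). Post-noise values are
not clipped before the network — the input instance normalization handles
range — and clipping is exposed as a flag.

Depth schedules are uniform in diopters (reciprocal distance), the natural
spacing because ψ_z is linear in 1/z: grid mode includes both range
endpoints, random mode draws i.i.d. uniform in 1/z. Five training depths
serve targets up to 50 μm and seven serve 75 μm; evaluation uses 41
diopter-uniform planes.

## Reconstruction network

As described in the README; the choices that were genuinely open:

* The residual head's final 1×1 convolution is **zero-initialized**, so the
  network is exactly `clamp(input)` at initialization — training starts
  from the identity map, which stabilizes the early co-design steps when
  the optic is still moving.
* The Fourier-domain attention block pools each channel's DFT magnitude
  with a log-mean, then applies a weight-shared two-layer bottleneck to
  (own statistic, cross-channel mean) followed by a sigmoid. Weight
  sharing makes the block permutation-equivariant: identical channels are
  guaranteed identical gates, and gates live strictly inside (0, 1). An ε
  inside the log guards all-zero channels.
* Instance normalization at the input (per channel, no affine), batch
  normalization inside the convolution blocks.

## Losses and training

Multi-term loss weights (w_RMSE, w_SSIM, w_grad, w_LP) = (1.0, 0.2, 0.1,
0.1): RMSE dominates, the rest act as structural/edge/coarse-content
regularizers. The low-pass filter is Gaussian with kernel size 9 and
σ = k/6 = 1.5. The differentiable SSIM term and the evaluation SSIM metric
both use the conventional formulation — 11×11 Gaussian window, σ = 1.5,
stabilizers (0.01·R)², (0.03·R)² at data range 1, population statistics,
valid-region averaging — and the evaluation implementation agrees with
scikit-image's to 1e-6 in the test suite. PSNR of identical images is
reported as +inf and excluded from depth averages.

The L2 penalty `β‖θ_deblur‖²` is applied as classic weight decay in the
network's Adam optimizer (gradient + 2βθ); the optical optimizer never
receives decay. Data augmentation uses right-angle rotations, flips, and
multiplicative brightness in [0.8, 1.25] with re-clamping; right angles
avoid interpolation artifacts against the [0, 1] bound, and a free-angle
mode is deliberately left out of the default path.

## Synthetic phantoms

The phantom generator replaces both the real fluorescence dataset and the
hyperspectral natural-image supplement for testing. Channels get
structurally distinct archetypes (soft elliptical nuclei blobs, smoothed
random-walk filament networks, ring-like membranes, sparse puncta) in
[0, 1], deterministic per seed, with per-channel object counts and gradient
energies returned as summary statistics; filament channels verifiably carry
more gradient energy than nuclei channels, which is the property the
spectral-attention and per-channel metrics need to be exercised against.
The phantoms emulate channel-distinct *structure* only — they do not
reproduce real staining photometry, optical sectioning statistics, sample
autofluorescence, or the spatial correlations of confluent cell layers, so
green results on phantoms demonstrate pipeline correctness and the
co-design effect, not clinical-grade restoration quality on real tissue.

## Desk-scale benchmark sizes

The co-design benchmark (`metascope.experiments.toy_codesign`) runs at
64×64 pixels, two channels (521/681 nm), a 64-sample pupil grid with a
20-sample aperture radius (D = 1.6 mm at 40 μm pitch), nominal focus 3 mm
and a 50 μm toy DoF — edge defocus ψ ≈ 10.8 rad at 521 nm, strong enough
that conventional imaging visibly degrades at the range edges while the
pupil phase stays adequately sampled on this grid. Three diopter-uniform
training depths, 30 pretraining epochs, 300 end-to-end steps, reduced
network widths (8, 16, 32), and scaled-up learning rates (optical 0.2 nm,
network 1e-3) are the package's own benchmark sizing: the full-scale
defaults (widths 32–128, lr 1e-2/1e-4) are kept on `ReconstructorSpec` and
`TrainConfig`, but at a few hundred steps those rates cannot produce
measurable learning. Evaluation uses nine diopter-uniform planes and three
held-out phantoms per seed. All randomness flows from explicit
`numpy.random.Generator` seeds; reruns are bit-identical.

## Numerical choices and degenerate inputs

* Everything is float64; the autodiff graph is freed after each backward.
* `max_pool2x2` breaks ties toward the first element of the window;
  PSF/MTF radial bins use round-to-nearest with clipping at the outermost
  bin; interp outside the table span has zero slope (inputs are clamped
  before lookup anyway).
* Degenerate inputs raise informative errors: empty pupil masks, pupils
  larger than their grid, zero-energy PSF slices, equal-halfwidth defocus
  fits, ragged or unsorted unit-cell tables (with line numbers), noise
  σ < 0, DoF half-widths ≥ nominal focus.
* Non-finite losses abort training with the offending step or (z, λ) pair
  named.

## Known limitations

* The scalar single-transform PSF model ignores vectorial high-NA effects
  precisely in the NA regime where they begin to matter; measured-PSF
  calibration would be needed before trusting absolute widths at NA > 1.
* The surrogate unit-cell library is a smooth monotone stand-in; real
  nanopillar phase responses have resonances the lookup would faithfully
  interpolate but the surrogate cannot produce.
* The benchmark's PSNR/SSIM numbers quantify the co-design effect at toy
  scale; they are not comparable to full-scale results trained for days on
  real micrographs.
* Fabrication-robustness analysis (geometry perturbations of the realized
  meta-optic) is out of scope.
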