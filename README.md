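# metascope

Co-design toolkit for **extended depth-of-field (EDoF) multispectral
fluorescence microscopy** with a learned meta-optic and a neural
reconstruction network.

High-NA fluorescence microscopes resolve subcellular detail but their depth
of field collapses as `DoF ∝ λ / NA²` — at NA 1.1 only a micron-scale slice
of a thick specimen is sharp, and chromatic dispersion shifts the best-focus
plane between emission channels. `metascope` implements the computational
alternative to axial scanning: a phase-coding meta-optic at a relayed
Fourier plane deliberately reshapes the point spread function (PSF) so that
sensor measurements stay informative across depth and wavelength, and a
convolutional network restores sharp, channel-registered images from a
single exposure. Optic and network are optimized **jointly** through a
differentiable scalar wave-optics forward model.

Intended users: computational-imaging and microscopy researchers who want a
desk-scale, fully inspectable implementation of the co-design recipe —
sampling planner, Fourier-optics PSF simulator, differentiable nanopillar
width → phase lookup, MTF-guided pre-optimization, end-to-end training, and
the matching evaluation harness — all runnable on a CPU with synthetic
fluorescence phantoms.

## The model

**Forward model.** A ground-truth scene `GT_λ` at depth `z` forms the
sensor image

```
SI_{z,λ} = GT_λ ∗ PSF_{z,λ} + η
```

where the PSF comes from the pupil phase `φ_{z,λ} = ψ_z ρ² + φ^M_λ`: a
quadratic defocus term with coefficient

```
ψ_z = (π/λ) (1/z − 1/z0) (D/2)²
```

(`D` pupil diameter, `z0` nominal focus, ρ the pupil radius normalized to
the aperture edge) plus the meta-optic modulation `φ^M_λ`, obtained from
the learnable radial nanopillar-width vector `γ = γ_init + Δγ` through a
piecewise-linear spectral lookup into a unit-cell library,
`φ^M_λ = Interp(U_γ, U_φλ, γ)`. `PSF_{z,λ} = |F{mask · e^{iφ}}|²`.

**Sampling planner.** The pupil grid pitch is bounded by the worst defocus
at the shortest wavelength, `Δs_crit = π(D/2) / (8 ψ_max)`, oversampled by a
factor α (default 4); the space-bandwidth product
`SBP(λ) = (2 L_x f_pass)(2 L_y f_pass)` with
`f_pass = min(2NA/λ, M/2p)` sizes the simulation per channel.

**EDoF pre-optimization.** Before joint training the optic alone minimizes
a frequency-domain objective: per wavelength, the bin-averaged ℓ₁ distance
between the DC-normalized radial MTF `M_λ(ρ, z)` and an ideal passband
`T(ρ)` is pooled over depths with a log-sum-exp (large sharpness → the most
defocused plane dominates), and channels are pooled with extra weight on
the currently limiting wavelength.

**End-to-end training.** The joint objective is `J = L + β‖θ_deblur‖²`
where `L` averages, over the depth/channel set, a fixed multi-term
reconstruction loss — RMSE + (1 − SSIM) + finite-difference gradient
matching + low-pass MSE. Two Adam optimizers run side by side: optical
parameters (lr 1e-2, never regularized) and network parameters (lr 1e-4,
weight decay 1e-3). Training depths are spaced uniformly in diopters (1/z).

**Reconstruction network.** Three-level encoder–decoder (feature widths
32→64→128) with per-channel instance normalization, an identity-initialized
1×1 spectral mixing layer, Fourier-domain channel attention (omitted for
single-channel variants), batch-normalized double convolutions, bilinear
upsampling with skip connections, and a residual `tanh` head clamped to
[0, 1].

Because no GPU autodiff framework is assumed, the package ships its own
compact reverse-mode autodiff engine (`metascope.autodiff`, numpy-based)
whose every custom operation — FFT-based PSF formation, spectral lookup,
convolutional rendering, network layers — is verified against central
finite differences in the test suite.

## Worked example

Plan the Fourier-plane sampling for a 50 μm target DoF at NA 1.1
(configuration in `examples` style YAML; values in nm/μm/mm):

```
$ metascope plan --config optcfg.yaml --dof 50 --alpha 4
psi_max: 221.32049862268389
ds_crit_um: 5.855340909090867
ds_um: 1.4638352272727166
alpha_oversample: 4.0
sbp_per_wavelength: [4194304.0, 3510864.1368760713, 2638399.3183235317, 2054921.5483358412]
sbp_total: 12398489.003535444
alpha_sbp_ratio: 2.956030131229268
threefold_margin: True
```

Reading: the worst-case defocus coefficient across z0 ± 25 μm is
ψ_max ≈ 221.3 rad at 433 nm, so the critical pupil pitch is 5.86 μm and the
α = 4 operating point samples at 1.46 μm; the system passes ≈ 4.2M
resolvable samples at 433 nm (Nyquist-limited) falling to ≈ 2.05M at
681 nm, 12.4M total.

The worst-case defocus model `ψ_max(Δ) = CΔ/(z0(z0−Δ))` is invertible from
two (DoF, ψ_max) pairs and predicts a third:

```python
>>> from metascope import fit_defocus_model
>>> from metascope.planner import eval_defocus_model
>>> z0, C = fit_defocus_model([(12.5, 110.20), (25.0, 221.32)])
>>> round(eval_defocus_model(z0, C, 37.5), 4)
333.3716
```

Pre-optimize the toy meta-optic (two channels, three depths, 30 epochs):

```
$ metascope pretrain --seed 0 --out design.json
seed=0 loss 0.4875 -> 0.4644
design written to design.json
```

The across-depth spread of the MTF-vs-passband error drops from 0.092
(flat-π start) to 0.029 after pre-optimization — the optic's contrast
transfer has become nearly depth-invariant. Running the full scaled-down
co-design benchmark (`metascope train --seed 1 --out run/`) then yields
depth-averaged PSNR ≈ 30 dB for the co-designed system versus ≈ 29 dB for
a network behind a conventional (unmodulated) microscope and ≈ 27 dB for
the pre-optimized optic without a network, with the co-designed system's
PSNR varying roughly half as much across depth as the conventional arm's —
the co-design advantage this package exists to demonstrate.

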