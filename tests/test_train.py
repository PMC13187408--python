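"""Losses, metrics, FWHM metrology, sweeps and the training loop contracts."""

import numpy as np
import pytest

from metascope.autodiff import Tensor
from metascope.experiments import toy_patch_source, toy_system
from metascope.forward import sample_depths
from metascope.reconstructor import ReconstructorSpec, build_reconstructor
from metascope.train import (FWHM_PER_SIGMA, LossWeights, TrainConfig,
                             depth_sweep, diopter_planes, fwhm_gaussian_fit,
                             make_optimizers, psnr, recon_loss, ssim,
                             train_end_to_end)


class TestReconLoss:
    def test_zero_iff_equal(self, rng):
        x = rng.uniform(0, 1, (2, 3, 32, 32))
        assert recon_loss(Tensor(x), Tensor(x.copy())).item() == 0.0
        y = np.clip(x + 0.01, 0, 1)
        assert recon_loss(Tensor(x), Tensor(y)).item() > 0.0

    def test_rmse_only_weights(self, rng):
        x = rng.uniform(0, 1, (1, 1, 16, 16))
        y = rng.uniform(0, 1, (1, 1, 16, 16))
        w = LossWeights(w_rmse=1.0, w_ssim=0.0, w_grad=0.0, w_lp=0.0)
        expected = np.sqrt(np.mean((x - y) ** 2))
        assert recon_loss(Tensor(x), Tensor(y), w).item() == pytest.approx(
            expected, rel=1e-12)

    def test_constant_offset_closed_forms(self):
        """Images differing by a constant d: RMSE term d, gradient term 0,
        low-pass MSE term d²."""
        d = 0.125
        x = np.full((1, 1, 32, 32), 0.25)
        y = x + d
        rmse_only = LossWeights(1.0, 0.0, 0.0, 0.0)
        grad_only = LossWeights(1e-12, 0.0, 1.0, 0.0)
        lp_only = LossWeights(1e-12, 0.0, 0.0, 1.0)
        assert recon_loss(Tensor(x), Tensor(y), rmse_only).item() \
            == pytest.approx(d, rel=1e-12)
        assert recon_loss(Tensor(x), Tensor(y), grad_only).item() \
            == pytest.approx(0.0, abs=1e-10)
        assert recon_loss(Tensor(x), Tensor(y), lp_only).item() \
            == pytest.approx(d ** 2, rel=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            recon_loss(Tensor(np.zeros((1, 1, 8, 8))),
                       Tensor(np.zeros((1, 1, 8, 9))))

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(0.0, 0.0, 0.0, 0.0)


class TestMetrics:
    def test_psnr_closed_form_and_sentinel(self):
        a = np.zeros((10, 10))
        b = np.full((10, 10), 0.1)   # MSE = 0.01
        assert psnr(a, b) == pytest.approx(20.0, rel=1e-12)
        assert psnr(a, a) == float("inf")

    def test_ssim_identity_and_symmetry(self, rng):
        a = rng.uniform(0, 1, (32, 32))
        b = np.clip(a + rng.normal(0, 0.05, a.shape), 0, 1)
        assert ssim(a, a) == pytest.approx(1.0, abs=1e-12)
        assert ssim(a, b) == pytest.approx(ssim(b, a), rel=1e-12)

    def test_agreement_with_reference_implementation(self, rng):
        """PSNR/SSIM match scikit-image on 20 random pairs to 1e-6."""
        from skimage.metrics import (peak_signal_noise_ratio,
                                     structural_similarity)
        for _ in range(20):
            a = rng.uniform(0, 1, (48, 48))
            b = np.clip(a + rng.normal(0, rng.uniform(0.01, 0.2), a.shape),
                        0, 1)
            assert psnr(a, b) == pytest.approx(
                peak_signal_noise_ratio(a, b, data_range=1.0), abs=1e-6)
            ref = structural_similarity(a, b, win_size=11,
                                        gaussian_weights=True, sigma=1.5,
                                        use_sample_covariance=False,
                                        data_range=1.0)
            assert ssim(a, b) == pytest.approx(ref, abs=1e-6)


class TestFwhmFit:
    @staticmethod
    def gauss(sx, sy, amp=0.8, offset=0.05, n=41):
        yy, xx = np.mgrid[0:n, 0:n]
        c = n // 2
        return amp * np.exp(-0.5 * (((xx - c) / sx) ** 2
                                    + ((yy - c) / sy) ** 2)) + offset

    def test_noiseless_closed_form(self):
        r = fwhm_gaussian_fit(self.gauss(2.0, 2.0), pitch_um=0.1)
        assert r["fwhm_x_um"] == pytest.approx(FWHM_PER_SIGMA * 2.0 * 0.1,
                                               rel=1e-6)
        assert r["converged"]

    def test_anisotropic_axes_recovered(self):
        r = fwhm_gaussian_fit(self.gauss(2.0, 3.5), pitch_um=0.1)
        assert r["fwhm_x_um"] == pytest.approx(FWHM_PER_SIGMA * 0.2, rel=1e-6)
        assert r["fwhm_y_um"] == pytest.approx(FWHM_PER_SIGMA * 0.35, rel=1e-6)

    def test_noisy_monte_carlo_median_within_5_percent(self):
        rng = np.random.default_rng(0)
        truth = FWHM_PER_SIGMA * 2.5
        fwhms = []
        for _ in range(100):
            img = self.gauss(2.5, 2.5) + rng.normal(0, 0.8 / 20, (41, 41))
            fwhms.append(fwhm_gaussian_fit(img)["fwhm_x_um"])
        assert np.median(fwhms) == pytest.approx(truth, rel=0.05)


class TestDepthSchedules:
    def test_diopter_planes_uniform_in_reciprocal(self):
        planes = diopter_planes(3000.0, 25.0, 41)
        assert len(planes) == 41
        inv = 1.0 / planes
        np.testing.assert_allclose(np.diff(inv), np.diff(inv)[0], rtol=1e-9)

    def test_train_and_eval_schedules_coincide(self):
        train = sample_depths(5, 3000.0, 25.0, "grid")
        eval_ = diopter_planes(3000.0, 25.0, 5)
        np.testing.assert_allclose(np.sort(train), np.sort(eval_), rtol=1e-12)


@pytest.fixture()
def setup():
    system = toy_system(with_design=True)
    depths = sample_depths(2, system.config.nominal_focus_um, 25.0)
    spec = ReconstructorSpec(channels=2, widths=(4, 8, 16))
    return system, depths, spec


class TestTrainingLoop:

    def test_frozen_optics_leave_delta_gamma_unchanged(self, setup):
        system, depths, spec = setup
        net = build_reconstructor(spec, seed=0)
        before = system.design.delta_gamma.data.copy()
        cfg = TrainConfig(steps=3, k_depths=2, freeze_optics=True)
        train_end_to_end(system, net, depths, toy_patch_source(), cfg,
                         np.random.default_rng(0))
        np.testing.assert_array_equal(system.design.delta_gamma.data, before)

    def test_optical_optimizer_has_no_weight_decay(self, setup):
        system, _, spec = setup
        net = build_reconstructor(spec, seed=0)
        cfg = TrainConfig(network_weight_decay=1e-3)
        opt_optical, opt_net = make_optimizers(system, net, cfg)
        assert opt_optical.weight_decay == 0.0
        assert opt_net.weight_decay == 1e-3

    def test_short_joint_run_decreases_loss_and_stays_finite(self, setup):
        system, depths, spec = setup
        net = build_reconstructor(spec, seed=0)
        cfg = TrainConfig(steps=12, k_depths=2, optical_lr=0.2,
                          network_lr=1e-3, seed=0)
        hist = train_end_to_end(system, net, depths, toy_patch_source(), cfg,
                                np.random.default_rng(0))
        losses = np.asarray(hist["loss"])
        assert np.all(np.isfinite(losses))
        # Δγ actually moved: gradients reached the optical parameters
        assert np.abs(system.design.delta_gamma.data).max() > 0


def test_depth_sweep_shape_and_focus_advantage():
    """The conventional system is best at focus and degrades at the DoF edge."""
    system = toy_system(with_design=False, noise_sigma=0.0)
    src = toy_patch_source()
    phantom = src(np.random.default_rng(2))
    df = depth_sweep(system, None, [phantom], 25.0, n_planes=5)
    assert len(df) == 5 * 1 * 2
    focus = df[df["plane"] == 2]
    edge = df[df["plane"] == 0]
    for c in (0, 1):
        assert focus[focus.channel == c].psnr_db.item() > \
            edge[edge.channel == c].psnr_db.item()
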