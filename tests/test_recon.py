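"""Reconstruction operators: baselines, GRAPPA, TV-CS, rescaling."""

import numpy as np
import pytest

from reconqa import phantom as ph
from reconqa import recon as rc
from reconqa import sampling as sp
from reconqa.fourier import fft2c, ifft2c
from reconqa.phantom import MultiCoilKSpace

from conftest import make_planted_kernel_data


def _total_variation(x):
    gx = np.roll(x, -1, axis=0) - x
    gy = np.roll(x, -1, axis=1) - x
    return np.sum(np.sqrt(gx**2 + gy**2))


class TestRssIfft:
    def test_single_uniform_coil_recovers_magnitude(self, shepp64):
        ksp = MultiCoilKSpace(data=fft2c(shepp64.pixels[None]))
        img = rc.rss_ifft_recon(ksp)
        np.testing.assert_allclose(img, np.abs(shepp64.pixels), atol=1e-12)

    def test_global_phase_invariance(self, kspace64):
        rotated = MultiCoilKSpace(data=kspace64.data * np.exp(1j * 0.7))
        np.testing.assert_allclose(
            rc.rss_ifft_recon(rotated), rc.rss_ifft_recon(kspace64), atol=1e-12
        )

    def test_multicoil_closed_form(self, shepp64, coils8_64, kspace64):
        expected = np.sqrt(
            np.sum(np.abs(coils8_64.maps * shepp64.pixels) ** 2, axis=0)
        )
        np.testing.assert_allclose(rc.rss_ifft_recon(kspace64), expected, atol=1e-10)


class TestZeroFilled:
    def test_full_mask_matches_rss(self, kspace64):
        full = sp.SamplingMask(np.ones(64, dtype=bool))
        np.testing.assert_array_equal(
            rc.zero_filled_recon(kspace64, full), rc.rss_ifft_recon(kspace64)
        )

    def test_regular_mask_aliasing_oracle(self, shepp64):
        # comb sampling every 4th centered line folds the image onto
        # shifted replicas at multiples of N/4 (Fourier shift theorem)
        ksp = MultiCoilKSpace(data=fft2c(shepp64.pixels[None]))
        m = sp.regular_mask(64, 4)
        img = rc.zero_filled_recon(ksp, m)
        replicas = sum(np.roll(shepp64.pixels, 16 * j, axis=1) for j in range(4))
        np.testing.assert_allclose(img, np.abs(replicas) / 4.0, atol=1e-10)

    def test_positive_scaling_linearity(self, kspace64):
        m = sp.regular_mask(64, 4)
        base = rc.zero_filled_recon(kspace64, m)
        scaled = rc.zero_filled_recon(MultiCoilKSpace(data=3.0 * kspace64.data), m)
        np.testing.assert_allclose(
            scaled, 3.0 * base, rtol=1e-12, atol=1e-12 * base.max()
        )


class TestGrappa:
    def test_planted_kernel_recovery_and_reconstruction(self):
        data, planted = make_planted_kernel_data()
        ksp = MultiCoilKSpace(data=data)
        lines = np.zeros(32, dtype=bool)
        lines[8:24] = True
        calib_mask = sp.SamplingMask(lines, acs=(8, 24))
        kernel = rc.grappa_calibrate(
            sp.apply_mask(ksp, calib_mask),
            kernel_kx=3,
            kernel_sampled_lines=2,
            R=2,
            tikhonov=0.0,
        )
        assert np.abs(kernel.weights[1] - planted[1]).max() <= 1e-6

        recon_mask = sp.regular_mask(32, 2)
        img = rc.grappa_reconstruct(sp.apply_mask(ksp, recon_mask), recon_mask, kernel)
        ref = rc.rss_ifft_recon(ksp)
        assert np.linalg.norm(img - ref) / np.linalg.norm(ref) <= 1e-6

    def test_fully_sampled_R1_is_identity(self, kspace64):
        mask = sp.regular_mask(64, 1)
        kernel = rc.GrappaKernel(
            weights={}, kernel_kx=3, kernel_sampled_lines=2, R=1, n_coils=8
        )
        np.testing.assert_array_equal(
            rc.grappa_reconstruct(kspace64, mask, kernel), rc.rss_ifft_recon(kspace64)
        )

    def test_shepp_logan_regression(self, grappa_study):
        """Noiseless 8-coil head phantom, R=4, 8% ACS: GRAPPA should land
        within a few percent of the fully sampled RSS reconstruction."""
        gs = grappa_study
        img = rc.grappa_reconstruct(
            sp.apply_mask(gs["kspace"], gs["recon_mask"]), gs["recon_mask"], gs["kernel"]
        )
        ref = rc.rss_ifft_recon(gs["kspace"])
        nrmse = np.linalg.norm(img - ref) / np.linalg.norm(ref)
        assert nrmse <= 0.05

    def test_large_tikhonov_shrinks_weights(self):
        data, _ = make_planted_kernel_data()
        ksp = MultiCoilKSpace(data=data)
        lines = np.zeros(32, dtype=bool)
        lines[8:24] = True
        calib_mask = sp.SamplingMask(lines, acs=(8, 24))

        def fit(tik):
            k = rc.grappa_calibrate(
                sp.apply_mask(ksp, calib_mask),
                kernel_kx=3,
                kernel_sampled_lines=2,
                R=2,
                tikhonov=tik,
            )
            return np.linalg.norm(k.weights[1])

        assert fit(1e8) < 1e-4 * fit(0.0)

    def test_dc_consistency_single_coil(self):
        # constant k-space rows: interpolation weights must sum to 1
        data = np.ones((1, 16, 32), dtype=complex)
        lines = np.zeros(32, dtype=bool)
        lines[8:24] = True
        calib_mask = sp.SamplingMask(lines, acs=(8, 24))
        kernel = rc.grappa_calibrate(
            sp.apply_mask(MultiCoilKSpace(data=data), calib_mask),
            kernel_kx=3,
            kernel_sampled_lines=2,
            R=2,
            tikhonov=1e-9,
        )
        assert np.sum(kernel.weights[1]).real == pytest.approx(1.0, abs=1e-3)

    def test_acs_too_small(self, kspace64):
        lines = np.zeros(64, dtype=bool)
        lines[30:34] = True
        calib_mask = sp.SamplingMask(lines, acs=(30, 34))
        with pytest.raises(ValueError):
            rc.grappa_calibrate(
                sp.apply_mask(kspace64, calib_mask),
                kernel_kx=5,
                kernel_sampled_lines=4,
                R=4,
            )

    def test_mask_kernel_mismatch(self, kspace64):
        kernel = rc.GrappaKernel(
            weights={}, kernel_kx=3, kernel_sampled_lines=2, R=4, n_coils=8
        )
        wrong = sp.random_mask(64, 4, 0.08, 0)
        with pytest.raises(ValueError):
            rc.grappa_reconstruct(kspace64, wrong, kernel)


class TestEstimateSensitivities:
    def test_uniform_coil_unit_magnitude_on_support(self, shepp64):
        ksp = MultiCoilKSpace(data=fft2c(shepp64.pixels[None]))
        lines = np.zeros(64, dtype=bool)
        lines[16:48] = True  # wide ACS
        calib = sp.apply_mask(ksp, sp.SamplingMask(lines, acs=(16, 48)))
        est = rc.estimate_sensitivities(calib)
        mags = np.abs(est.maps[0][est.support])
        np.testing.assert_allclose(mags, 1.0, atol=1e-12)
        assert not est.support[0, 0]  # background flagged invalid

    def test_recovers_true_maps_with_wide_acs(self, shepp64, coils8_64):
        ksp = MultiCoilKSpace(data=fft2c(coils8_64.maps * shepp64.pixels))
        lines = np.zeros(64, dtype=bool)
        lines[8:56] = True
        calib = sp.apply_mask(ksp, sp.SamplingMask(lines, acs=(8, 56)))
        est = rc.estimate_sensitivities(calib)
        true_rss = coils8_64.rss()
        true_unit = coils8_64.maps / true_rss
        # align the smooth common phase pixel-wise before comparing
        inner = np.sum(np.conj(est.maps) * true_unit, axis=0)
        aligned = est.maps * np.exp(1j * np.angle(inner))
        w = (true_rss * np.abs(shepp64.pixels)) * est.support
        err = np.sqrt(
            np.sum(w * np.sum(np.abs(aligned - true_unit) ** 2, axis=0)) / np.sum(w)
        )
        assert err <= 0.05

    def test_empty_acs_raises(self):
        empty = MultiCoilKSpace(data=np.zeros((1, 16, 16), dtype=complex))
        with pytest.raises(ValueError):
            rc.estimate_sensitivities(empty)


class TestTvCs:
    def test_unregularized_limit_matches_least_squares(self, kspace64, coils8_64):
        full = sp.SamplingMask(np.ones(64, dtype=bool))
        cfg = rc.CSConfig(lambda_tv=0.0)
        img = rc.tv_cs_recon(kspace64, full, coils8_64, cfg)
        num = np.sum(np.conj(coils8_64.maps) * ifft2c(kspace64.data), axis=0)
        den = np.sum(np.abs(coils8_64.maps) ** 2, axis=0)
        ls = np.abs(num / den)
        assert np.linalg.norm(img - ls) / np.linalg.norm(ls) <= 1e-6

    def test_blocks_phantom_beats_zero_filled(self, blocks64, coils8_64):
        ksp = MultiCoilKSpace(data=fft2c(coils8_64.maps * blocks64.pixels))
        mask = sp.random_mask(64, 4, 0.08, 1)
        und = sp.apply_mask(ksp, mask)
        truth = np.abs(blocks64.pixels)
        cfg = rc.CSConfig(lambda_tv=3e-3, n_iter=50, cg_iter=8)
        cs = rc.rescale_to_reference(rc.tv_cs_recon(und, mask, coils8_64, cfg), truth)
        zf = rc.rescale_to_reference(rc.zero_filled_recon(ksp, mask), truth)
        cs_err = np.linalg.norm(cs - truth)
        zf_err = np.linalg.norm(zf - truth)
        assert cs_err < zf_err

    def test_objective_non_increasing_after_burn_in(self, cs_study):
        und = sp.apply_mask(cs_study["kspace"], cs_study["mask"])
        _, info = rc.tv_cs_recon(
            und, cs_study["mask"], cs_study["sens"], cs_study["cfg"], return_info=True
        )
        obj = np.asarray(info["objective"])
        increases = np.diff(obj[5:])
        assert np.all(increases <= 1e-6 * np.abs(obj[5:-1]) + 1e-12)

    def test_strong_tv_flattens_noisy_constant_phantom(self):
        n = 48
        rng = np.random.default_rng(4)
        flat = np.zeros((n, n), dtype=complex)
        flat[8:40, 8:40] = 1.0
        noisy = flat + 0.05 * rng.standard_normal((n, n))
        sens = ph.make_coil_sensitivities(1, n, n, "uniform")
        ksp = MultiCoilKSpace(data=fft2c(noisy[None]))
        mask = sp.random_mask(n, 2, 0.1, 3)
        und = sp.apply_mask(ksp, mask)
        cfg = rc.CSConfig(lambda_tv=0.05, n_iter=60, cg_iter=8)
        cs = rc.tv_cs_recon(und, mask, sens, cfg)
        zf = rc.zero_filled_recon(ksp, mask)
        assert _total_variation(cs) < _total_variation(zf)


class TestRescaleToReference:
    def test_exact_multiple(self):
        rng = np.random.default_rng(0)
        img = rng.random((8, 8))
        np.testing.assert_allclose(rc.rescale_to_reference(img, 3 * img), 3 * img)

    def test_orthogonal_gives_zero(self):
        img = np.zeros((2, 2))
        img[0, 0] = 1.0
        ref = np.zeros((2, 2))
        ref[1, 1] = 1.0
        np.testing.assert_array_equal(rc.rescale_to_reference(img, ref), 0 * img)

    def test_optimal_against_scanned_scales(self):
        rng = np.random.default_rng(1)
        img = rng.random((16, 16))
        ref = rng.random((16, 16))
        best = np.linalg.norm(rc.rescale_to_reference(img, ref) - ref)
        for c in np.linspace(-2.0, 2.0, 100):
            assert best <= np.linalg.norm(c * img - ref) + 1e-12

    def test_zero_image_raises(self):
        with pytest.raises(ValueError):
            rc.rescale_to_reference(np.zeros((4, 4)), np.ones((4, 4)))
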