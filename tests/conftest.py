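"""Shared fixtures: synthetic acquisitions and calibrated operators.

Heavy fixtures (the GRAPPA study at 128x128 and the TV-CS study at 64x64)
are session-scoped so the expensive calibration and reconstruction work is
done once and shared between unit and acceptance tests.
"""

import numpy as np
import pytest

from reconqa import phantom as ph
from reconqa import recon as rc
from reconqa import sampling as sp
from reconqa.fourier import fft2c
from reconqa.phantom import MultiCoilKSpace


@pytest.fixture(scope="session")
def shepp64():
    return ph.make_phantom(64, 64, "shepp_logan")


@pytest.fixture(scope="session")
def blocks64():
    return ph.make_phantom(64, 64, "blocks")


@pytest.fixture(scope="session")
def coils8_64():
    return ph.make_coil_sensitivities(8, 64, 64, "gaussian_ring")


@pytest.fixture(scope="session")
def coil_images_64(shepp64, coils8_64):
    return coils8_64.maps * shepp64.pixels


@pytest.fixture(scope="session")
def kspace64(coil_images_64):
    return MultiCoilKSpace(data=fft2c(coil_images_64))


@pytest.fixture(scope="session")
def cov8():
    return ph.make_noise_covariance(8, 0.2, 7)


def make_planted_kernel_data(seed=3, n_coils=2, n_rows=32, n_cols=32, R=2,
                             kernel_kx=3, kernel_sampled_lines=2):
    """K-space data in which every missing line is exactly a fixed linear
    combination of the adjacent sampled lines (circular row handling),
    together with the planted weights.  Source feature ordering matches
    the calibration convention: coil-major, then row offset, then sampled
    line."""
    rng = np.random.default_rng(seed)
    dxs = np.arange(kernel_kx) - kernel_kx // 2
    jrange = np.arange(kernel_sampled_lines) - (kernel_sampled_lines - 1) // 2
    n_feat = n_coils * kernel_kx * kernel_sampled_lines
    weights = {}
    for d in range(1, R):
        weights[d] = 0.3 * (
            rng.normal(size=(n_feat, n_coils))
            + 1j * rng.normal(size=(n_feat, n_coils))
        )
    data = np.zeros((n_coils, n_rows, n_cols), dtype=complex)
    n_sampled = len(range(0, n_cols, R))
    data[:, :, ::R] = rng.normal(size=(n_coils, n_rows, n_sampled)) + 1j * rng.normal(
        size=(n_coils, n_rows, n_sampled)
    )
    for t in range(n_cols):
        d = t % R
        if d == 0:
            continue
        b = t - d
        feats = []
        for c in range(n_coils):
            for dx in dxs:
                for j in jrange:
                    feats.append(
                        np.roll(data[c], -dx, axis=0)[:, (b + j * R) % n_cols]
                    )
        A = np.stack(feats, axis=1)
        data[:, :, t] = (A @ weights[d]).T
    return data, weights


@pytest.fixture(scope="session")
def grappa_study():
    """Noiseless 8-coil acquisition at 128x128 with a calibrated GRAPPA
    R=4 operator (compact kernel sized to the 8% ACS of this matrix)."""
    n = 128
    phantom = ph.make_phantom(n, n, "shepp_logan")
    sens = ph.make_coil_sensitivities(8, n, n, "gaussian_ring")
    coil_images = sens.maps * phantom.pixels
    kspace = MultiCoilKSpace(data=fft2c(coil_images))
    calib_mask, recon_mask = sp.grappa_masks(n, 4, 0.08)
    kernel = rc.grappa_calibrate(
        sp.apply_mask(kspace, calib_mask),
        kernel_kx=5,
        kernel_sampled_lines=2,
        R=4,
        tikhonov=1e-6,
    )
    return {
        "phantom": phantom,
        "sens": sens,
        "coil_images": coil_images,
        "kspace": kspace,
        "calib_mask": calib_mask,
        "recon_mask": recon_mask,
        "kernel": kernel,
        "operator": rc.grappa_operator(kernel),
    }


@pytest.fixture(scope="session")
def cs_study(shepp64, coils8_64, coil_images_64, kspace64):
    """8-coil acquisition at 64x64 with a random R=4 mask and a TV-CS
    operator using the generator's true sensitivities."""
    mask = sp.random_mask(64, 4, 0.08, 1)
    cfg = rc.CSConfig(lambda_tv=3e-3, n_iter=50, cg_iter=8)
    return {
        "phantom": shepp64,
        "sens": coils8_64,
        "coil_images": coil_images_64,
        "kspace": kspace64,
        "mask": mask,
        "cfg": cfg,
        "operator": rc.tv_cs_operator(coils8_64, cfg),
    }
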