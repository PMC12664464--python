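"""Synthetic multi-coil MRI acquisitions.

Everything needed to exercise the resolution / g-factor machinery without
scanner data: a piecewise-smooth complex phantom, smooth complex coil
sensitivity maps, a coil noise covariance, and simulated k-space and
noise-only acquisitions with correlated complex Gaussian noise.

Conventions
-----------
* Coordinates are 0-based and row-major.  The phase-encode direction is the
  column axis (horizontal image direction); undersampling acts on columns.
* Unit-variance complex noise has variance 1/2 per real/imaginary component,
  so the coil covariance matches the complex covariance estimator
  ``psi = (1/n) N N^H``.
* Pixel spacing is 1 throughout; resolution is reported in pixel units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .fourier import fft2c, ifft2c

logger = logging.getLogger(__name__)

__all__ = [
    "PhantomImage",
    "CoilSensitivities",
    "NoiseCovariance",
    "NoiseSamples",
    "MultiCoilKSpace",
    "SHEPP_LOGAN_ELLIPSES",
    "make_phantom",
    "make_coil_sensitivities",
    "make_noise_covariance",
    "simulate_acquisition",
    "simulate_noise_scan",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class PhantomImage:
    """A 2D complex object to be imaged.

    Attributes
    ----------
    pixels : ndarray, complex, shape (rows, cols)
        Object values in arbitrary signal units; exactly zero outside the
        object support.
    spacing : float
        Isotropic pixel spacing (1.0: all widths are in pixel units).
    """

    pixels: np.ndarray
    spacing: float = 1.0

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


@dataclass
class CoilSensitivities:
    """Smooth complex receive profiles, one map per coil.

    ``maps`` has shape (coil, rows, cols).  ``support`` optionally flags
    pixels where the maps are considered valid (used by ACS-based
    estimates); ``None`` means valid everywhere.
    """

    maps: np.ndarray
    support: Optional[np.ndarray] = None

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    def rss(self) -> np.ndarray:
        """Root sum of squares of the coil maps."""
        return np.sqrt(np.sum(np.abs(self.maps) ** 2, axis=0))


@dataclass
class NoiseCovariance:
    """Hermitian coil-by-coil noise covariance (variance units)."""

    psi: np.ndarray

    @property
    def n_coils(self) -> int:
        return self.psi.shape[0]


@dataclass
class NoiseSamples:
    """Noise-only acquisition: complex samples per coil, shape (coil, n)."""

    samples: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class MultiCoilKSpace:
    """Complex k-space data for one 2D slice, shape (coil, rows, cols)."""

    data: np.ndarray
    sampled_mask: object = None  # SamplingMask, attached by sampling.apply_mask

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]

    @property
    def image_shape(self) -> tuple:
        return self.data.shape[-2:]


# ---------------------------------------------------------------------------
# Phantom
# ---------------------------------------------------------------------------

#: The classic head phantom: (intensity, semi-axis a, semi-axis b,
#: center x, center y, rotation angle in degrees).  Coordinates live in
#: [-1, 1]^2; intensities of overlapping ellipses add.
SHEPP_LOGAN_ELLIPSES = (
    (2.00, 0.6900, 0.9200, 0.00, 0.0000, 0.0),
    (-0.98, 0.6624, 0.8740, 0.00, -0.0184, 0.0),
    (-0.02, 0.1100, 0.3100, 0.22, 0.0000, -18.0),
    (-0.02, 0.1600, 0.4100, -0.22, 0.0000, 18.0),
    (0.01, 0.2100, 0.2500, 0.00, 0.3500, 0.0),
    (0.01, 0.0460, 0.0460, 0.00, 0.1000, 0.0),
    (0.01, 0.0460, 0.0460, 0.00, -0.1000, 0.0),
    (0.01, 0.0460, 0.0230, -0.08, -0.6050, 0.0),
    (0.01, 0.0230, 0.0230, 0.00, -0.6060, 0.0),
    (0.01, 0.0230, 0.0460, 0.06, -0.6050, 0.0),
)


def _pixel_grid(n_rows: int, n_cols: int):
    """Pixel-center coordinates in [-1, 1]^2, y up."""
    x = (np.arange(n_cols) - (n_cols - 1) / 2.0) * (2.0 / n_cols)
    y = -(np.arange(n_rows) - (n_rows - 1) / 2.0) * (2.0 / n_rows)
    return np.meshgrid(x, y)  # xx, yy with shape (rows, cols)


def make_phantom(
    n_rows: int,
    n_cols: int,
    kind: str = "shepp_logan",
    phase_cycles: float = 0.0,
) -> PhantomImage:
    """Deterministically rasterize a synthetic phantom at pixel centers.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid size; both must be at least 16.
    kind : {"shepp_logan", "blocks"}
        ``shepp_logan`` sums the classic 10-ellipse head phantom;
        ``blocks`` is a piecewise-constant pattern suited to
        total-variation reconstruction tests.
    phase_cycles : float
        If nonzero, multiply the (real, non-negative) phantom by a smooth
        linear phase ramp with this many cycles across the field of view,
        to exercise complex handling.
    """
    if n_rows < 16 or n_cols < 16:
        raise ValueError("phantom dimensions must be at least 16x16")

    if kind == "shepp_logan":
        xx, yy = _pixel_grid(n_rows, n_cols)
        img = np.zeros((n_rows, n_cols))
        for amp, a, b, x0, y0, phi_deg in SHEPP_LOGAN_ELLIPSES:
            phi = np.deg2rad(phi_deg)
            xr = (xx - x0) * np.cos(phi) + (yy - y0) * np.sin(phi)
            yr = -(xx - x0) * np.sin(phi) + (yy - y0) * np.cos(phi)
            img[(xr / a) ** 2 + (yr / b) ** 2 <= 1.0] += amp
    elif kind == "blocks":
        img = np.zeros((n_rows, n_cols))
        m = n_rows // 8, n_cols // 8
        r0, r1 = m[0], n_rows - m[0]
        c0, c1 = m[1], n_cols - m[1]
        rm, cm = (r0 + r1) // 2, (c0 + c1) // 2
        img[r0:rm, c0:cm] = 1.0
        img[r0:rm, cm:c1] = 0.6
        img[rm:r1, c0:cm] = 0.8
        img[rm:r1, cm:c1] = 0.4
        # inner square on top of the quadrants
        qr, qc = (r1 - r0) // 4, (c1 - c0) // 4
        img[rm - qr // 2 : rm + qr // 2, cm - qc // 2 : cm + qc // 2] = 1.2
    else:
        raise ValueError(f"unknown phantom kind: {kind!r}")

    pixels = img.astype(complex)
    if phase_cycles:
        xx, yy = _pixel_grid(n_rows, n_cols)
        pixels = pixels * np.exp(1j * np.pi * phase_cycles * (xx + yy) / 2.0)
    return PhantomImage(pixels=pixels)


# ---------------------------------------------------------------------------
# Coil sensitivities
# ---------------------------------------------------------------------------

def make_coil_sensitivities(
    n_coils: int,
    n_rows: int,
    n_cols: int,
    profile: str = "gaussian_ring",
    peak: float = 1.0,
    sigma_frac: float = 0.25,
) -> CoilSensitivities:
    """Construct smooth complex coil sensitivity maps.

    ``gaussian_ring`` places the coil centers evenly on a circle around the
    field of view; each map is a complex Gaussian falloff from its center
    (magnitude exactly ``peak`` at the center pixel) with a gentle linear
    phase and a per-coil constant phase offset.  ``uniform`` returns
    all-ones maps (single-coil limit).

    ``sigma_frac`` sets the Gaussian falloff width as a fraction of the
    larger grid dimension.  The default 0.25 emulates the localized
    receive profiles of a head array: surface coils must differ
    appreciably across the field of view for parallel imaging to encode
    anything; near-uniform profiles would make undersampled
    reconstruction ill-posed regardless of coil count.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")

    if profile == "uniform":
        maps = np.ones((n_coils, n_rows, n_cols), dtype=complex)
        return CoilSensitivities(maps=maps)
    if profile != "gaussian_ring":
        raise ValueError(f"unknown sensitivity profile: {profile!r}")

    rows = np.arange(n_rows)[:, None]
    cols = np.arange(n_cols)[None, :]
    cy, cx = (n_rows - 1) / 2.0, (n_cols - 1) / 2.0
    radius = 0.45 * min(n_rows, n_cols)
    sigma = sigma_frac * max(n_rows, n_cols)

    maps = np.empty((n_coils, n_rows, n_cols), dtype=complex)
    for c in range(n_coils):
        theta = 2.0 * np.pi * c / n_coils
        # snap the coil center to a pixel so the peak value is exact there
        r_c = int(round(cy + radius * np.sin(theta)))
        c_c = int(round(cx + radius * np.cos(theta)))
        d2 = (rows - r_c) ** 2 + (cols - c_c) ** 2
        mag = peak * np.exp(-d2 / (2.0 * sigma**2))
        # smooth linear phase pointing away from the coil, plus an offset
        ramp = 0.5 * np.pi * ((rows - r_c) / n_rows + (cols - c_c) / n_cols)
        maps[c] = mag * np.exp(1j * (ramp + theta))
    return CoilSensitivities(maps=maps)


# ---------------------------------------------------------------------------
# Noise model
# ---------------------------------------------------------------------------

def make_noise_covariance(n_coils: int, offdiag: float, seed: int) -> NoiseCovariance:
    """Build a Hermitian positive-definite coil covariance.

    The matrix has a unit diagonal and nearest-neighbor correlations of
    magnitude ``offdiag`` with random phases drawn from ``seed``.  If the
    construction is not positive definite (possible for ``offdiag``
    approaching 1) the eigenvalues are floored and the diagonal
    renormalized back to 1; this is logged.
    """
    if not 0.0 <= offdiag < 1.0:
        raise ValueError("offdiag must be in [0, 1)")
    psi = np.eye(n_coils, dtype=complex)
    if offdiag > 0.0 and n_coils > 1:
        rng = np.random.default_rng(seed)
        phases = np.exp(1j * rng.uniform(0.0, 2.0 * np.pi, n_coils - 1))
        for i in range(n_coils - 1):
            psi[i, i + 1] = offdiag * phases[i]
            psi[i + 1, i] = np.conj(psi[i, i + 1])
    w = np.linalg.eigvalsh(psi)
    if w.min() <= 0.0:
        floor = 1e-6
        logger.warning(
            "covariance not positive definite (min eigenvalue %.3g); "
            "flooring eigenvalues at %.1g and renormalizing diagonal",
            w.min(),
            floor,
        )
        vals, vecs = np.linalg.eigh(psi)
        psi = (vecs * np.maximum(vals, floor)) @ vecs.conj().T
        d = np.sqrt(np.real(np.diag(psi)))
        psi = psi / np.outer(d, d)
        psi = 0.5 * (psi + psi.conj().T)
    return NoiseCovariance(psi=psi)


def simulate_acquisition(
    phantom: PhantomImage,
    sens: CoilSensitivities,
    cov: NoiseCovariance,
    noise_scale: float,
    seed: int,
) -> MultiCoilKSpace:
    """Simulate a fully sampled multi-coil acquisition.

    Coil images are ``sens * phantom``; each coil is taken to k-space with
    the centered orthonormal FFT, and correlated complex Gaussian noise
    (colored by ``cov``, scaled by ``noise_scale``) is added to every
    sample.  Reproducible for a given ``seed``.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    if sens.maps.shape[1:] != phantom.pixels.shape:
        raise ValueError(
            f"sensitivity shape {sens.maps.shape[1:]} does not match "
            f"phantom shape {phantom.pixels.shape}"
        )
    if cov.n_coils != sens.n_coils:
        raise ValueError("covariance and sensitivities disagree on coil count")

    coil_images = sens.maps * phantom.pixels[None, :, :]
    kspace = fft2c(coil_images)
    if noise_scale > 0:
        from .gfactor import synthesize_noise

        noise = synthesize_noise(cov, kspace.shape[1:], seed)
        kspace = kspace + noise_scale * noise
    return MultiCoilKSpace(data=kspace)


def simulate_noise_scan(cov: NoiseCovariance, n_samples: int, seed: int) -> NoiseSamples:
    """Simulate an RF-free noise acquisition: i.i.d. complex Gaussian
    column vectors with coil covariance ``cov``."""
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    from .gfactor import synthesize_noise

    return NoiseSamples(samples=synthesize_noise(cov, (n_samples,), seed))
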