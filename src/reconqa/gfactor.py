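"""Pseudo multiple-replica noise analysis and g-factor maps.

Receiver arrays exhibit white complex Gaussian noise that is correlated
across coils.  The coil covariance is estimated from an RF-free noise
acquisition as ``psi[i,j] = (1/n) sum_k N[i,k] N[j,k]*`` (no mean
subtraction).  Synthetic correlated noise is obtained by coloring
i.i.d. standard complex Gaussian draws with a matrix square root of
``psi``; pseudo replicas of a measurement add such noise to the k-space
data, reconstruct, and measure the per-pixel standard deviation over
replicas.  The g-factor then compares an accelerated reconstruction
against the fully sampled reference:

    g(x, y) = sigma_acc(x, y) / (sigma_normal(x, y) * sqrt(R)),

so g > 1 means the method amplifies noise beyond the sqrt(R) penalty of
the shortened acquisition and g < 1 means it suppresses noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Tuple, Union

import numpy as np

from .phantom import MultiCoilKSpace, NoiseCovariance, NoiseSamples
from .recon import rss_operator
from .sampling import SamplingMask, apply_mask, effective_acceleration

logger = logging.getLogger(__name__)

__all__ = [
    "StdMap",
    "GFactorMap",
    "ReplicaConfig",
    "estimate_noise_covariance",
    "covariance_sqrt",
    "synthesize_noise",
    "pseudo_replica_std",
    "gfactor_map",
    "gfactor_pipeline",
]

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]


@dataclass
class StdMap:
    """Per-pixel standard deviation over pseudo replicas."""

    sigma: np.ndarray
    n_replicas: int
    role: str  # "accelerated" or "normal"


@dataclass
class GFactorMap:
    """Per-pixel noise amplification relative to the sqrt(R) baseline."""

    g: np.ndarray
    R: float
    invalid_mask: np.ndarray

    def valid_values(self) -> np.ndarray:
        return self.g[~self.invalid_mask]


@dataclass
class ReplicaConfig:
    """Pseudo multiple-replica settings.

    ``n_replicas`` defaults to 1000; tests and desk-scale runs use fewer
    with correspondingly widened Monte-Carlo tolerances.  ``noise_scale``
    multiplies the synthesized noise before it is added to the data.
    """

    n_replicas: int = 1000
    seed: SeedLike = 0
    noise_scale: float = 1.0

    def __post_init__(self):
        if self.n_replicas < 2:
            raise ValueError("n_replicas must be >= 2")


# ---------------------------------------------------------------------------
# Covariance estimation and noise synthesis
# ---------------------------------------------------------------------------

def estimate_noise_covariance(
    noise: NoiseSamples, mean_subtract: bool = False
) -> NoiseCovariance:
    """The sample covariance ``(1/n) N N^H`` of a noise-only acquisition.

    By default no mean is subtracted, matching the estimator used with
    RF-free acquisitions (the noise has zero mean by construction); set
    ``mean_subtract`` for the centered variant."""
    samples = noise.samples
    n = samples.shape[1]
    if n < 2:
        raise ValueError("need at least 2 noise samples")
    if mean_subtract:
        samples = samples - samples.mean(axis=1, keepdims=True)
    psi = (samples @ samples.conj().T) / n
    psi = 0.5 * (psi + psi.conj().T)
    return NoiseCovariance(psi=psi)


def covariance_sqrt(cov: NoiseCovariance) -> np.ndarray:
    """Lower-triangular Cholesky factor ``L`` with ``L L^H = psi``.

    Any factor ``B`` with ``B B^H = psi`` colors white noise to the same
    law; Cholesky is the cheapest.  A singular-but-PSD input gets a tiny
    jitter; a genuinely non-PSD input raises with its smallest eigenvalue.
    """
    psi = cov.psi
    try:
        return np.linalg.cholesky(psi)
    except np.linalg.LinAlgError:
        w = np.linalg.eigvalsh(psi)
        scale = max(np.abs(w).max(), 1.0)
        if w.min() < -1e-10 * scale:
            raise ValueError(
                f"covariance is not positive semi-definite "
                f"(smallest eigenvalue {w.min():.3g})"
            )
        jitter = 1e-12 * scale
        logger.info("covariance singular; adding jitter %.1g for Cholesky", jitter)
        return np.linalg.cholesky(psi + jitter * np.eye(psi.shape[0]))


def synthesize_noise(
    cov: NoiseCovariance, shape: Tuple[int, ...], seed: SeedLike
) -> np.ndarray:
    """Correlated complex Gaussian noise of shape ``(n_coils, *shape)``.

    Draws i.i.d. standard complex Gaussian samples (variance 1/2 per
    real/imaginary component, unit complex variance) per coil and mixes
    them with the Cholesky factor of ``cov``.  Reproducible by seed."""
    rng = np.random.default_rng(seed)
    n_coils = cov.n_coils
    n = int(np.prod(shape)) if shape else 1
    std = (
        rng.standard_normal((n_coils, n)) + 1j * rng.standard_normal((n_coils, n))
    ) / np.sqrt(2.0)
    mixed = covariance_sqrt(cov) @ std
    return mixed.reshape((n_coils,) + tuple(shape))


# ---------------------------------------------------------------------------
# Replica ensembles
# ---------------------------------------------------------------------------

def pseudo_replica_std(
    op: Callable,
    kspace: MultiCoilKSpace,
    mask: Optional[SamplingMask],
    cov: NoiseCovariance,
    cfg: ReplicaConfig,
    role: str = "accelerated",
) -> StdMap:
    """Per-pixel sample standard deviation of ``op`` over pseudo replicas.

    Each replica adds fresh synthetic noise (scaled by
    ``cfg.noise_scale``) to every sample of the full k-space grid, applies
    the mask if one is given, and reconstructs.  Replica random streams
    are spawned from ``cfg.seed`` so they are independent and
    reproducible.  The std uses ddof=1 and is computed on the final
    (real-valued magnitude) images."""
    ss = (
        cfg.seed
        if isinstance(cfg.seed, np.random.SeedSequence)
        else np.random.SeedSequence(cfg.seed)
    )
    children = ss.spawn(cfg.n_replicas)
    shape = kspace.image_shape
    acc = np.zeros(shape)
    acc2 = np.zeros(shape)
    for r, child in enumerate(children):
        data = kspace.data
        if cfg.noise_scale > 0.0:
            data = data + cfg.noise_scale * synthesize_noise(cov, shape, child)
        replica = MultiCoilKSpace(data=data)
        if mask is not None:
            replica = apply_mask(replica, mask)
        try:
            img = np.asarray(op(replica, mask))
        except Exception as exc:
            raise RuntimeError(f"reconstruction failed on replica {r}") from exc
        acc += img
        acc2 += img * img
    n = cfg.n_replicas
    var = (acc2 - acc * acc / n) / (n - 1)
    sigma = np.sqrt(np.maximum(var, 0.0))
    return StdMap(sigma=sigma, n_replicas=n, role=role)


def gfactor_map(acc: StdMap, normal: StdMap, R: float) -> GFactorMap:
    """``g = sigma_acc / (sigma_normal * sqrt(R))`` element-wise.

    Pixels whose reference std falls below a floor (1e-3 times its
    median) are flagged invalid (NaN) instead of diverging."""
    if acc.sigma.shape != normal.sigma.shape:
        raise ValueError("std map shapes differ")
    if acc.role != "accelerated" or normal.role != "normal":
        raise ValueError("expected roles 'accelerated' and 'normal'")
    floor = 1e-3 * np.median(normal.sigma)
    invalid = normal.sigma < floor
    denom = np.where(invalid, 1.0, normal.sigma)
    g = acc.sigma / (denom * np.sqrt(R))
    g[invalid] = np.nan
    return GFactorMap(g=g, R=R, invalid_mask=invalid)


def gfactor_pipeline(
    op_acc: Callable,
    kspace: MultiCoilKSpace,
    mask: SamplingMask,
    cov: NoiseCovariance,
    cfg: ReplicaConfig,
) -> GFactorMap:
    """Full pseudo multiple-replica g-factor computation.

    The reference arm reconstructs fully sampled replicas with inverse
    FFT + RSS; the accelerated arm reconstructs masked replicas with
    ``op_acc``.  The two arms use independent noise streams spawned from
    ``cfg.seed``, and ``R`` is the mask's effective acceleration."""
    ss = (
        cfg.seed
        if isinstance(cfg.seed, np.random.SeedSequence)
        else np.random.SeedSequence(cfg.seed)
    )
    seed_normal, seed_acc = ss.spawn(2)
    cfg_normal = ReplicaConfig(
        n_replicas=cfg.n_replicas, seed=seed_normal, noise_scale=cfg.noise_scale
    )
    cfg_acc = ReplicaConfig(
        n_replicas=cfg.n_replicas, seed=seed_acc, noise_scale=cfg.noise_scale
    )
    normal = pseudo_replica_std(rss_operator, kspace, None, cov, cfg_normal, role="normal")
    accelerated = pseudo_replica_std(op_acc, kspace, mask, cov, cfg_acc, role="accelerated")
    R = effective_acceleration(mask)
    return gfactor_map(accelerated, normal, R)
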