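"""Cartesian undersampling masks over phase-encode lines.

Phase-encode lines are the k-space columns (the horizontal image
direction).  A mask is a boolean vector over lines plus optional
autocalibration (ACS) metadata; applying a mask zeroes unsampled columns
in every coil.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .phantom import MultiCoilKSpace

__all__ = [
    "SamplingMask",
    "acs_range",
    "regular_mask",
    "grappa_masks",
    "random_mask",
    "equispaced_alternating_mask",
    "apply_mask",
    "effective_acceleration",
]


@dataclass
class SamplingMask:
    """Which phase-encode lines are acquired.

    Attributes
    ----------
    sampled_lines : ndarray of bool, shape (n_lines,)
        True where a line is acquired.
    acs : tuple (start, stop) or None
        Half-open index interval of the fully sampled autocalibration
        region; all lines in it are sampled.
    nominal_R : float
        The acceleration factor the pattern was designed for.
    """

    sampled_lines: np.ndarray
    acs: Optional[Tuple[int, int]] = None
    nominal_R: float = 1.0

    def __post_init__(self):
        self.sampled_lines = np.asarray(self.sampled_lines, dtype=bool)
        if not self.sampled_lines.any():
            raise ValueError("mask must sample at least one line")
        if self.acs is not None:
            lo, hi = self.acs
            if not self.sampled_lines[lo:hi].all():
                raise ValueError("ACS lines must all be sampled")

    @property
    def n_lines(self) -> int:
        return self.sampled_lines.size

    @property
    def sampled_indices(self) -> np.ndarray:
        return np.flatnonzero(self.sampled_lines)


def acs_range(n_lines: int, acs_fraction: float) -> Tuple[int, int]:
    """Centered half-open interval covering ``round(acs_fraction * n_lines)``
    lines; for an odd leftover the extra line goes to the lower side."""
    if not 0.0 < acs_fraction < 1.0:
        raise ValueError("acs_fraction must be in (0, 1)")
    width = round(acs_fraction * n_lines)
    if width == 0:
        raise ValueError(
            f"ACS width rounds to zero for n_lines={n_lines}, "
            f"acs_fraction={acs_fraction}"
        )
    start = (n_lines - width) // 2
    return start, start + width


def regular_mask(n_lines: int, R: int) -> SamplingMask:
    """Every ``R``-th line starting at line 0; no ACS region."""
    if R < 1:
        raise ValueError("R must be >= 1")
    if R > n_lines:
        raise ValueError("R exceeds the number of lines")
    sampled = np.zeros(n_lines, dtype=bool)
    sampled[::R] = True
    return SamplingMask(sampled_lines=sampled, acs=None, nominal_R=float(R))


def grappa_masks(
    n_lines: int, R: int, acs_fraction: float
) -> Tuple[SamplingMask, SamplingMask]:
    """The GRAPPA pair: a calibration mask of ACS lines only, and a
    reconstruction mask of every ``R``-th line with no ACS lines added, so
    the effective acceleration of the reconstructed data stays at ``R``."""
    lo, hi = acs_range(n_lines, acs_fraction)
    calib_lines = np.zeros(n_lines, dtype=bool)
    calib_lines[lo:hi] = True
    calibration = SamplingMask(sampled_lines=calib_lines, acs=(lo, hi), nominal_R=1.0)
    reconstruction = regular_mask(n_lines, R)
    return calibration, reconstruction


def random_mask(n_lines: int, R: int, acs_fraction: float, seed: int) -> SamplingMask:
    """Fully sampled ACS plus uniformly random lines, budgeted so the total
    sampled count is exactly ``round(n_lines / R)``."""
    lo, hi = acs_range(n_lines, acs_fraction)
    target = round(n_lines / R)
    n_extra = target - (hi - lo)
    if n_extra < 0:
        raise ValueError(
            f"ACS region ({hi - lo} lines) already exceeds the sampling "
            f"budget of {target} lines"
        )
    candidates = np.setdiff1d(np.arange(n_lines), np.arange(lo, hi))
    if n_extra > candidates.size:
        raise ValueError("sampling budget exceeds available lines")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(candidates, size=n_extra, replace=False)
    sampled = np.zeros(n_lines, dtype=bool)
    sampled[lo:hi] = True
    sampled[chosen] = True
    return SamplingMask(sampled_lines=sampled, acs=(lo, hi), nominal_R=float(R))


def equispaced_alternating_mask(n_lines: int, acs_fraction: float) -> SamplingMask:
    """Sampled lines with gaps alternating between 4 and 5 missing lines
    (strides +5, +6), anchored at line 0, plus the ACS region on top.
    The alternating stride targets a net acceleration of 4.
    ``acs_fraction = 0`` disables the ACS region."""
    if n_lines < 12:
        raise ValueError("n_lines must be >= 12")
    sampled = np.zeros(n_lines, dtype=bool)
    pos, step = 0, 5
    while pos < n_lines:
        sampled[pos] = True
        pos += step
        step = 11 - step  # alternate 5, 6
    acs = None
    if acs_fraction > 0.0:
        lo, hi = acs_range(n_lines, acs_fraction)
        sampled[lo:hi] = True
        acs = (lo, hi)
    return SamplingMask(sampled_lines=sampled, acs=acs, nominal_R=4.0)


def apply_mask(kspace: MultiCoilKSpace, mask: SamplingMask) -> MultiCoilKSpace:
    """Zero the unsampled phase-encode columns in every coil and attach the
    mask to the result."""
    if kspace.data.shape[-1] != mask.n_lines:
        raise ValueError(
            f"mask covers {mask.n_lines} lines but k-space has "
            f"{kspace.data.shape[-1]} columns"
        )
    data = kspace.data * mask.sampled_lines[None, None, :]
    return MultiCoilKSpace(data=data, sampled_mask=mask)


def effective_acceleration(mask: SamplingMask) -> float:
    """Total lines divided by sampled lines."""
    return mask.n_lines / int(mask.sampled_lines.sum())
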