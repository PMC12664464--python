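"""Centered, orthonormal 2D Fourier transforms.

A single FFT convention is used project-wide: the DC component sits at the
array center (``fftshift`` layout) and the transform is unitary
(``norm="ortho"``), so white noise keeps its variance between k-space and
image space.  The transform always acts on the last two axes, which lets the
same helpers serve single images ``(rows, cols)`` and coil stacks
``(coil, rows, cols)``.
"""

from __future__ import annotations

import numpy as np

_AXES = (-2, -1)


def fft2c(x: np.ndarray) -> np.ndarray:
    """Centered orthonormal 2D FFT over the last two axes."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=_AXES), axes=_AXES, norm="ortho"),
        axes=_AXES,
    )


def ifft2c(x: np.ndarray) -> np.ndarray:
    """Centered orthonormal 2D inverse FFT over the last two axes."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(x, axes=_AXES), axes=_AXES, norm="ortho"),
        axes=_AXES,
    )
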