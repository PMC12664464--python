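"""File formats: HDF5 k-space containers, CSV masks and maps, PNG export.

The HDF5 layout follows the fastMRI convention of complex datasets named
``kspace`` (coil, row, col) and ``noise`` (coil, sample), with provenance
attributes on the root group.
"""

from __future__ import annotations

from typing import Optional, Tuple

import h5py
import numpy as np

from .phantom import MultiCoilKSpace, NoiseSamples
from .sampling import SamplingMask

__all__ = [
    "save_kspace",
    "load_kspace",
    "save_mask_csv",
    "load_mask_csv",
    "save_map_csv",
    "load_map_csv",
    "save_map_png",
]


def save_kspace(
    path: str,
    kspace: MultiCoilKSpace,
    noise: Optional[NoiseSamples] = None,
    **attrs,
) -> None:
    """Write a k-space container (datasets ``kspace`` and optionally
    ``noise``; keyword arguments become root attributes)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=np.asarray(kspace.data, dtype=complex))
        if noise is not None:
            f.create_dataset("noise", data=np.asarray(noise.samples, dtype=complex))
        for k, v in attrs.items():
            f.attrs[k] = v


def load_kspace(path: str) -> Tuple[MultiCoilKSpace, Optional[NoiseSamples], dict]:
    """Read a k-space container written by `save_kspace`."""
    with h5py.File(path, "r") as f:
        kspace = MultiCoilKSpace(data=f["kspace"][...])
        noise = NoiseSamples(samples=f["noise"][...]) if "noise" in f else None
        attrs = dict(f.attrs)
    return kspace, noise, attrs


def save_mask_csv(path: str, mask: SamplingMask) -> None:
    """One 0/1 value per phase-encode line; ACS interval and nominal R are
    kept in comment headers."""
    header = [f"nominal_R={mask.nominal_R}"]
    if mask.acs is not None:
        header.append(f"acs={mask.acs[0]},{mask.acs[1]}")
    np.savetxt(
        path,
        mask.sampled_lines.astype(int),
        fmt="%d",
        header="\n".join(header),
    )


def load_mask_csv(path: str) -> SamplingMask:
    acs = None
    nominal_R = 1.0
    with open(path) as f:
        for line in f:
            if not line.startswith("#"):
                break
            text = line[1:].strip()
            if text.startswith("acs="):
                lo, hi = text[4:].split(",")
                acs = (int(lo), int(hi))
            elif text.startswith("nominal_R="):
                nominal_R = float(text.split("=", 1)[1])
    lines = np.loadtxt(path, dtype=int).astype(bool)
    return SamplingMask(sampled_lines=lines, acs=acs, nominal_R=nominal_R)


def save_map_csv(path: str, map_2d: np.ndarray) -> None:
    np.savetxt(path, np.asarray(map_2d), delimiter=",")


def load_map_csv(path: str) -> np.ndarray:
    return np.loadtxt(path, delimiter=",")


def save_map_png(
    path: str,
    map_2d: np.ndarray,
    vmin: float = 0.8,
    vmax: float = 2.5,
    cmap: str = "viridis",
    title: Optional[str] = None,
) -> None:
    """Render a map with a fixed colormap scale (default [0.8, 2.5], the
    range used for resolution maps)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(map_2d, vmin=vmin, vmax=vmax, cmap=cmap)
    fig.colorbar(im, ax=ax)
    if title:
        ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
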