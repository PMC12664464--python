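"""Map summaries: anatomy masking, cumulative frequency analysis, quartiles.

Resolution and g-factor maps are only meaningful inside the imaged
anatomy, so summaries are computed over a thresholded support mask.
The cumulative frequency analysis (percentile plot) shows, for each
percentage on the x-axis, the corresponding percentile of the map values
over the masked pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "PercentileCurve",
    "MapSummary",
    "anatomy_mask",
    "cumulative_frequency",
    "summarize",
]


@dataclass
class PercentileCurve:
    """Percentiles of a map over a region of interest."""

    percents: np.ndarray
    values: np.ndarray


@dataclass
class MapSummary:
    """Quartiles and exceedance statistics of a masked map."""

    q25: float
    q50: float
    q75: float
    fraction_above_one: float
    n_invalid: int
    n_valid: int


def anatomy_mask(image: np.ndarray, rel_threshold: float = 0.05) -> np.ndarray:
    """Support mask: pixels at or above ``rel_threshold`` times the image
    maximum, followed by one binary closing pass to fill interior holes."""
    if not 0.0 < rel_threshold < 1.0:
        raise ValueError("rel_threshold must be in (0, 1)")
    mask = image >= rel_threshold * image.max()
    # close on an edge-padded copy so the array border is treated as
    # continuing the image rather than as background
    padded = np.pad(mask, 1, mode="edge")
    mask = ndimage.binary_closing(padded)[1:-1, 1:-1]
    if not mask.any():
        raise ValueError("anatomy mask is empty")
    return mask


def _masked_values(map_2d: np.ndarray, mask: np.ndarray) -> np.ndarray:
    vals = np.asarray(map_2d)[np.asarray(mask, dtype=bool)]
    return vals[np.isfinite(vals)]


def cumulative_frequency(
    map_2d: np.ndarray, mask: np.ndarray, percents: np.ndarray
) -> PercentileCurve:
    """Empirical quantiles (linear interpolation between order statistics,
    the type-7 convention) of the masked, valid map pixels."""
    vals = _masked_values(map_2d, mask)
    if vals.size == 0:
        raise ValueError("no valid pixels under the mask")
    percents = np.asarray(percents, dtype=float)
    values = np.percentile(vals, percents, method="linear")
    return PercentileCurve(percents=percents, values=values)


def summarize(map_2d: np.ndarray, mask: np.ndarray) -> MapSummary:
    """Quartiles, fraction of pixels above 1, and invalid-pixel count of a
    map over the masked region."""
    mask = np.asarray(mask, dtype=bool)
    vals = _masked_values(map_2d, mask)
    if vals.size == 0:
        raise ValueError("no valid pixels under the mask")
    q25, q50, q75 = np.percentile(vals, [25, 50, 75], method="linear")
    n_invalid = int(mask.sum()) - vals.size
    return MapSummary(
        q25=float(q25),
        q50=float(q50),
        q75=float(q75),
        fraction_above_one=float(np.mean(vals > 1.0)),
        n_invalid=n_invalid,
        n_valid=int(vals.size),
    )
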