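"""Transmural extent of infarction along equidistant transmural radii.

The transmural extent of a slice is the average, over ten radii placed
equidistantly across the infarct's circumferential span, of the
percentage of the endocardium-to-epicardium wall path classified as
infarct. On the circular-annulus slice model, radial rays through the
LV center are exactly perpendicular to both boundaries, matching the
clinical chord construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import SliceGeometry, wrap_angle

__all__ = ["TransmuralityResult", "transmural_extent"]


@dataclass(frozen=True)
class TransmuralityResult:
    """Per-slice transmurality.

    ``extent_pct`` is the arithmetic mean of ``per_radius_pct``;
    ``defined`` is False (and the numeric fields NaN/empty) when the
    infarct mask is empty.
    """

    extent_pct: float
    per_radius_pct: np.ndarray
    radius_angles: np.ndarray
    defined: bool

    @staticmethod
    def undefined() -> "TransmuralityResult":
        return TransmuralityResult(
            extent_pct=float("nan"),
            per_radius_pct=np.array([]),
            radius_angles=np.array([]),
            defined=False,
        )


def transmural_extent(
    infarct_mask: np.ndarray,
    geometry: SliceGeometry,
    n_radii: int = 10,
    step_fraction: float = 0.1,
    span_percentiles: tuple[float, float] = (1.0, 99.0),
) -> TransmuralityResult:
    """Average transmural extent of an infarct mask.

    Procedure: the circumferential span of the infarct is estimated from
    the angles of its mask pixels about the LV center (1st-99th
    percentile of the angle distribution, computed circularly so spans
    crossing the +/-180 degree cut are handled); ``n_radii`` rays are
    placed equidistantly across the span, endpoints included; each ray is
    sampled from the endocardial to the epicardial radius at
    ``step_fraction`` of a pixel per step with nearest-pixel mask lookup;
    the per-ray extent is the percentage of sampled wall length
    classified as infarct (not necessarily contiguous), and the slice
    extent is the mean over rays. Samples whose nearest pixel falls
    outside the rasterized myocardium (blood pool, or beyond the
    epicardial boundary) are excluded from the wall length, so a fully
    transmural rasterized infarct reads 100% independent of pixel size. A mask whose span covers the whole
    circumference switches to full-ring mode with rays equidistant over
    360 degrees.
    """
    mask = np.asarray(infarct_mask, dtype=bool)
    if mask.shape != tuple(geometry.grid_shape):
        raise ValueError(f"mask shape {mask.shape} != grid shape {geometry.grid_shape}")
    if n_radii < 1:
        raise ValueError("n_radii must be >= 1")
    rr, cc = np.nonzero(mask)
    if rr.size == 0:
        return TransmuralityResult.undefined()

    spacing = geometry.pixel_spacing
    cx, cy = geometry.center
    theta = np.degrees(np.arctan2(rr * spacing - cy, cc * spacing - cx))

    # circular span: recentre on the mean direction, then take percentiles
    rad = np.radians(theta)
    mu = math.degrees(math.atan2(np.mean(np.sin(rad)), np.mean(np.cos(rad))))
    delta = wrap_angle(theta - mu)
    lo, hi = np.percentile(delta, span_percentiles)
    # the percentile span of a full ring is (p_hi - p_lo)% of 360; treat
    # anything within 2% of that ceiling as circumferentially complete
    full_span = 360.0 * (span_percentiles[1] - span_percentiles[0]) / 100.0
    if hi - lo >= 0.98 * full_span:
        angles = mu + np.arange(n_radii) * 360.0 / n_radii
    elif n_radii == 1:
        angles = np.array([mu + 0.5 * (lo + hi)])
    else:
        angles = mu + np.linspace(lo, hi, n_radii)

    wall = geometry.wall_thickness
    step = step_fraction * spacing
    n_samples = max(int(math.ceil(wall / step)), 2)
    # midpoint sampling of the wall path avoids double counting the
    # boundaries themselves
    t = (np.arange(n_samples) + 0.5) / n_samples
    radii = geometry.endo_radius + t * wall

    from .core import annulus_mask

    myo = annulus_mask(geometry)
    nrows, ncols = mask.shape
    per_radius = np.empty(len(angles))
    for i, ang in enumerate(angles):
        x = cx + radii * math.cos(math.radians(ang))
        y = cy + radii * math.sin(math.radians(ang))
        cols = np.clip(np.rint(x / spacing).astype(int), 0, ncols - 1)
        rows = np.clip(np.rint(y / spacing).astype(int), 0, nrows - 1)
        on_wall = myo[rows, cols]
        if on_wall.any():
            per_radius[i] = 100.0 * np.mean(mask[rows, cols][on_wall])
        else:
            per_radius[i] = 100.0 * np.mean(mask[rows, cols])

    return TransmuralityResult(
        extent_pct=float(np.mean(per_radius)),
        per_radius_pct=per_radius,
        radius_angles=np.asarray(angles, dtype=float) % 360.0,
        defined=True,
    )
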