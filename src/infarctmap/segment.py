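"""Remote-ROI statistics and SD-threshold infarct segmentation.

Infarcted myocardium is segmented as the set of myocardial pixels whose
value strictly exceeds ``mean + k * SD`` of a reference region of
interest drawn in remote (normal) myocardium — ``k = 3`` on native T1
maps and ``k = 5`` on LGE images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from skimage.draw import polygon2mask

from .core import ParametricMap, SliceGeometry, angular_distance, annulus_mask

__all__ = [
    "RemoteStats",
    "InfarctSizeResult",
    "remote_stats",
    "threshold_mask",
    "infarct_size",
    "remote_roi_mask",
]


@dataclass(frozen=True)
class RemoteStats:
    """Sample statistics of the remote-myocardium reference ROI."""

    mean: float
    sd: float
    n_pixels: int
    roi_mask: Optional[np.ndarray] = None

    def threshold(self, k: float) -> float:
        """Segmentation decision boundary ``mean + k * sd``."""
        return self.mean + k * self.sd


@dataclass(frozen=True)
class InfarctSizeResult:
    """Absolute and relative infarct size of one slice.

    ``pct_of_slice_myocardium`` is the infarct pixel count as a
    percentage of the slice's myocardial pixel count (blood pool
    excluded).
    """

    area_mm2: float
    pct_of_slice_myocardium: float
    n_pixels: int
    threshold_used: float
    k: float


def _roi_to_mask(roi: Union[np.ndarray, "np.typing.ArrayLike"], shape: tuple[int, int]) -> np.ndarray:
    roi = np.asarray(roi)
    if roi.dtype == bool and roi.shape == shape:
        return roi
    if roi.ndim == 2 and roi.shape[1] == 2:
        # polygon vertices as (row, col) pairs, in pixel units
        return polygon2mask(shape, roi.astype(float))
    if roi.shape == shape:
        return roi.astype(bool)
    raise ValueError(
        "roi must be a boolean mask matching the map shape or an (N, 2) "
        f"polygon of (row, col) vertices; got shape {roi.shape}"
    )


def remote_stats(
    pmap: ParametricMap,
    roi: np.ndarray,
    min_pixels: int = 20,
    myo_mask: Optional[np.ndarray] = None,
) -> RemoteStats:
    """Mean and sample SD (n - 1 denominator) of the remote ROI pixels.

    ``roi`` is either a boolean mask or an (N, 2) polygon of (row, col)
    vertices rasterized with the pixel-center rule. Missing (NaN) pixels
    are excluded. If ``myo_mask`` is given, an ROI leaking outside the
    myocardium raises a warning (not an error).
    """
    mask = _roi_to_mask(roi, pmap.shape)
    if myo_mask is not None and np.any(mask & ~np.asarray(myo_mask, bool)):
        warnings.warn("remote ROI extends outside the myocardial mask", stacklevel=2)
    vals = pmap.values[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size < min_pixels:
        raise ValueError(
            f"remote ROI has {vals.size} usable pixels; at least {min_pixels} required"
        )
    return RemoteStats(
        mean=float(np.mean(vals)),
        sd=float(np.std(vals, ddof=1)),
        n_pixels=int(vals.size),
        roi_mask=mask,
    )


def threshold_mask(
    pmap: ParametricMap,
    myo_mask: np.ndarray,
    stats: RemoteStats,
    k: float,
    remove_islands: int = 0,
) -> np.ndarray:
    """Binary infarct mask: myocardial pixels with value > mean + k*sd.

    The inequality is strict; ties at the threshold are excluded, as are
    missing (NaN) pixels. No morphological cleanup is applied unless
    ``remove_islands`` > 0, in which case connected components smaller
    than that pixel count are dropped (off by default).
    """
    if not k > 0:
        raise ValueError(f"k must be > 0, got {k}")
    myo = np.asarray(myo_mask, dtype=bool)
    if myo.shape != pmap.shape:
        raise ValueError(f"mask shape {myo.shape} != map shape {pmap.shape}")
    thr = stats.threshold(k)
    with np.errstate(invalid="ignore"):
        mask = myo & np.isfinite(pmap.values) & (pmap.values > thr)
    if remove_islands > 0:
        from scipy import ndimage

        labels, n = ndimage.label(mask)
        if n:
            sizes = np.bincount(labels.ravel())
            keep = sizes >= remove_islands
            keep[0] = False
            mask = keep[labels]
    return mask


def infarct_size(
    infarct_mask: np.ndarray,
    myo_mask: np.ndarray,
    spacing: float,
    threshold_used: float = float("nan"),
    k: float = float("nan"),
) -> InfarctSizeResult:
    """Infarct area (pixel count x spacing^2) and percentage of the
    slice's myocardium."""
    inf = np.asarray(infarct_mask, dtype=bool)
    myo = np.asarray(myo_mask, dtype=bool)
    if inf.shape != myo.shape:
        raise ValueError("mask shapes differ")
    n_myo = int(myo.sum())
    if n_myo == 0:
        raise ValueError("myocardial mask is empty")
    if np.any(inf & ~myo):
        raise ValueError("infarct mask has pixels outside the myocardial mask")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    n = int(inf.sum())
    return InfarctSizeResult(
        area_mm2=n * float(spacing) ** 2,
        pct_of_slice_myocardium=100.0 * n / n_myo,
        n_pixels=n,
        threshold_used=float(threshold_used),
        k=float(k),
    )


def remote_roi_mask(
    geometry: SliceGeometry,
    center_angle_deg: float,
    half_width_deg: float = 30.0,
    radial_margin_mm: float = 0.0,
) -> np.ndarray:
    """Sector-shaped remote ROI wholly inside the myocardial annulus.

    The synthetic pipeline places this 180 degrees away from the infarct
    center; ``radial_margin_mm`` shrinks the ROI away from both
    boundaries.
    """
    r = geometry.radius_map()
    theta = geometry.angle_map()
    radial = (r > geometry.endo_radius + radial_margin_mm) & (
        r <= geometry.epi_radius - radial_margin_mm
    )
    return (
        annulus_mask(geometry)
        & radial
        & (angular_distance(theta, center_angle_deg) <= half_width_deg)
    )
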