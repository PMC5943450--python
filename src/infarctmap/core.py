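"""Core raster/geometry types shared across the pipeline.

Conventions used throughout the package:

* Rasters are 2-D ``numpy`` arrays indexed ``[row, col]``; pixel centers sit
  at integer grid coordinates, with physical position ``x = col * spacing``,
  ``y = row * spacing`` (mm), x to the right and y down.
* A pixel belongs to a region iff its *center* lies inside the region's
  analytic boundary.
* Angles are in degrees in ``[0, 360)``, measured with ``atan2(y - cy,
  x - cx)`` in the image coordinate frame above.
* Missing / unfit pixels in a parametric map carry ``NaN``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

__all__ = [
    "ParametricMap",
    "SliceGeometry",
    "annulus_mask",
    "sector_mask",
    "wrap_angle",
    "angular_distance",
]

MISSING = np.nan

SLICE_LEVELS = ("basal", "mid", "apical")


def wrap_angle(angle_deg):
    """Wrap angle(s) to the half-open interval [-180, 180)."""
    return (np.asarray(angle_deg, dtype=float) + 180.0) % 360.0 - 180.0


def angular_distance(a_deg, b_deg):
    """Absolute circular distance between two angles, in [0, 180]."""
    return np.abs(wrap_angle(np.asarray(a_deg, float) - np.asarray(b_deg, float)))


@dataclass(frozen=True)
class ParametricMap:
    """A 2-D pixel map of a quantitative modality.

    Parameters
    ----------
    values
        2-D raster; milliseconds for T1 maps, arbitrary units for LGE
        signal intensity. ``NaN`` marks missing/unfit pixels.
    pixel_spacing
        In-plane pixel spacing in mm (isotropic).
    modality
        Either ``"T1"`` or ``"LGE"``.
    provenance
        Free-text note on how the map was produced.
    """

    values: np.ndarray
    pixel_spacing: float
    modality: str
    provenance: str = ""

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"map values must be 2-D, got shape {values.shape}")
        if not self.pixel_spacing > 0:
            raise ValueError(f"pixel_spacing must be > 0, got {self.pixel_spacing}")
        if self.modality not in ("T1", "LGE"):
            raise ValueError(f"modality must be 'T1' or 'LGE', got {self.modality!r}")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_area_mm2(self) -> float:
        return float(self.pixel_spacing) ** 2


@dataclass(frozen=True)
class SliceGeometry:
    """Analytic geometry of one short-axis slice.

    The myocardium is modeled as a circular annulus between the
    endocardial and epicardial radii. RV insertion angles anchor the
    AHA sector partition.

    All lengths are in mm, angles in degrees (see module docstring for
    the coordinate convention).
    """

    center: tuple[float, float]
    endo_radius: float
    epi_radius: float
    rv_insertion_anterior: Optional[float] = 120.0
    rv_insertion_inferior: Optional[float] = 240.0
    pixel_spacing: float = 1.4
    grid_shape: tuple[int, int] = (48, 48)
    level: str = "mid"

    def __post_init__(self):
        if not (0 < self.endo_radius < self.epi_radius):
            raise ValueError(
                "degenerate geometry: need 0 < endo_radius < epi_radius, got "
                f"endo={self.endo_radius}, epi={self.epi_radius}"
            )
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be > 0")
        if self.level not in SLICE_LEVELS:
            raise ValueError(f"level must be one of {SLICE_LEVELS}, got {self.level!r}")
        rows, cols = self.grid_shape
        cx, cy = self.center
        xmax = (cols - 1) * self.pixel_spacing
        ymax = (rows - 1) * self.pixel_spacing
        r = self.epi_radius
        if cx - r < 0 or cy - r < 0 or cx + r > xmax or cy + r > ymax:
            raise ValueError(
                f"grid {self.grid_shape} at spacing {self.pixel_spacing} mm is too "
                f"small to contain the epicardial circle (center={self.center}, "
                f"epi_radius={self.epi_radius})"
            )

    @property
    def wall_thickness(self) -> float:
        return self.epi_radius - self.endo_radius

    def pixel_xy(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) coordinate grids of all pixel centers, in mm."""
        rows, cols = self.grid_shape
        y = np.arange(rows, dtype=float)[:, None] * self.pixel_spacing
        x = np.arange(cols, dtype=float)[None, :] * self.pixel_spacing
        return np.broadcast_to(x, (rows, cols)), np.broadcast_to(y, (rows, cols))

    def radius_map(self) -> np.ndarray:
        """Distance (mm) of every pixel center from the LV center."""
        x, y = self.pixel_xy()
        cx, cy = self.center
        return np.hypot(x - cx, y - cy)

    def angle_map(self) -> np.ndarray:
        """Angle (deg in [0, 360)) of every pixel center about the LV center."""
        x, y = self.pixel_xy()
        cx, cy = self.center
        return np.degrees(np.arctan2(y - cy, x - cx)) % 360.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["center"] = list(d["center"])
        d["grid_shape"] = list(d["grid_shape"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SliceGeometry":
        d = dict(d)
        d["center"] = tuple(d["center"])
        d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


def annulus_mask(geometry: SliceGeometry) -> np.ndarray:
    """Boolean myocardial mask: pixel centers with endo < r <= epi."""
    r = geometry.radius_map()
    return (r > geometry.endo_radius) & (r <= geometry.epi_radius)


def sector_mask(
    geometry: SliceGeometry, center_angle_deg: float, angular_extent_deg: float
) -> np.ndarray:
    """Boolean mask of the angular sector |angle - center| <= extent / 2.

    An extent >= 360 selects the full circle; an extent of 0 selects
    nothing (the boundary ray itself has measure zero under the
    pixel-center rule and is deliberately excluded).
    """
    if angular_extent_deg >= 360.0:
        return np.ones(geometry.grid_shape, dtype=bool)
    if angular_extent_deg <= 0.0:
        return np.zeros(geometry.grid_shape, dtype=bool)
    theta = geometry.angle_map()
    return angular_distance(theta, center_angle_deg) <= angular_extent_deg / 2.0
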