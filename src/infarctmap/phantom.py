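"""Synthetic short-axis phantom generator.

Builds digital left-ventricular slices that stand in for 2-week
post-infarct swine data: a circular myocardial annulus containing an
annular-sector infarct anchored at the endocardium, with pixelwise
Gaussian tissue statistics for both native T1 (ms) and LGE signal
intensity (a.u.), exact ground-truth masks, and simulated MOLLI
inversion-recovery series.

The default tissue statistics are the cohort-average values observed in
2-week reperfused swine infarcts at 1.5 T: remote myocardium
995 +/- 48 ms native T1 and 21 +/- 8.4 a.u. LGE signal, infarct
1347 +/- 89 ms and 112.6 +/- 17 a.u.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import ParametricMap, SliceGeometry, annulus_mask, sector_mask

__all__ = [
    "TissueStats",
    "InfarctSpec",
    "Phantom",
    "MolliSeries",
    "CohortVariation",
    "Cohort",
    "DEFAULT_TISSUE",
    "default_geometry",
    "make_phantom",
    "default_inversion_times",
    "make_molli_series",
    "make_cohort",
]


@dataclass(frozen=True)
class TissueStats:
    """Per-class pixel statistics for the two modalities.

    Means/SDs are in ms for T1 and arbitrary units for LGE signal
    intensity. Pixels of each tissue class are drawn i.i.d. Gaussian
    around the class mean.
    """

    remote_t1_mean: float = 995.0
    remote_t1_sd: float = 48.0
    infarct_t1_mean: float = 1347.0
    infarct_t1_sd: float = 89.0
    remote_lge_mean: float = 21.0
    remote_lge_sd: float = 8.4
    infarct_lge_mean: float = 112.6
    infarct_lge_sd: float = 17.0

    def __post_init__(self):
        for name in ("remote_t1_sd", "infarct_t1_sd", "remote_lge_sd", "infarct_lge_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.infarct_t1_mean > self.remote_t1_mean:
            raise ValueError("infarct T1 mean must exceed remote T1 mean")
        if not self.infarct_lge_mean > self.remote_lge_mean:
            raise ValueError("infarct LGE mean must exceed remote LGE mean")


DEFAULT_TISSUE = TissueStats()


@dataclass(frozen=True)
class InfarctSpec:
    """Analytic infarct geometry: an annular sector anchored at the
    endocardium and extending outward through ``transmural_depth`` of the
    wall thickness.

    ``angular_extent = 0`` means no infarct. ``smooth_edge`` enables a
    one-pixel linear blend of tissue means across the infarct border
    (ground-truth masks stay crisp either way).
    """

    center_angle: float = 60.0
    angular_extent: float = 120.0
    transmural_depth: float = 0.8
    smooth_edge: bool = False

    def __post_init__(self):
        if not (0.0 <= self.angular_extent <= 360.0):
            raise ValueError("angular_extent must be in [0, 360]")
        if not (0.0 <= self.transmural_depth <= 1.0):
            raise ValueError("transmural_depth must be in [0, 1]")


@dataclass(frozen=True)
class Phantom:
    """One synthetic short-axis slice with exact ground truth."""

    geometry: SliceGeometry
    infarct: InfarctSpec
    tissue: TissueStats
    t1_map: ParametricMap
    lge_image: ParametricMap
    myo_mask: np.ndarray
    gt_infarct_mask: np.ndarray
    gt_size_pct: float
    gt_transmurality_pct: float  # NaN when there is no infarct
    seed: int


# Plausible swine LV radii by slice level (mm); not calibrated to any
# measured wall thickness — configurable through `default_geometry`.
_LEVEL_RADII = {"basal": (13.0, 21.0), "mid": (12.0, 20.0), "apical": (9.0, 16.0)}


def default_geometry(
    level: str = "mid",
    pixel_spacing: float = 1.4,
    endo_radius: Optional[float] = None,
    epi_radius: Optional[float] = None,
    margin_mm: float = 4.0,
) -> SliceGeometry:
    """A centered geometry for the given slice level, with a grid sized
    to contain the epicardial circle plus ``margin_mm`` on every side."""
    if level not in _LEVEL_RADII:
        raise ValueError(f"unknown level {level!r}")
    endo0, epi0 = _LEVEL_RADII[level]
    endo = endo0 if endo_radius is None else endo_radius
    epi = epi0 if epi_radius is None else epi_radius
    half = epi + margin_mm
    n = int(math.ceil(2 * half / pixel_spacing)) + 1
    c = (n - 1) / 2.0 * pixel_spacing
    return SliceGeometry(
        center=(c, c),
        endo_radius=endo,
        epi_radius=epi,
        pixel_spacing=pixel_spacing,
        grid_shape=(n, n),
        level=level,
    )


def _infarct_mask(geometry: SliceGeometry, infarct: InfarctSpec, myo: np.ndarray) -> np.ndarray:
    if infarct.angular_extent <= 0 or infarct.transmural_depth <= 0:
        return np.zeros(geometry.grid_shape, dtype=bool)
    outer = geometry.endo_radius + infarct.transmural_depth * geometry.wall_thickness
    r = geometry.radius_map()
    sector = sector_mask(geometry, infarct.center_angle, infarct.angular_extent)
    return myo & sector & (r <= outer)


def make_phantom(
    geometry: Optional[SliceGeometry] = None,
    infarct: InfarctSpec = InfarctSpec(),
    tissue: TissueStats = DEFAULT_TISSUE,
    seed: int = 0,
) -> Phantom:
    """Generate one synthetic slice.

    Pixel values are i.i.d. Gaussian around the pixel's true-class mean;
    pixels outside the myocardium are zero. The same seed yields
    bit-identical output.
    """
    if geometry is None:
        geometry = default_geometry()
    myo = annulus_mask(geometry)
    if not myo.any():
        raise ValueError("grid too small: myocardial mask is empty")
    gt = _infarct_mask(geometry, infarct, myo)

    if infarct.smooth_edge and gt.any():
        # linear one-pixel blend of the class-mean field across the border
        d_in = ndimage.distance_transform_edt(gt)
        d_out = ndimage.distance_transform_edt(~gt)
        signed = np.where(gt, d_in, -d_out)
        w = np.clip((signed + 1.5) / 3.0, 0.0, 1.0)
    else:
        w = gt.astype(float)

    rng = np.random.default_rng(seed)
    z_t1 = rng.standard_normal(geometry.grid_shape)
    z_lge = rng.standard_normal(geometry.grid_shape)

    t1_mean = tissue.remote_t1_mean + w * (tissue.infarct_t1_mean - tissue.remote_t1_mean)
    t1_sd = tissue.remote_t1_sd + w * (tissue.infarct_t1_sd - tissue.remote_t1_sd)
    lge_mean = tissue.remote_lge_mean + w * (tissue.infarct_lge_mean - tissue.remote_lge_mean)
    lge_sd = tissue.remote_lge_sd + w * (tissue.infarct_lge_sd - tissue.remote_lge_sd)

    t1_values = np.where(myo, t1_mean + t1_sd * z_t1, 0.0)
    lge_values = np.where(myo, lge_mean + lge_sd * z_lge, 0.0)

    n_myo = int(myo.sum())
    n_inf = int(gt.sum())
    gt_size_pct = 100.0 * n_inf / n_myo
    gt_tm = 100.0 * infarct.transmural_depth if n_inf > 0 else float("nan")

    return Phantom(
        geometry=geometry,
        infarct=infarct,
        tissue=tissue,
        t1_map=ParametricMap(t1_values, geometry.pixel_spacing, "T1", "phantom"),
        lge_image=ParametricMap(lge_values, geometry.pixel_spacing, "LGE", "phantom"),
        myo_mask=myo,
        gt_infarct_mask=gt,
        gt_size_pct=gt_size_pct,
        gt_transmurality_pct=gt_tm,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# MOLLI series simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MolliSeries:
    """A stack of inversion-recovery rasters, one per inversion time.

    ``frames`` has shape ``(n_ti, rows, cols)``. ``magnitude`` records
    whether frames carry |S| (True) or signed S (False).
    """

    frames: np.ndarray
    inversion_times: np.ndarray  # ms, strictly increasing
    magnitude: bool
    scheme: str
    b_over_a: float
    a_signal: float
    pixel_spacing: float


def default_inversion_times(
    scheme: str = "3(3)5",
    rr_ms: float = 800.0,
    ti_first_ms: float = 100.0,
    ti_second_ms: float = 180.0,
) -> np.ndarray:
    """Inversion times of the standard two-inversion MOLLI scheme.

    ``"3(3)5"``: 3 images one RR apart after the first inversion, a
    3-heartbeat pause, then 5 images one RR apart after the second
    inversion, giving 8 effective TIs interleaved on the recovery curve.
    """
    if scheme != "3(3)5":
        raise ValueError(f"unsupported MOLLI scheme {scheme!r}")
    first = ti_first_ms + rr_ms * np.arange(3)
    second = ti_second_ms + rr_ms * np.arange(5)
    return np.sort(np.concatenate([first, second]))


def make_molli_series(
    phantom: Phantom,
    inversion_times: Optional[Sequence[float]] = None,
    scheme: str = "3(3)5",
    b_over_a: float = 2.0,
    a_signal: float = 100.0,
    noise_sd: float = 0.0,
    magnitude: bool = False,
    seed: Optional[int] = None,
) -> MolliSeries:
    """Simulate an inversion-recovery image series from the phantom's T1 map.

    The per-pixel signal follows the three-parameter Look-Locker model
    ``S(TI) = A - B exp(-TI / T1*)`` with ``B = b_over_a * A`` and the
    apparent time ``T1* = T1 / (b_over_a - 1)``, so that the Look-Locker
    correction ``T1 = T1* (B/A - 1)`` recovers the generating T1 exactly.
    With the ideal-inversion default ``b_over_a = 2``, ``T1* = T1``.
    """
    tis = default_inversion_times(scheme) if inversion_times is None else np.asarray(
        inversion_times, dtype=float
    )
    if tis.size < 3:
        raise ValueError(f"need at least 3 inversion times, got {tis.size}")
    if np.any(np.diff(tis) <= 0):
        raise ValueError("inversion times must be strictly increasing")
    if b_over_a <= 1.0:
        raise ValueError("b_over_a must exceed 1 (inversion must cross zero)")

    t1 = phantom.t1_map.values
    a = float(a_signal)
    b = b_over_a * a
    t1_star = np.where(t1 > 0, t1 / (b_over_a - 1.0), np.inf)
    # background (t1 <= 0) pixels stay at the fully recovered value A
    frames = a - b * np.exp(-tis[:, None, None] / t1_star[None, :, :])
    frames = np.where(t1[None] > 0, frames, a)

    if noise_sd > 0:
        rng = np.random.default_rng(phantom.seed if seed is None else seed)
        frames = frames + noise_sd * rng.standard_normal(frames.shape)
    if magnitude:
        frames = np.abs(frames)

    return MolliSeries(
        frames=frames,
        inversion_times=tis,
        magnitude=magnitude,
        scheme=scheme,
        b_over_a=b_over_a,
        a_signal=a,
        pixel_spacing=phantom.geometry.pixel_spacing,
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortVariation:
    """Between-animal variation of the cohort generator.

    Tissue-mean SDs reproduce the inter-animal spread of per-animal mean
    values in the 2-week swine cohort; infarct geometry varies mildly
    around an ~120 degree sector at ~80% transmural depth, which yields
    slice infarct sizes in the 25-30% range. Basal slices are generated
    infarct-free by default.
    """

    remote_t1_mean_sd: float = 38.0
    infarct_t1_mean_sd: float = 76.0
    remote_lge_mean_sd: float = 5.8
    # LGE enhancement is positive and right-skewed across animals, so the
    # infarct-mean jitter is lognormal (sigma on the log scale)
    infarct_lge_mean_log_sd: float = 0.34
    center_angle_mean: float = 60.0
    center_angle_sd: float = 15.0
    angular_extent_mean: float = 120.0
    angular_extent_sd: float = 15.0
    transmural_depth_mean: float = 0.8
    transmural_depth_sd: float = 0.05
    basal_infarct_free: bool = True


@dataclass(frozen=True)
class Cohort:
    """A list of phantoms keyed by (animal_id, level) plus a manifest of
    all ground truth."""

    phantoms: dict
    manifest: pd.DataFrame

    def slices(self):
        return sorted(self.phantoms.items())


def make_cohort(
    n_animals: int = 10,
    variation: CohortVariation = CohortVariation(),
    tissue: TissueStats = DEFAULT_TISSUE,
    seed: int = 0,
    pixel_spacing: float = 1.4,
    noise_scale: float = 1.0,
) -> Cohort:
    """Generate a cohort of ``n_animals`` animals x (basal, mid, apical).

    Per-animal tissue means are jittered around the cohort averages with
    the stated between-animal SDs; within-tissue pixel SDs are scaled by
    ``noise_scale`` (0 gives noise-free slices and, with zero variation,
    identical animals).
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    rng = np.random.default_rng(seed)
    phantoms: dict = {}
    rows = []
    for animal in range(1, n_animals + 1):
        jitter = rng.standard_normal(4)
        remote_t1 = tissue.remote_t1_mean + variation.remote_t1_mean_sd * jitter[0]
        infarct_t1 = tissue.infarct_t1_mean + variation.infarct_t1_mean_sd * jitter[1]
        remote_lge = tissue.remote_lge_mean + variation.remote_lge_mean_sd * jitter[2]
        infarct_lge = tissue.infarct_lge_mean * math.exp(
            variation.infarct_lge_mean_log_sd * jitter[3]
        )
        # keep the class ordering invariant under extreme jitter draws
        remote_lge = max(remote_lge, 5.0)
        infarct_t1 = max(infarct_t1, remote_t1 + 50.0)
        infarct_lge = max(infarct_lge, remote_lge + 5.0)
        animal_tissue = TissueStats(
            remote_t1_mean=remote_t1,
            remote_t1_sd=tissue.remote_t1_sd * noise_scale,
            infarct_t1_mean=infarct_t1,
            infarct_t1_sd=tissue.infarct_t1_sd * noise_scale,
            remote_lge_mean=remote_lge,
            remote_lge_sd=tissue.remote_lge_sd * noise_scale,
            infarct_lge_mean=infarct_lge,
            infarct_lge_sd=tissue.infarct_lge_sd * noise_scale,
        )
        center = variation.center_angle_mean + variation.center_angle_sd * rng.standard_normal()
        extent = variation.angular_extent_mean + variation.angular_extent_sd * rng.standard_normal()
        extent = float(np.clip(extent, 30.0, 359.0))
        depth = variation.transmural_depth_mean + variation.transmural_depth_sd * rng.standard_normal()
        depth = float(np.clip(depth, 0.2, 1.0))
        for level in ("basal", "mid", "apical"):
            if level == "basal" and variation.basal_infarct_free:
                spec = InfarctSpec(center_angle=center, angular_extent=0.0, transmural_depth=0.0)
            else:
                spec = InfarctSpec(
                    center_angle=center % 360.0,
                    angular_extent=extent,
                    transmural_depth=depth,
                )
            slice_seed = int(rng.integers(0, 2**31 - 1))
            ph = make_phantom(
                geometry=default_geometry(level, pixel_spacing=pixel_spacing),
                infarct=spec,
                tissue=animal_tissue,
                seed=slice_seed,
            )
            phantoms[(animal, level)] = ph
            rows.append(
                {
                    "animal_id": animal,
                    "level": level,
                    "seed": slice_seed,
                    "center_angle_deg": spec.center_angle,
                    "angular_extent_deg": spec.angular_extent,
                    "transmural_depth": spec.transmural_depth,
                    "gt_size_pct": ph.gt_size_pct,
                    "gt_transmurality_pct": ph.gt_transmurality_pct,
                    "remote_t1_mean": animal_tissue.remote_t1_mean,
                    "infarct_t1_mean": animal_tissue.infarct_t1_mean,
                    "remote_lge_mean": animal_tissue.remote_lge_mean,
                    "infarct_lge_mean": animal_tissue.infarct_lge_mean,
                }
            )
    return Cohort(phantoms=phantoms, manifest=pd.DataFrame(rows))
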