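"""AHA segmentation of short-axis slices and segment-level scoring.

Each slice's myocardium is partitioned into the standard American Heart
Association circumferential segments — 6 equal 60-degree sectors on
basal (segments 1-6) and mid-ventricular (7-12) slices, 4 equal
90-degree sectors on apical slices (13-16) — anchored at the anterior RV
insertion point. The apical-cap segment 17 has no short-axis extent and
is not produced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import ParametricMap, SliceGeometry

__all__ = [
    "ContrastResult",
    "segment_ids_for_level",
    "partition_segments",
    "segment_table",
    "normalized_difference",
    "contrast_result",
]

SEGMENT_TABLE_COLUMNS = [
    "animal_id",
    "slice_level",
    "segment_id",
    "n_pixels",
    "mean_t1",
    "lge_positive",
    "reference_positive",
    "t1_positive_at_cutoff",
    "excluded",
]

_LEVEL_BASE = {"basal": 1, "mid": 7, "apical": 13}
_LEVEL_COUNT = {"basal": 6, "mid": 6, "apical": 4}


@dataclass(frozen=True)
class ContrastResult:
    """Infarct-to-remote contrast of one modality."""

    infarct_mean: float
    remote_mean: float
    normalized_difference: float


def segment_ids_for_level(level: str) -> list[int]:
    base = _LEVEL_BASE[level]
    return list(range(base, base + _LEVEL_COUNT[level]))


def partition_segments(
    geometry: SliceGeometry,
    myo_mask: np.ndarray,
    level: Optional[str] = None,
) -> np.ndarray:
    """Label raster of AHA segments over the myocardial mask.

    Sector boundaries lie at ``anchor + i * width`` with the anchor at
    the anterior RV insertion; returns an int raster with segment ids
    (0 outside the myocardium). The segments are disjoint and exhaust
    the mask by construction.
    """
    if level is None:
        level = geometry.level
    if level not in _LEVEL_COUNT:
        raise ValueError(f"unknown slice level {level!r}")
    if geometry.rv_insertion_anterior is None:
        raise ValueError("anterior RV insertion landmark is required to anchor segments")
    myo = np.asarray(myo_mask, dtype=bool)
    if myo.shape != tuple(geometry.grid_shape):
        raise ValueError("mask shape does not match geometry grid")
    n_seg = _LEVEL_COUNT[level]
    width = 360.0 / n_seg
    theta = geometry.angle_map()
    idx = np.floor(((theta - geometry.rv_insertion_anterior) % 360.0) / width).astype(int)
    idx = np.minimum(idx, n_seg - 1)  # guard the 360-degree wrap edge case
    labels = np.where(myo, _LEVEL_BASE[level] + idx, 0)
    return labels


def segment_table(
    t1_map: ParametricMap,
    lge_mask: np.ndarray,
    reference_mask: np.ndarray,
    labels: np.ndarray,
    t1_cutoff: Optional[float] = None,
    animal_id: Optional[int] = None,
    slice_level: Optional[str] = None,
) -> pd.DataFrame:
    """Per-segment mean T1 and modality positivity.

    A segment is positive on a modality iff at least one of that
    modality's infarct-mask pixels falls inside it ("any pixel" rule).
    ``t1_positive_at_cutoff`` applies ``mean_t1 > cutoff`` when a cutoff
    is supplied. Segments with no usable myocardial pixels are flagged
    ``excluded`` and should be dropped from ROC analysis.
    """
    labels = np.asarray(labels)
    lge = np.asarray(lge_mask, dtype=bool)
    ref = np.asarray(reference_mask, dtype=bool)
    for arr, name in ((lge, "lge_mask"), (ref, "reference_mask")):
        if arr.shape != t1_map.shape:
            raise ValueError(f"{name} shape {arr.shape} != map shape {t1_map.shape}")
    if labels.shape != t1_map.shape:
        raise ValueError("labels shape does not match map shape")

    rows = []
    for seg in sorted(np.unique(labels[labels > 0])):
        in_seg = labels == seg
        vals = t1_map.values[in_seg]
        vals = vals[np.isfinite(vals)]
        n = int(vals.size)
        mean_t1 = float(np.mean(vals)) if n else float("nan")
        rows.append(
            {
                "animal_id": animal_id,
                "slice_level": slice_level,
                "segment_id": int(seg),
                "n_pixels": n,
                "mean_t1": mean_t1,
                "lge_positive": bool(np.any(lge & in_seg)),
                "reference_positive": bool(np.any(ref & in_seg)),
                "t1_positive_at_cutoff": (
                    bool(mean_t1 > t1_cutoff) if (t1_cutoff is not None and n) else None
                ),
                "excluded": n == 0,
            }
        )
    return pd.DataFrame(rows, columns=SEGMENT_TABLE_COLUMNS)


def normalized_difference(infarct_mean: float, remote_mean: float) -> float:
    """Relative infarct-to-remote contrast ``(infarct - remote) / remote``."""
    if not remote_mean > 0:
        raise ValueError(f"remote mean must be positive, got {remote_mean}")
    return (infarct_mean - remote_mean) / remote_mean


def contrast_result(infarct_mean: float, remote_mean: float) -> ContrastResult:
    return ContrastResult(
        infarct_mean=float(infarct_mean),
        remote_mean=float(remote_mean),
        normalized_difference=normalized_difference(infarct_mean, remote_mean),
    )
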