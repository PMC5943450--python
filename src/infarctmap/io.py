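"""NIfTI and CSV input/output.

Maps and masks round-trip through NIfTI-1 with the in-plane pixel
spacing (and a nominal 6 mm slice thickness) in the header zooms;
tables round-trip through CSV with named-column validation.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import nibabel as nib
import numpy as np
import pandas as pd

from .core import ParametricMap

__all__ = [
    "write_map",
    "read_map",
    "write_mask",
    "read_mask",
    "write_table",
    "read_table",
    "write_json",
]

DEFAULT_SLICE_THICKNESS_MM = 6.0

PathLike = Union[str, Path]


def _affine(spacing: float) -> np.ndarray:
    return np.diag([float(spacing), float(spacing), DEFAULT_SLICE_THICKNESS_MM, 1.0])


def write_map(pmap: ParametricMap, path: PathLike) -> None:
    """Write a parametric map as a single-slice NIfTI (float64, exact)."""
    img = nib.Nifti1Image(pmap.values[:, :, None].astype(np.float64), _affine(pmap.pixel_spacing))
    img.header.set_zooms((pmap.pixel_spacing, pmap.pixel_spacing, DEFAULT_SLICE_THICKNESS_MM))
    img.header["descrip"] = f"{pmap.modality}|{pmap.provenance}"[:79].encode()
    nib.save(img, str(path))


def read_map(path: PathLike, modality: Optional[str] = None) -> ParametricMap:
    """Read a parametric map; spacing comes from the header zooms."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        if data.shape[2] != 1:
            raise ValueError(f"expected a single-slice image, got shape {data.shape}")
        data = data[:, :, 0]
    elif data.ndim != 2:
        raise ValueError(f"expected a 2-D or single-slice 3-D image, got shape {data.shape}")
    zooms = img.header.get_zooms()
    spacing = float(zooms[0])
    if spacing <= 0:
        raise ValueError(f"non-positive pixel spacing in header: {spacing}")
    descrip = img.header["descrip"].tobytes().split(b"\x00")[0].decode(errors="replace")
    stored_modality, _, provenance = descrip.partition("|")
    if modality is None:
        modality = stored_modality if stored_modality in ("T1", "LGE") else "T1"
    return ParametricMap(data, spacing, modality, provenance)


def write_mask(mask: np.ndarray, spacing: float, path: PathLike) -> None:
    """Write a binary mask as uint8 NIfTI."""
    arr = np.asarray(mask, dtype=bool).astype(np.uint8)[:, :, None]
    img = nib.Nifti1Image(arr, _affine(spacing))
    img.header.set_zooms((spacing, spacing, DEFAULT_SLICE_THICKNESS_MM))
    nib.save(img, str(path))


def read_mask(path: PathLike) -> tuple[np.ndarray, float]:
    """Read a binary mask; returns (bool array, pixel spacing)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[:, :, 0]
    spacing = float(img.header.get_zooms()[0])
    if spacing <= 0:
        raise ValueError(f"non-positive pixel spacing in header: {spacing}")
    return data.astype(bool), spacing


def write_table(df: pd.DataFrame, path: PathLike) -> None:
    """Write a table as CSV with a stable float format (round-trips to
    full double precision via repr-style %.17g)."""
    df.to_csv(str(path), index=False, float_format="%.17g")


def read_table(path: PathLike, required: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Read a CSV table, verifying that all ``required`` columns exist."""
    df = pd.read_csv(str(path))
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"table {path} is missing required column(s): {missing}")
    return df


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_json(obj: dict, path: PathLike) -> None:
    """Deterministic JSON dump (sorted keys, fixed separators)."""
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_json_default, allow_nan=True)
        + "\n"
    )
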