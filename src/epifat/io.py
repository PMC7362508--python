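"""NIfTI / CSV / JSON input-output.

Volumes travel as NIfTI-1 with voxel spacing in the header affine, axis
order fixed to (x, y, z[, t]); arrays round-trip voxel-identically with
their on-disk dtype preserved.  Measurement tables are tidy CSV; sidecars
and reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "EpifatIOError",
    "read_volume",
    "write_volume",
    "read_sidecar",
    "write_roi_json",
    "read_roi_json",
    "read_observer_table",
    "write_observer_table",
]


class EpifatIOError(Exception):
    """Raised for missing, malformed or unwritable image/table files."""


def write_volume(volume: np.ndarray, spacing_mm: Sequence[float],
                 path: str | Path) -> Path:
    """Write a 3D or 4D volume as NIfTI-1 with the given spatial spacing."""
    volume = np.asarray(volume)
    if volume.ndim not in (3, 4):
        raise EpifatIOError("volume must be 3D (x,y,z) or 4D (x,y,z,t)")
    spacing = tuple(float(s) for s in spacing_mm)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise EpifatIOError("spacing_mm must be three positive values")
    affine = np.diag([*spacing, 1.0])
    img = nib.Nifti1Image(volume, affine)
    path = Path(path)
    try:
        nib.save(img, path)
    except OSError as err:
        raise EpifatIOError(f"cannot write volume to {path}: {err}") from err
    return path


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume; returns (array, (sx, sy, sz) in mm).

    The on-disk dtype is preserved (no float casting), so write/read
    round-trips are voxel-identical.  Truncated or malformed files raise
    :class:`EpifatIOError` without a partial result.
    """
    path = Path(path)
    if not path.exists():
        raise EpifatIOError(f"no such volume file: {path}")
    try:
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
    except Exception as err:  # nibabel raises a zoo of error types
        raise EpifatIOError(f"cannot read volume {path}: {err}") from err
    zooms = img.header.get_zooms()[:3]
    spacing = tuple(float(z) for z in zooms)
    if any(s <= 0 for s in spacing):
        raise EpifatIOError(f"non-positive voxel spacing in {path}: {spacing}")
    return data, spacing


def read_sidecar(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise EpifatIOError(f"no such sidecar file: {path}")
    with open(path) as fh:
        return json.load(fh)


def write_roi_json(polygons: Mapping[int, np.ndarray],
                   slice_range: tuple[int, int], path: str | Path,
                   frame_index: int = 0) -> Path:
    """Per-slice outer-boundary polygons, voxel (x, y) coordinates."""
    payload = {
        "slice_range": list(slice_range),
        "frame_index": frame_index,
        "slices": {str(z): np.asarray(p, dtype=float).tolist()
                   for z, p in polygons.items()},
    }
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
    return path


def read_roi_json(path: str | Path) -> tuple[dict[int, np.ndarray],
                                             tuple[int, int], int]:
    path = Path(path)
    if not path.exists():
        raise EpifatIOError(f"no such ROI file: {path}")
    with open(path) as fh:
        payload = json.load(fh)
    try:
        polys = {int(z): np.asarray(p, dtype=float)
                 for z, p in payload["slices"].items()}
        lo, hi = payload["slice_range"]
        frame = int(payload.get("frame_index", 0))
    except (KeyError, TypeError, ValueError) as err:
        raise EpifatIOError(f"malformed ROI file {path}: {err}") from err
    return polys, (int(lo), int(hi)), frame


def read_observer_table(path: str | Path) -> pd.DataFrame:
    from .stats import validate_observer_table

    path = Path(path)
    if not path.exists():
        raise EpifatIOError(f"no such table: {path}")
    return validate_observer_table(pd.read_csv(path))


def write_observer_table(table: pd.DataFrame, path: str | Path) -> Path:
    from .stats import validate_observer_table

    validate_observer_table(table)
    path = Path(path)
    table.to_csv(path, index=False)
    return path
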