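"""Fat-fraction mapping: FF = F / (F + W) per voxel.

Signal voids (F + W below a small epsilon) map to FF = 0 so that chamber
and background voxels fall below the fat classification threshold; values
are clamped to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["FatFractionMap", "compute_ff"]

logger = logging.getLogger(__name__)


@dataclass
class FatFractionMap:
    """Per-voxel fat fraction in [0, 1], aligned to its source W/F volumes."""

    ff: np.ndarray
    spacing: tuple[float, float, float] | None = None
    frame_time_ms: float | None = None

    def frame(self, index: int) -> np.ndarray:
        """One 3D frame of a 4D cine FF map."""
        if self.ff.ndim != 4:
            raise ValueError("frame() requires a 4D (x, y, z, t) FF map")
        return self.ff[..., index]


def compute_ff(water: np.ndarray, fat: np.ndarray,
               eps: float | None = None,
               spacing: tuple[float, float, float] | None = None,
               frame_time_ms: float | None = None) -> FatFractionMap:
    """FF = F / (F + W) per voxel, with the signal-void convention.

    Parameters
    ----------
    water, fat : ndarray
        Same-shape non-negative magnitude images; negative values are
        clipped to zero (a count is logged).
    eps : float, optional
        Denominator floor; voxels with ``F + W <= eps`` get FF = 0.
        Defaults to 1e-6 of the maximum channel signal.
    """
    water = np.asarray(water, dtype=float)
    fat = np.asarray(fat, dtype=float)
    if water.shape != fat.shape:
        raise ValueError("water and fat shapes differ")
    n_neg = int((water < 0).sum() + (fat < 0).sum())
    if n_neg:
        logger.warning("clipped %d negative input voxels to 0", n_neg)
        water = np.clip(water, 0.0, None)
        fat = np.clip(fat, 0.0, None)
    if eps is None:
        peak = max(float(water.max(initial=0.0)), float(fat.max(initial=0.0)))
        eps = 1e-6 * peak if peak > 0 else 1e-12
    elif eps <= 0:
        raise ValueError("eps must be a small positive scalar")

    denom = water + fat
    ff = np.zeros_like(denom)
    good = denom > eps
    ff[good] = fat[good] / denom[good]
    ff = np.clip(ff, 0.0, 1.0)
    return FatFractionMap(ff=ff, spacing=spacing, frame_time_ms=frame_time_ms)
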