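"""Synthetic cine Dixon cardiac phantom.

Generates seeded water/fat (and optional complex two-echo) image series of a
stylized axial whole-heart geometry: a contrast-bright blood pool inside a
myocardial shell, wrapped in an epicardial fat rind, a one-voxel parietal
pericardium, a static paracardial fat slab outside the pericardium, and
static lungs.  The cardiac compartments translate longitudinally (the
atrioventricular-plane descent toward the apex in systole) and contract
radially over the cine cycle, while the paracardial fat stays put -- the
motion contrast that makes the epicardial/paracardial boundary visible in
time-resolved imaging.

All randomness (channel noise) flows from ``PhantomSpec.seed``; the anatomy
itself is a deterministic function of the spec.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import ndimage

from .quantify import EpicardialROISet

__all__ = [
    "Tissue",
    "PhantomSpec",
    "TissueLabelMap",
    "DixonSeries",
    "GroundTruth",
    "build_anatomy",
    "render_dixon",
    "synthesize_echoes",
    "export_dataset",
    "import_dataset",
]

logger = logging.getLogger(__name__)

# Water-fat chemical shift at 1.5 T (3.5 ppm), Hz.  Fat precesses slower
# than water, hence the negative sign.
DEFAULT_WATER_FAT_SHIFT_HZ = -220.0


class Tissue:
    """Integer labels of the phantom compartments."""

    BACKGROUND = 0
    LUNG = 1
    BLOOD_POOL = 2
    MYOCARDIUM = 3
    EPICARDIAL_FAT = 4
    PERICARDIUM = 5
    PARACARDIAL_FAT = 6

    NAMES = {
        BACKGROUND: "background",
        LUNG: "lung",
        BLOOD_POOL: "blood_pool",
        MYOCARDIUM: "myocardium",
        EPICARDIAL_FAT: "epicardial_fat",
        PERICARDIUM: "pericardium",
        PARACARDIAL_FAT: "paracardial_fat",
    }

    #: labels attached to the beating heart (move with the cine phase)
    CARDIAC = (BLOOD_POOL, MYOCARDIUM, EPICARDIAL_FAT, PERICARDIUM)
    #: labels that stay fixed over the cycle
    STATIC = (BACKGROUND, LUNG, PARACARDIAL_FAT)


def _default_tissue_ff() -> dict[str, float]:
    # True fat fractions.  Everything non-adipose sits far below the 0.35
    # classification threshold; both fat depots sit far above it.
    return {
        "background": 0.0,
        "lung": 0.10,
        "blood_pool": 0.02,
        "myocardium": 0.05,
        "epicardial_fat": 0.80,
        "pericardium": 0.10,
        "paracardial_fat": 0.85,
    }


def _default_total_signal() -> dict[str, float]:
    # Noiseless W+F amplitude per tissue, in arbitrary units with the
    # contrast-enhanced blood pool as the brightest compartment (unity).
    return {
        "background": 0.0,
        "lung": 0.05,
        "blood_pool": 1.0,
        "myocardium": 0.60,
        "epicardial_fat": 0.90,
        "pericardium": 0.40,
        "paracardial_fat": 0.90,
    }


def _signals_from_ff(ff: Mapping[str, float], total: Mapping[str, float]):
    water = {t: (1.0 - ff[t]) * total[t] for t in ff}
    fat = {t: ff[t] * total[t] for t in ff}
    return water, fat


_DEF_W, _DEF_F = _signals_from_ff(_default_tissue_ff(), _default_total_signal())


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic cine Dixon acquisition.

    Defaults follow the study geometry: acquired voxel 1.5 x 1.5 x 3.0 mm,
    15 cine frames at 65 ms temporal resolution.  ``motion_amplitude_mm`` is
    the peak longitudinal (apical) displacement of the atrioventricular
    plane; ``contraction_fraction`` the peak in-plane radial contraction of
    the cardiac compartments, both following a sin^2 systolic time course.
    Ellipsoid semi-axes are in millimetres.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 40)
    voxel_spacing_mm: tuple[float, float, float] = (1.5, 1.5, 3.0)
    n_frames: int = 15
    rr_interval_ms: float = 975.0
    tissue_ff: Mapping[str, float] = field(default_factory=_default_tissue_ff)
    tissue_water_signal: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEF_W))
    tissue_fat_signal: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEF_F))
    motion_amplitude_mm: float = 12.0
    contraction_fraction: float = 0.12
    noise_sigma: float = 0.02
    fieldmap_hz: float | None = None
    seed: int = 0
    # geometry (mm): heart centre and outer semi-axes of the nested shells
    heart_center_mm: tuple[float, float, float] = (48.0, 46.0, 62.0)
    blood_pool_radii_mm: tuple[float, float, float] = (20.0, 18.0, 28.0)
    myocardium_radii_mm: tuple[float, float, float] = (27.0, 24.0, 35.0)
    epicardial_fat_radii_mm: tuple[float, float, float] = (33.0, 29.0, 41.0)

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ValueError("grid_shape must be three positive integers")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacings must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.rr_interval_ms <= 0:
            raise ValueError("rr_interval_ms must be > 0")
        for t, v in self.tissue_ff.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"tissue_ff[{t!r}]={v} outside [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0.0 <= self.contraction_fraction < 0.5:
            raise ValueError("contraction_fraction must be in [0, 0.5)")
        if self.motion_amplitude_mm < 0:
            raise ValueError("motion_amplitude_mm must be >= 0")
        inner = self.blood_pool_radii_mm
        for outer, name in ((self.myocardium_radii_mm, "myocardium"),
                            (self.epicardial_fat_radii_mm, "epicardial_fat")):
            if any(o <= i for o, i in zip(outer, inner)):
                raise ValueError(f"{name} radii must exceed the enclosed shell")
            inner = outer

    @property
    def frame_times_ms(self) -> np.ndarray:
        """Frame acquisition times, one cardiac cycle starting at the R-wave."""
        dt = self.rr_interval_ms / self.n_frames
        return np.arange(self.n_frames) * dt

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in
                     zip(self.grid_shape, self.voxel_spacing_mm))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_spacing_mm))

    def motion_phase(self, t: int) -> float:
        """sin^2 systolic phase factor for frame ``t`` (0 at the R-wave)."""
        return float(np.sin(np.pi * t / self.n_frames) ** 2)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tissue_ff"] = dict(self.tissue_ff)
        d["tissue_water_signal"] = dict(self.tissue_water_signal)
        d["tissue_fat_signal"] = dict(self.tissue_fat_signal)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PhantomSpec":
        d = dict(d)
        for key in ("grid_shape", "voxel_spacing_mm", "heart_center_mm",
                    "blood_pool_radii_mm", "myocardium_radii_mm",
                    "epicardial_fat_radii_mm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TissueLabelMap:
    """4D (x, y, z, frame) integer tissue labels with voxel spacing."""

    labels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        if self.labels.ndim != 4:
            raise ValueError("labels must be 4D (x, y, z, frame)")

    @property
    def n_frames(self) -> int:
        return self.labels.shape[3]


@dataclass
class DixonSeries:
    """Registered water and fat magnitude volumes over the cine cycle."""

    water: np.ndarray  # (x, y, z, frame), non-negative
    fat: np.ndarray    # same shape
    spacing: tuple[float, float, float]
    frame_times_ms: np.ndarray
    fieldmap_hz: np.ndarray | None = None  # static 3D off-resonance map

    def __post_init__(self):
        if self.water.shape != self.fat.shape:
            raise ValueError("water and fat shapes differ")
        if self.water.ndim != 4:
            raise ValueError("volumes must be 4D (x, y, z, frame)")
        if len(self.frame_times_ms) != self.water.shape[3]:
            raise ValueError("frame_times_ms length does not match frames")

    @property
    def n_frames(self) -> int:
        return self.water.shape[3]


@dataclass
class GroundTruth:
    """What the phantom actually contains, for validating the pipeline."""

    epicardial_fat_mask: np.ndarray          # (x, y, z, frame) bool
    true_volume_ml: np.ndarray               # per frame
    roi: list[EpicardialROISet]              # per frame, outer epicardial border
    slice_range: tuple[int, int]             # apex .. pulmonary-bifurcation analogue


def _voxel_centers(spec: PhantomSpec):
    """Physical (mm) coordinates of voxel centres along each axis."""
    return [ (np.arange(n) + 0.5) * s
             for n, s in zip(spec.grid_shape, spec.voxel_spacing_mm) ]


def _check_fit(spec: PhantomSpec) -> None:
    """Raise if a shell (incl. motion excursion and pericardial rind) leaves
    the grid, naming the first one that does not fit."""
    ext = spec.extent_mm
    c = spec.heart_center_mm
    a = spec.motion_amplitude_mm
    shells = [
        ("blood_pool", spec.blood_pool_radii_mm, 0.0),
        ("myocardium", spec.myocardium_radii_mm, 0.0),
        ("epicardial_fat", spec.epicardial_fat_radii_mm, 0.0),
        # pericardium = one-voxel dilation of the epicardial surface
        ("pericardium", spec.epicardial_fat_radii_mm, 1.0),
    ]
    for name, radii, margin_vox in shells:
        for ax in range(3):
            m = margin_vox * spec.voxel_spacing_mm[ax]
            lo = c[ax] - radii[ax] - m - (a if ax == 2 else 0.0)
            hi = c[ax] + radii[ax] + m
            if lo < 0 or hi > ext[ax]:
                raise ValueError(
                    f"grid too small: shell '{name}' does not fit along axis "
                    f"{ax} (needs [{lo:.1f}, {hi:.1f}] mm of {ext[ax]:.1f} mm)")


def _ellipsoid_mask(coords, center, radii) -> np.ndarray:
    x, y, z = coords
    rx = (x - center[0]) / radii[0]
    ry = (y - center[1]) / radii[1]
    rz = (z - center[2]) / radii[2]
    return (rx[:, None, None] ** 2 + ry[None, :, None] ** 2
            + rz[None, None, :] ** 2) <= 1.0


def build_anatomy(spec: PhantomSpec) -> TissueLabelMap:
    """Rasterize the nested-ellipsoid anatomy for every cine frame.

    Cardiac compartments are shifted apically by
    ``motion_amplitude_mm * sin^2(pi t / n_frames)`` and their in-plane
    radii scaled by ``1 - contraction_fraction * sin^2(...)``; lungs and the
    paracardial slab are identical in all frames (carved clear of the full
    cardiac motion envelope so label sets never collide).
    """
    _check_fit(spec)
    coords = _voxel_centers(spec)
    nx, ny, nz = spec.grid_shape
    labels = np.zeros((nx, ny, nz, spec.n_frames), dtype=np.int8)

    cardiac_any = np.zeros((nx, ny, nz), dtype=bool)
    per_frame = []
    for t in range(spec.n_frames):
        s = spec.motion_phase(t)
        shift = spec.motion_amplitude_mm * s          # toward the apex (-z)
        scale = 1.0 - spec.contraction_fraction * s   # in-plane contraction
        c = (spec.heart_center_mm[0], spec.heart_center_mm[1],
             spec.heart_center_mm[2] - shift)

        def scaled(radii):
            return (radii[0] * scale, radii[1] * scale, radii[2])

        epi = _ellipsoid_mask(coords, c, scaled(spec.epicardial_fat_radii_mm))
        myo = _ellipsoid_mask(coords, c, scaled(spec.myocardium_radii_mm))
        blood = _ellipsoid_mask(coords, c, scaled(spec.blood_pool_radii_mm))
        peri = ndimage.binary_dilation(epi) & ~epi
        per_frame.append((epi, myo, blood, peri))
        cardiac_any |= epi | peri

    # static compartments, clear of anywhere the heart ever reaches
    static_free = ~ndimage.binary_dilation(cardiac_any)
    lung = _static_lungs(spec, coords) & static_free
    para = _paracardial_slab(spec, coords) & static_free

    for t, (epi, myo, blood, peri) in enumerate(per_frame):
        frame = labels[..., t]
        frame[lung] = Tissue.LUNG
        frame[para] = Tissue.PARACARDIAL_FAT
        frame[peri] = Tissue.PERICARDIUM
        frame[epi] = Tissue.EPICARDIAL_FAT
        frame[myo] = Tissue.MYOCARDIUM
        frame[blood] = Tissue.BLOOD_POOL

    return TissueLabelMap(labels=labels, spacing=spec.voxel_spacing_mm)


def _static_lungs(spec: PhantomSpec, coords) -> np.ndarray:
    """Two lateral lung ellipsoids scaled to the grid extent."""
    ex, ey, ez = spec.extent_mm
    cz = spec.heart_center_mm[2] - spec.motion_amplitude_mm / 2.0
    rx = max(0.06 * ex, 1.5 * spec.voxel_spacing_mm[0])
    radii = (rx, 0.30 * ey, 0.38 * ez)
    left = _ellipsoid_mask(coords, (0.09 * ex, ey / 2, cz), radii)
    right = _ellipsoid_mask(coords, (0.91 * ex, ey / 2, cz), radii)
    return left | right


def _paracardial_slab(spec: PhantomSpec, coords) -> np.ndarray:
    """Static fat slab just outside the anterior pericardium."""
    x, y, z = coords
    cx, cy, cz = spec.heart_center_mm
    ry = spec.epicardial_fat_radii_mm[1]
    rz = spec.epicardial_fat_radii_mm[2]
    y_lo, y_hi = cy + ry - 3.0, cy + ry + 8.0
    x_lo = cx - spec.epicardial_fat_radii_mm[0]
    x_hi = cx + spec.epicardial_fat_radii_mm[0]
    z_lo, z_hi = cz - rz - spec.motion_amplitude_mm, cz + rz
    box = ((x[:, None, None] >= x_lo) & (x[:, None, None] <= x_hi)
           & (y[None, :, None] >= y_lo) & (y[None, :, None] <= y_hi)
           & (z[None, None, :] >= z_lo) & (z[None, None, :] <= z_hi))
    return box


def _cardiac_complex(labels_3d: np.ndarray) -> np.ndarray:
    """Everything inside the outer epicardial border (blood, myocardium,
    epicardial fat); this is the region a reader would outline."""
    return np.isin(labels_3d, (Tissue.BLOOD_POOL, Tissue.MYOCARDIUM,
                               Tissue.EPICARDIAL_FAT))


def _ground_truth(labels: TissueLabelMap, spec: PhantomSpec) -> GroundTruth:
    mask = labels.labels == Tissue.EPICARDIAL_FAT
    vv = spec.voxel_volume_mm3
    true_ml = mask.reshape(-1, labels.n_frames).sum(axis=0) * vv / 1000.0

    inside_any = np.zeros(labels.labels.shape[:3], dtype=bool)
    rois: list[EpicardialROISet] = []
    for t in range(labels.n_frames):
        inside = _cardiac_complex(labels.labels[..., t])
        inside_any |= inside
        z_has = np.flatnonzero(inside.any(axis=(0, 1)))
        lo, hi = int(z_has[0]), int(z_has[-1])
        masks = {z: inside[:, :, z].copy() for z in range(lo, hi + 1)}
        rois.append(EpicardialROISet(masks=masks, slice_range=(lo, hi),
                                     frame_index=t))
    z_any = np.flatnonzero(inside_any.any(axis=(0, 1)))
    slice_range = (int(z_any[0]), int(z_any[-1]))
    return GroundTruth(epicardial_fat_mask=mask,
                       true_volume_ml=np.asarray(true_ml),
                       roi=rois, slice_range=slice_range)


def render_dixon(labels: TissueLabelMap,
                 spec: PhantomSpec) -> tuple[DixonSeries, GroundTruth]:
    """Render noiseless water/fat amplitudes from the label map, add seeded
    Gaussian channel noise and clip at zero.

    Returns the image series and the ground truth (epicardial fat masks,
    per-frame true volumes, per-frame outer epicardial ROIs and the axial
    analysis slice range).
    """
    if labels.labels.shape[:3] != tuple(spec.grid_shape):
        raise ValueError("label map shape does not match spec grid_shape")
    if labels.n_frames != spec.n_frames:
        raise ValueError("label map frame count does not match spec")

    n_labels = max(Tissue.NAMES) + 1
    w_lut = np.zeros(n_labels)
    f_lut = np.zeros(n_labels)
    for lab, name in Tissue.NAMES.items():
        w_lut[lab] = spec.tissue_water_signal[name]
        f_lut[lab] = spec.tissue_fat_signal[name]
    water = w_lut[labels.labels]
    fat = f_lut[labels.labels]

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        water = water + rng.normal(0.0, spec.noise_sigma, water.shape)
        fat = fat + rng.normal(0.0, spec.noise_sigma, fat.shape)
    water = np.clip(water, 0.0, None)
    fat = np.clip(fat, 0.0, None)

    fieldmap = None
    if spec.fieldmap_hz is not None:
        fieldmap = _smooth_fieldmap(spec)

    series = DixonSeries(water=water, fat=fat, spacing=spec.voxel_spacing_mm,
                         frame_times_ms=spec.frame_times_ms,
                         fieldmap_hz=fieldmap)
    return series, _ground_truth(labels, spec)


def _smooth_fieldmap(spec: PhantomSpec) -> np.ndarray:
    """Deterministic spatially smooth off-resonance map (Hz), one lobe
    across the field of view with peak amplitude ``fieldmap_hz``."""
    coords = _voxel_centers(spec)
    ext = spec.extent_mm
    gx = np.cos(np.pi * coords[0] / ext[0])
    gy = np.cos(np.pi * coords[1] / ext[1])
    gz = np.cos(np.pi * coords[2] / ext[2])
    return spec.fieldmap_hz * (gx[:, None, None] * gy[None, :, None]
                               * gz[None, None, :])


def synthesize_echoes(series: DixonSeries, spec: PhantomSpec,
                      te1_ms: float = 2.3, te2_ms: float = 3.9,
                      delta_f_hz: float = DEFAULT_WATER_FAT_SHIFT_HZ,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Forward two-point Dixon signal model.

    ``S(TE) = (W + F e^{i theta(TE)}) e^{i 2 pi psi TE / 1000}`` with
    ``theta(TE) = 2 pi delta_f TE / 1000`` (TE in ms, shifts in Hz) and
    ``psi`` the static per-voxel field map (zero when absent).
    """
    if te1_ms <= 0 or te2_ms <= 0:
        raise ValueError("echo times must be positive")
    if te2_ms <= te1_ms:
        raise ValueError("te2_ms must exceed te1_ms")
    psi = series.fieldmap_hz
    psi = np.zeros(series.water.shape[:3]) if psi is None else psi
    psi4 = psi[..., None]
    echoes = []
    for te in (te1_ms, te2_ms):
        theta = 2.0 * np.pi * delta_f_hz * te / 1000.0
        s = (series.water + series.fat * np.exp(1j * theta)) \
            * np.exp(1j * 2.0 * np.pi * psi4 * te / 1000.0)
        echoes.append(s.astype(np.complex128))
    return echoes[0], echoes[1]


# ---------------------------------------------------------------------------
# dataset export / import

def export_dataset(series: DixonSeries, truth: GroundTruth, spec: PhantomSpec,
                   path: str | Path) -> Path:
    """Write the phantom dataset to ``path``: 4D NIfTI volumes (water, fat,
    epicardial-fat mask, ROI mask) plus a JSON sidecar with frame times,
    spacing, the generating spec and the ground-truth volumes."""
    from . import io as eio

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    sp = series.spacing
    eio.write_volume(series.water, sp, path / "water.nii")
    eio.write_volume(series.fat, sp, path / "fat.nii")
    eio.write_volume(truth.epicardial_fat_mask.astype(np.uint8), sp,
                     path / "epicardial_fat_mask.nii")

    roi_vol = np.zeros(series.water.shape, dtype=np.uint8)
    for t, roi in enumerate(truth.roi):
        for z, m in roi.masks.items():
            roi_vol[:, :, z, t] = m
    eio.write_volume(roi_vol, sp, path / "roi.nii")

    sidecar = {
        "frame_times_ms": [float(t) for t in series.frame_times_ms],
        "voxel_spacing_mm": list(sp),
        "seed": spec.seed,
        "spec": spec.to_dict(),
        "true_volume_ml": [float(v) for v in truth.true_volume_ml],
        "slice_range": list(truth.slice_range),
        "roi_slice_ranges": [list(r.slice_range) for r in truth.roi],
        "roi_frame_indices": [r.frame_index for r in truth.roi],
    }
    with open(path / "sidecar.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    logger.info("exported phantom dataset to %s", path)
    return path


def import_dataset(path: str | Path) -> tuple[DixonSeries, GroundTruth,
                                              PhantomSpec]:
    """Read a dataset written by :func:`export_dataset` (lossless)."""
    from . import io as eio

    path = Path(path)
    with open(path / "sidecar.json") as fh:
        sidecar = json.load(fh)
    spec = PhantomSpec.from_dict(sidecar["spec"])
    water, sp = eio.read_volume(path / "water.nii")
    fat, _ = eio.read_volume(path / "fat.nii")
    mask, _ = eio.read_volume(path / "epicardial_fat_mask.nii")
    roi_vol, _ = eio.read_volume(path / "roi.nii")

    rois = []
    for t, (rng, fi) in enumerate(zip(sidecar["roi_slice_ranges"],
                                      sidecar["roi_frame_indices"])):
        lo, hi = int(rng[0]), int(rng[1])
        masks = {z: roi_vol[:, :, z, t].astype(bool) for z in range(lo, hi + 1)}
        rois.append(EpicardialROISet(masks=masks, slice_range=(lo, hi),
                                     frame_index=fi))
    truth = GroundTruth(
        epicardial_fat_mask=mask.astype(bool),
        true_volume_ml=np.asarray(sidecar["true_volume_ml"]),
        roi=rois,
        slice_range=tuple(sidecar["slice_range"]),
    )
    series = DixonSeries(water=water, fat=fat, spacing=sp,
                         frame_times_ms=np.asarray(sidecar["frame_times_ms"]))
    return series, truth, spec
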