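"""CT geometry and intensity preprocessing.

Raw HU volume + GTVp mask -> model-ready instances: couch removal by
thresholding and connected components, 1 mm isotropic resampling, soft-tissue
windowing (level 50 HU / width 120 HU), 224x224 in-plane crops around the GTVp
center of mass per view, and Gaussian-sampled 50^3 subvolumes for the 3D route.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

PATCH_SIZE = 224
SUBVOLUME_SIZE = 50
VIEWS = ("axial", "coronal", "sagittal")
#: axis index sliced over for each view; axial = last axis
VIEW_AXIS = {"sagittal": 0, "coronal": 1, "axial": 2}

AIR_FILL_HU = -1024.0
BODY_THRESHOLD_HU = -500.0


@dataclass(frozen=True)
class WindowSpec:
    """Soft-tissue HU window: clip to level +/- width/2, scale to [0, 1]."""

    level: float = 50.0
    width: float = 120.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("window width must be > 0")


@dataclass(frozen=True)
class Patch2D:
    pixels: np.ndarray
    view: str
    slice_index: int
    patient_id: str

    def __post_init__(self) -> None:
        if self.pixels.shape != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError(f"patch must be {PATCH_SIZE}x{PATCH_SIZE}")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("patch values must lie in [0, 1]")


@dataclass(frozen=True)
class SubVolume3D:
    voxels: np.ndarray
    center_voxel: tuple[int, int, int]
    patient_id: str

    def __post_init__(self) -> None:
        if self.voxels.shape != (SUBVOLUME_SIZE,) * 3:
            raise ValueError(f"subvolume must be {SUBVOLUME_SIZE}^3")


def mask_body(ct: np.ndarray, threshold: float = BODY_THRESHOLD_HU) -> np.ndarray:
    """Largest connected above-air component with holes filled.

    Stands in for an anatomical body segmentation: anything outside (couch,
    air) is meant to be replaced with air HU before downstream steps.
    """
    above = ct > threshold
    if not above.any():
        raise ValueError("no voxels above the air threshold; empty body mask")
    labels, n = ndimage.label(above)
    if n == 0:
        raise ValueError("no connected components found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    body = labels == largest
    return ndimage.binary_fill_holes(body)


def apply_body_mask(
    ct: np.ndarray, body: np.ndarray, fill_hu: float = AIR_FILL_HU
) -> np.ndarray:
    out = ct.astype(np.float32, copy=True)
    out[~body] = fill_hu
    return out


def resample_isotropic(
    ct: np.ndarray,
    mask: np.ndarray,
    spacing: Sequence[float],
    target_spacing: float | Sequence[float] = 1.0,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float, float]]:
    """Resample CT (linear) and mask (nearest) to the target voxel spacing."""
    spacing = np.asarray(spacing, dtype=float)
    target = np.asarray(
        [target_spacing] * 3 if np.isscalar(target_spacing) else target_spacing,
        dtype=float,
    )
    if (spacing <= 0).any() or (target <= 0).any():
        raise ValueError("voxel spacings must be positive")
    factors = spacing / target
    if np.allclose(factors, 1.0):
        return ct.copy(), mask.copy(), tuple(target)
    ct2 = ndimage.zoom(ct.astype(np.float32), factors, order=1, mode="nearest")
    mask2 = ndimage.zoom(mask.astype(np.uint8), factors, order=0, mode="nearest")
    return ct2, mask2, tuple(target)


def window_hu(ct: np.ndarray, window: WindowSpec = WindowSpec()) -> np.ndarray:
    lo = window.level - window.width / 2.0
    return ((np.clip(ct, lo, lo + window.width) - lo) / window.width).astype(np.float32)


def normalize_3d(ct: np.ndarray, lo: float = -1024.0, hi: float = 2048.0) -> np.ndarray:
    """Clip HU to [-1024, 2048] and scale affinely to [0, 1]."""
    return ((np.clip(ct, lo, hi) - lo) / (hi - lo)).astype(np.float32)


def mask_center_of_mass(mask: np.ndarray) -> np.ndarray:
    """Voxel-index center of mass, rounded half-up to integer indices."""
    if not mask.any():
        raise ValueError("empty mask has no center of mass")
    com = np.asarray(ndimage.center_of_mass(mask))
    return np.floor(com + 0.5).astype(int)


def _crop_2d(plane: np.ndarray, center: Sequence[int], size: int) -> np.ndarray:
    out = np.zeros((size, size), dtype=plane.dtype)
    half = size // 2
    r0, c0 = int(center[0]) - half, int(center[1]) - half
    rs, cs = max(r0, 0), max(c0, 0)
    re = min(r0 + size, plane.shape[0])
    ce = min(c0 + size, plane.shape[1])
    if rs < re and cs < ce:
        out[rs - r0 : re - r0, cs - c0 : ce - c0] = plane[rs:re, cs:ce]
    return out


def extract_view_slices(
    ct01: np.ndarray,
    gtvp_mask: np.ndarray,
    views: Sequence[str] = ("axial",),
    patient_id: str = "",
    size: int = PATCH_SIZE,
) -> list[Patch2D]:
    """One 224x224 crop per mask-positive slice index, per requested view.

    Crops are centered at the in-plane projection of the 3D GTVp center of
    mass and zero-padded at volume borders.
    """
    if not gtvp_mask.any():
        raise ValueError("empty GTVp mask")
    for v in views:
        if v not in VIEW_AXIS:
            raise ValueError(f"unknown view {v!r}")
    com = mask_center_of_mass(gtvp_mask)
    patches = []
    for view in views:
        axis = VIEW_AXIS[view]
        in_plane = tuple(i for i in range(3) if i != axis)
        idxs = np.unique(np.nonzero(gtvp_mask)[axis])
        center = com[list(in_plane)]
        for k in idxs:
            plane = np.take(ct01, int(k), axis=axis)
            patches.append(
                Patch2D(
                    pixels=_crop_2d(plane, center, size),
                    view=view,
                    slice_index=int(k),
                    patient_id=patient_id,
                )
            )
    return patches


def sample_centers(
    mask: np.ndarray,
    n: int,
    variance: float,
    size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian subvolume centers around the GTVp center of mass.

    Centers are drawn from N(com, variance * I), rounded to voxel indices and
    clamped so the size^3 box lies inside the volume (exactly n are returned).
    """
    if any(d < size for d in mask.shape):
        raise ValueError(f"volume {mask.shape} smaller than {size}^3 subvolume")
    if not mask.any():
        raise ValueError("empty GTVp mask")
    com = np.asarray(ndimage.center_of_mass(mask))
    centers = rng.normal(loc=com, scale=np.sqrt(variance), size=(n, 3))
    centers = np.floor(centers + 0.5).astype(int)
    half = size // 2
    for ax in range(3):
        centers[:, ax] = np.clip(centers[:, ax], half, mask.shape[ax] - (size - half))
    return centers


def sample_subvolumes(
    ct_norm3d: np.ndarray,
    gtvp_mask: np.ndarray,
    rng: np.random.Generator,
    n: int = 100,
    variance: float = 16.0,
    size: int = SUBVOLUME_SIZE,
    patient_id: str = "",
) -> list[SubVolume3D]:
    centers = sample_centers(gtvp_mask, n, variance, size, rng)
    half = size // 2
    subs = []
    for c in centers:
        sl = tuple(slice(int(ci) - half, int(ci) - half + size) for ci in c)
        subs.append(
            SubVolume3D(
                voxels=ct_norm3d[sl].copy(),
                center_voxel=tuple(int(x) for x in c),
                patient_id=patient_id,
            )
        )
    return subs


def preprocess_for_2d(
    ct: np.ndarray,
    mask: np.ndarray,
    spacing: Sequence[float],
    views: Sequence[str] = ("axial",),
    window: WindowSpec = WindowSpec(),
    patient_id: str = "",
) -> list[Patch2D]:
    """Full 2D chain: bed removal, 1 mm resampling, windowing, per-view crops."""
    body = mask_body(ct)
    ct = apply_body_mask(ct, body)
    ct, mask, _ = resample_isotropic(ct, mask, spacing)
    return extract_view_slices(window_hu(ct, window), mask, views, patient_id)


def preprocess_for_3d(
    ct: np.ndarray,
    mask: np.ndarray,
    spacing: Sequence[float],
    rng: np.random.Generator,
    n: int = 100,
    variance: float = 16.0,
    patient_id: str = "",
) -> list[SubVolume3D]:
    """Full 3D chain: bed removal, 1 mm resampling, [-1024, 2048] scaling, sampling."""
    body = mask_body(ct)
    ct = apply_body_mask(ct, body)
    ct, mask, _ = resample_isotropic(ct, mask, spacing)
    return sample_subvolumes(normalize_3d(ct), mask, rng, n=n, variance=variance,
                             patient_id=patient_id)
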