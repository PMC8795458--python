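"""Volume I/O, preprocessing and light augmentation.

Volumes live in memory as :class:`VolumeSample`: a 3D float array ordered
(slice, row, col) with its voxel spacing in millimetres.  Preprocessing
follows the standard single-contrast MRI recipe: clip intensities to the
[0.5, 99.5] percentile range and rescale to [0, 1], then resample onto a
2 mm isotropic grid with trilinear interpolation.  Training-time ("light")
augmentation is a random isotropic scale in [0.9, 1.2] combined with random
rotations of up to 10 degrees per axis, plus a left-right flip with
probability 0.25.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from numba import njit
from scipy import ndimage

__all__ = [
    "AugmentationPolicy",
    "VolumeSample",
    "apply_affine",
    "augment",
    "percentile_clip_scale",
    "random_affine",
    "random_flip_lr",
    "read_volume",
    "resample_isotropic",
    "write_volume",
]


@dataclass
class VolumeSample:
    """A single-channel 3D volume with spacing, id and optional class label."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    subject_id: str = ""
    label: str | None = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D (slice, row, col), got {self.voxels.ndim} axes")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must all be finite")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be three positive values, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class AugmentationPolicy:
    scale_range: tuple[float, float] = (0.9, 1.2)
    rotation_max_degrees: float = 10.0
    flip_probability: float = 0.25
    enabled: bool = True
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.scale_range
        if lo > hi or lo <= 0:
            raise ValueError(f"invalid scale_range {self.scale_range}")
        if not 0.0 <= self.flip_probability <= 1.0:
            raise ValueError("flip_probability must be in [0, 1]")
        if self.rotation_max_degrees < 0:
            raise ValueError("rotation_max_degrees must be >= 0")


# ---------------------------------------------------------------------------
# I/O


def read_volume(path) -> VolumeSample:
    """Read a 3D NIfTI volume into the canonical (slice, row, col) order."""
    path = Path(path)
    try:
        img = nib.load(path)
    except Exception as e:  # nibabel raises several I/O error types
        raise IOError(f"could not read NIfTI file {path}: {e}") from e
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim} dimensions")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    sid = path.name
    for suffix in (".gz", ".nii"):
        if sid.endswith(suffix):
            sid = sid[: -len(suffix)]
    return VolumeSample(voxels=data.astype(np.float32), spacing_mm=spacing, subject_id=sid)


def write_volume(sample: VolumeSample, path) -> Path:
    path = Path(path)
    affine = np.diag(list(sample.spacing_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(sample.voxels, dtype=np.float32), affine)
    img.header.set_zooms(sample.spacing_mm)
    try:
        nib.save(img, path)
    except Exception as e:
        raise IOError(f"could not write NIfTI file {path}: {e}") from e
    return path


# ---------------------------------------------------------------------------
# Preprocessing


def percentile_clip_scale(v: VolumeSample, lo_pct: float = 0.5, hi_pct: float = 99.5) -> VolumeSample:
    """Clip intensities to the [lo_pct, hi_pct] percentiles and rescale to [0, 1].

    Percentiles are computed over all voxels of the volume (background
    included).  The map is monotone and invariant to positive affine
    transforms of the input intensities.
    """
    x = np.asarray(v.voxels, dtype=np.float64)
    p_lo, p_hi = np.percentile(x, [lo_pct, hi_pct])
    if p_hi <= p_lo:
        raise ValueError(
            f"degenerate intensity distribution (P{lo_pct}={p_lo} >= P{hi_pct}={p_hi}); "
            "volume is (near-)constant"
        )
    scaled = (np.clip(x, p_lo, p_hi) - p_lo) / (p_hi - p_lo)
    return replace(v, voxels=scaled.astype(v.voxels.dtype if v.voxels.dtype.kind == "f" else np.float32))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def resample_isotropic(v: VolumeSample, target_mm: float = 2.0) -> VolumeSample:
    """Trilinearly resample onto an isotropic grid of ``target_mm`` spacing.

    The output extent per axis is ``round_half_up(dim * spacing / target)``.
    A volume already at the target spacing is returned unchanged (identity).
    """
    if target_mm <= 0:
        raise ValueError("target spacing must be positive")
    spacing = np.asarray(v.spacing_mm, dtype=np.float64)
    if np.allclose(spacing, target_mm):
        return replace(v, voxels=v.voxels.copy(), spacing_mm=(target_mm,) * 3)
    out_shape = tuple(
        _round_half_up(dim * s / target_mm) for dim, s in zip(v.shape, spacing)
    )
    if any(d < 1 for d in out_shape):
        raise ValueError(
            f"resampling {v.shape} at {v.spacing_mm} mm to {target_mm} mm would "
            f"produce an empty grid {out_shape}"
        )
    # Output index i maps to input index i * target / spacing along each axis.
    matrix = np.diag(target_mm / spacing)
    voxels = ndimage.affine_transform(
        np.asarray(v.voxels, dtype=np.float32), matrix, offset=0.0,
        output_shape=out_shape, order=1, mode="nearest",
    )
    return replace(v, voxels=voxels, spacing_mm=(target_mm,) * 3)


def preprocess(v: VolumeSample, lo_pct: float = 0.5, hi_pct: float = 99.5,
               target_mm: float = 2.0) -> VolumeSample:
    """Intensity normalization followed by isotropic resampling."""
    return resample_isotropic(percentile_clip_scale(v, lo_pct, hi_pct), target_mm)


# ---------------------------------------------------------------------------
# Light augmentation


def random_flip_lr(v: VolumeSample, p: float, rng: np.random.Generator) -> VolumeSample:
    """Reverse the left-right (last, column) axis with probability ``p``."""
    if rng.random() < p:
        return replace(v, voxels=v.voxels[:, :, ::-1].copy())
    return replace(v, voxels=v.voxels.copy())


def _rotation_matrix(angles_deg: np.ndarray) -> np.ndarray:
    a, b, c = np.deg2rad(angles_deg)
    ca, sa = math.cos(a), math.sin(a)
    cb, sb = math.cos(b), math.sin(b)
    cc, sc = math.cos(c), math.sin(c)
    rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rz = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
    return rz @ ry @ rx


@njit(cache=True, fastmath=True)
def _trilinear_warp(vol, inv, offset):
    """Output voxel (z,y,x) samples the input at inv @ (z,y,x) + offset,
    trilinear, zero outside the field of view."""
    d, h, w = vol.shape
    out = np.empty_like(vol)
    for z in range(d):
        for y in range(h):
            for x in range(w):
                sz = inv[0, 0] * z + inv[0, 1] * y + inv[0, 2] * x + offset[0]
                sy = inv[1, 0] * z + inv[1, 1] * y + inv[1, 2] * x + offset[1]
                sx = inv[2, 0] * z + inv[2, 1] * y + inv[2, 2] * x + offset[2]
                z0 = int(np.floor(sz))
                y0 = int(np.floor(sy))
                x0 = int(np.floor(sx))
                fz = sz - z0
                fy = sy - y0
                fx = sx - x0
                val = 0.0
                for dz in range(2):
                    zz = z0 + dz
                    if zz < 0 or zz >= d:
                        continue
                    wz = fz if dz else 1.0 - fz
                    for dy in range(2):
                        yy = y0 + dy
                        if yy < 0 or yy >= h:
                            continue
                        wy = fy if dy else 1.0 - fy
                        for dx in range(2):
                            xx = x0 + dx
                            if xx < 0 or xx >= w:
                                continue
                            wx = fx if dx else 1.0 - fx
                            val += wz * wy * wx * vol[zz, yy, xx]
                out[z, y, x] = val
    return out


def apply_affine(v: VolumeSample, scale: float, angles_deg) -> VolumeSample:
    """Zoom by ``scale`` and rotate by ``angles_deg`` about the volume centre,
    resampling back onto the original grid (trilinear, zero fill)."""
    angles = np.asarray(angles_deg, dtype=np.float64)
    if scale == 1.0 and not angles.any():
        return replace(v, voxels=v.voxels.copy())
    rot = _rotation_matrix(angles)
    # the warp maps output coords to input coords: invert scale*R.
    inv = rot.T / scale
    center = (np.asarray(v.shape) - 1) / 2.0
    offset = center - inv @ center
    voxels = _trilinear_warp(np.ascontiguousarray(v.voxels, dtype=np.float32),
                             inv, offset)
    return replace(v, voxels=voxels)


def random_affine(v: VolumeSample, policy: AugmentationPolicy,
                  rng: np.random.Generator) -> VolumeSample:
    lo, hi = policy.scale_range
    scale = rng.uniform(lo, hi)
    angles = rng.uniform(-policy.rotation_max_degrees, policy.rotation_max_degrees, size=3)
    return apply_affine(v, scale, angles)


def augment(v: VolumeSample, policy: AugmentationPolicy,
            rng: np.random.Generator) -> VolumeSample:
    """Apply the light-augmentation pipeline; identity when disabled."""
    if not policy.enabled:
        return v
    out = random_affine(v, policy, rng)
    return random_flip_lr(out, policy.flip_probability, rng)
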