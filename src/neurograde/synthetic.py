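"""Labelled phantom brain volumes with class-dependent lesion structure.

The phantoms emulate skull-stripped, contrast-enhanced T1 appearance at the
level of detail the classifier needs: an ellipsoidal "brain" of roughly
uniform tissue intensity on an exactly-zero background, plus

* ``HEALTHY`` -- brain tissue and noise only,
* ``LGG``     -- one homogeneous hyperintense ball (enhancing low-grade lesion),
* ``HGG``     -- one ball with a hyperintense rim around a hypointense core,
                 mimicking the enhancing rim / necrotic core of a high-grade
                 glioma.

Scanner noise is modelled as a Gaussian random field smoothed with a one-voxel
kernel: magnitude MR images interpolated onto a grid have spatially correlated
noise, and the smoothing keeps single-voxel extremes bounded so that the three
classes are separable from simple intensity features by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .labels import CLASSES, validate_label
from .volumes import VolumeSample, write_volume

__all__ = [
    "DatasetManifest",
    "SyntheticSpec",
    "generate_samples",
    "load_manifest",
    "make_dataset",
    "make_volume",
]

#: necrotic-core radius as a fraction of the outer lesion radius (HGG only);
#: leaves a rim at least two voxels thick at the default radius range.
HGG_CORE_FRACTION = 0.5


def _default_counts() -> dict[str, int]:
    return {"LGG": 60, "HGG": 60, "HEALTHY": 60}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the phantom generator.

    Intensities are in arbitrary units with brain tissue at ``brain_mean``;
    lesion contrasts are additive.  ``hgg_core_contrast`` is negative (the
    core is darker than brain tissue).  Identical spec + seed reproduce
    bit-identical volumes and manifests.
    """

    volume_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_per_class: dict[str, int] = field(default_factory=_default_counts)
    brain_axes_frac: tuple[float, float, float] = (0.85, 0.85, 0.85)
    brain_mean: float = 0.5
    brain_sd: float = 0.02
    lgg_radius_range: tuple[float, float] = (5.0, 9.0)
    hgg_radius_range: tuple[float, float] = (5.0, 9.0)
    lgg_contrast: float = 0.30
    hgg_rim_contrast: float = 0.35
    hgg_core_contrast: float = -0.25
    noise_sd: float = 0.05
    noise_smoothing_vox: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if len(self.volume_shape) != 3 or any(int(d) < 8 for d in self.volume_shape):
            raise ValueError(f"volume_shape must be 3 axes of >= 8 voxels, got {self.volume_shape}")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")
        for label, n in self.n_per_class.items():
            validate_label(label)
            if n < 0:
                raise ValueError(f"negative count for class {label}: {n}")
        if not all(0 < f <= 1 for f in self.brain_axes_frac):
            raise ValueError("brain_axes_frac entries must be in (0, 1]")
        if self.noise_sd < 0 or self.brain_sd < 0:
            raise ValueError("noise_sd and brain_sd must be >= 0")
        for name, (lo, hi) in (("lgg", self.lgg_radius_range), ("hgg", self.hgg_radius_range)):
            if not 0 < lo <= hi:
                raise ValueError(f"{name}_radius_range must satisfy 0 < lo <= hi")
            if hi + 1 >= min(self._semi_axes()):
                raise ValueError(
                    f"{name}_radius_range upper bound {hi} does not fit inside the brain "
                    f"ellipsoid (semi-axes {self._semi_axes()})"
                )

    def _semi_axes(self) -> tuple[float, float, float]:
        return tuple(f * d / 2.0 for f, d in zip(self.brain_axes_frac, self.volume_shape))

    @property
    def total_samples(self) -> int:
        return sum(self.n_per_class.values())


def _brain_mask(spec: SyntheticSpec) -> np.ndarray:
    shape = spec.volume_shape
    center = (np.asarray(shape) - 1) / 2.0
    axes = np.asarray(spec._semi_axes())
    grids = np.ogrid[tuple(slice(0, d) for d in shape)]
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes))
    return q <= 1.0


def _sample_lesion_center(spec: SyntheticSpec, radius: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Uniform point inside the brain ellipsoid eroded by the lesion radius."""
    center = (np.asarray(spec.volume_shape) - 1) / 2.0
    axes = np.asarray(spec._semi_axes()) - radius - 1.0
    if np.any(axes <= 0):
        raise ValueError(
            f"lesion radius {radius} infeasible for brain semi-axes {spec._semi_axes()}"
        )
    while True:
        p = rng.uniform(-1.0, 1.0, size=3)
        if (p ** 2).sum() <= 1.0:
            return center + p * axes


def _ball_mask(shape, center: np.ndarray, radius: float) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, d) for d in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius ** 2


def make_volume(label: str, spec: SyntheticSpec, rng: np.random.Generator,
                subject_id: str = "", with_masks: bool = False):
    """Generate one phantom volume of the given class.

    Returns a :class:`VolumeSample`; with ``with_masks=True`` also returns a
    dict of boolean masks (``brain``, ``lesion``, ``core``) for oracle checks.
    """
    validate_label(label)
    shape = spec.volume_shape
    brain = _brain_mask(spec)
    vol = spec.brain_mean + spec.brain_sd * rng.standard_normal(shape)
    if spec.noise_sd > 0:
        noise = rng.standard_normal(shape)
        if spec.noise_smoothing_vox > 0:
            noise = ndimage.gaussian_filter(noise, spec.noise_smoothing_vox)
        vol += spec.noise_sd * noise
    lesion = np.zeros(shape, dtype=bool)
    core = np.zeros(shape, dtype=bool)
    if label == "LGG":
        lo, hi = spec.lgg_radius_range
        r = rng.uniform(lo, hi)
        lesion = _ball_mask(shape, _sample_lesion_center(spec, r, rng), r)
        vol[lesion] += spec.lgg_contrast
    elif label == "HGG":
        lo, hi = spec.hgg_radius_range
        r = rng.uniform(lo, hi)
        lesion = _ball_mask(shape, (c := _sample_lesion_center(spec, r, rng)), r)
        core = _ball_mask(shape, c, HGG_CORE_FRACTION * r)
        vol[lesion & ~core] += spec.hgg_rim_contrast
        vol[core] += spec.hgg_core_contrast
    vol = np.where(brain, vol, 0.0).astype(np.float32)
    sample = VolumeSample(voxels=vol, spacing_mm=spec.voxel_spacing_mm,
                          subject_id=subject_id, label=label)
    if with_masks:
        return sample, {"brain": brain, "lesion": lesion, "core": core}
    return sample


def generate_samples(spec: SyntheticSpec) -> list[VolumeSample]:
    """All samples of the spec, deterministically seeded per sample."""
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.total_samples)
    samples = []
    i = 0
    for label in CLASSES:
        for k in range(spec.n_per_class.get(label, 0)):
            rng = np.random.default_rng(seeds[i])
            samples.append(make_volume(label, spec, rng,
                                       subject_id=f"{label.lower()}_{k:03d}"))
            i += 1
    return samples


@dataclass(frozen=True)
class DatasetManifest:
    root: Path
    frame: pd.DataFrame  # columns: subject_id, path, label

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def path(self) -> Path:
        return self.root / "manifest.csv"


def make_dataset(spec: SyntheticSpec, out_dir) -> DatasetManifest:
    """Write one NIfTI per sample plus a ``manifest.csv`` into ``out_dir``."""
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for sample in generate_samples(spec):
        rel = f"{sample.subject_id}.nii.gz"
        write_volume(sample, root / rel)
        rows.append({"subject_id": sample.subject_id, "path": rel, "label": sample.label})
    frame = pd.DataFrame(rows, columns=["subject_id", "path", "label"])
    frame.to_csv(root / "manifest.csv", index=False)
    return DatasetManifest(root=root, frame=frame)


def load_manifest(path) -> DatasetManifest:
    path = Path(path)
    root = path.parent
    frame = pd.read_csv(path)
    expected = ["subject_id", "path", "label"]
    if list(frame.columns) != expected:
        raise ValueError(f"manifest {path} must have columns {expected}, got {list(frame.columns)}")
    for label in frame["label"]:
        validate_label(label)
    return DatasetManifest(root=root, frame=frame)
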