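"""Template-space scalar images, SUVR normalization, and regional measures.

Images are assumed to already live in a common template space (e.g. MNI at
2 mm). No resampling is ever performed: an image, atlas and mask that do not
share shape and affine are a hard error, because silent resampling would
corrupt the 2-mm cube geometry the node model depends on.

SUVR (standardized uptake value ratio) divides every voxel by the mean
uptake inside a reference region (cerebellar crus in the tau-PET setting).
The regional comparator measures are the entorhinal SUVR (mean over the
entorhinal labels) and the tau composite SUVR, the median over the *pooled*
voxels of six temporal-lobe regions — pooled, not a median of per-region
medians. Positivity calls are strict inequalities against configurable
thresholds (defaults: tau composite > 1.23, amyloid > 1.17).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelImage",
    "LabelImage",
    "RegionalMeasures",
    "RegionalConfig",
    "load_image",
    "save_image",
    "load_labels",
    "compute_suvr",
    "region_statistic",
    "regional_measures",
]

_AFFINE_ATOL = 1e-4  # mm; NIfTI affines written by common tools agree far tighter


@dataclass
class VoxelImage:
    """A 3-D scalar volume with its voxel-to-world affine.

    Parameters
    ----------
    values : ndarray of shape (X, Y, Z)
        Scalar voxel values (raw uptake or SUVR; unitless).
    affine : ndarray of shape (4, 4)
        Voxel-index to world-coordinate (mm) transform.
    is_suvr : bool
        Whether the values have been reference-normalized.
    """

    values: np.ndarray
    affine: np.ndarray
    is_suvr: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(
                f"expected a 3-D volume, got {self.values.ndim}-D array"
            )
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if np.any(self.grid_spacing <= 0):
            raise ValueError("grid spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def grid_spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm, derived from the affine."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class LabelImage:
    """An integer parcellation: 0 is background, positive values are regions."""

    labels: np.ndarray
    affine: np.ndarray
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.allclose(self.labels, rounded, atol=1e-6):
                raise ValueError("label image contains non-integer values")
            self.labels = rounded.astype(np.int32)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.labels.ndim != 3:
            raise ValueError("label image must be 3-D")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def region_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i > 0]

    def mask(self, region_ids: Iterable[int]) -> np.ndarray:
        """Boolean mask of voxels belonging to any of the given regions."""
        return np.isin(self.labels, np.asarray(list(region_ids), dtype=self.labels.dtype))


@dataclass
class RegionalMeasures:
    """The conventional (non-network) tau comparator measures for a subject."""

    entorhinal_suvr: float
    composite_suvr: float
    tau_positive: bool
    amyloid_suvr: float | None = None
    amyloid_positive: bool | None = None


@dataclass
class RegionalConfig:
    """Region-id sets and positivity thresholds for regional measures.

    The atlas label ids for the entorhinal, composite and reference regions
    vary between parcellations, so they are configuration, not constants.
    """

    entorhinal_ids: tuple[int, ...]
    composite_ids: tuple[int, ...]
    reference_ids: tuple[int, ...] = ()
    tau_threshold: float = 1.23
    amyloid_threshold: float = 1.17


def _check_geometry(a, b, what: str) -> None:
    if a.shape != b.shape:
        raise ValueError(f"{what}: shape mismatch {a.shape} vs {b.shape}; resampling is not performed")
    if not np.allclose(a.affine, b.affine, atol=_AFFINE_ATOL):
        raise ValueError(f"{what}: affine mismatch; resampling is not performed")


def load_image(path: str | Path) -> VoxelImage:
    """Read a 3-D NIfTI-1 scalar volume. No resampling, no dtype coercion."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several error types
        raise ValueError(f"cannot read NIfTI image at {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got {data.ndim}-D")
    return VoxelImage(values=data, affine=img.affine)


def save_image(image: VoxelImage, path: str | Path) -> Path:
    """Write a VoxelImage as NIfTI-1, preserving the array dtype."""
    path = Path(path)
    nifti = nib.Nifti1Image(np.asarray(image.values), image.affine)
    nib.save(nifti, str(path))
    return path


def load_labels(path: str | Path, names: Mapping[int, str] | None = None) -> LabelImage:
    """Read an integer atlas parcellation from NIfTI-1."""
    vol = load_image(path)
    return LabelImage(labels=vol.values, affine=vol.affine, names=dict(names or {}))


def compute_suvr(image: VoxelImage, reference_mask) -> VoxelImage:
    """Divide every voxel by the mean uptake inside the reference region.

    ``reference_mask`` may be a boolean/binary array, a ``VoxelImage`` whose
    nonzero voxels define the reference, or a ``LabelImage`` whose positive
    labels define it.
    """
    if isinstance(reference_mask, LabelImage):
        _check_geometry(image, reference_mask, "image vs reference labels")
        mask = reference_mask.labels > 0
    elif isinstance(reference_mask, VoxelImage):
        _check_geometry(image, reference_mask, "image vs reference mask")
        mask = reference_mask.values > 0
    else:
        mask = np.asarray(reference_mask) > 0
        if mask.shape != image.shape:
            raise ValueError(
                f"reference mask shape {mask.shape} does not match image {image.shape}"
            )
    if not mask.any():
        raise ValueError("reference mask is empty")
    ref_mean = float(np.mean(image.values[mask]))
    if not np.isfinite(ref_mean) or ref_mean <= 0:
        raise ValueError(f"nonpositive or non-finite reference mean ({ref_mean})")
    return VoxelImage(values=image.values / ref_mean, affine=image.affine, is_suvr=True)


def region_statistic(
    image: VoxelImage,
    labels: LabelImage,
    region_ids: Iterable[int],
    statistic: str = "mean",
) -> float:
    """Mean or median over the pooled voxels of the listed regions.

    Voxels of all regions are pooled first and the statistic taken once over
    the pool; this matters for the median, which differs from a median of
    per-region medians when regions have unequal sizes.
    """
    _check_geometry(image, labels, "image vs labels")
    ids = list(region_ids)
    pooled = image.values[labels.mask(ids)]
    if pooled.size == 0:
        present = set(labels.region_ids)
        missing = sorted(set(ids) - present)
        raise ValueError(f"no voxels found for regions {ids} (missing ids: {missing})")
    if statistic == "mean":
        return float(np.mean(pooled))
    if statistic == "median":
        return float(np.median(pooled))
    raise ValueError(f"unknown statistic {statistic!r}; use 'mean' or 'median'")


def regional_measures(
    suvr: VoxelImage,
    labels: LabelImage,
    config: RegionalConfig,
    amyloid_suvr: float | None = None,
) -> RegionalMeasures:
    """Entorhinal SUVR, pooled-median composite SUVR, and positivity flags.

    Positivity is a strict inequality against the configured thresholds:
    a composite exactly at the threshold is negative.
    """
    present = set(labels.region_ids)
    required = set(config.entorhinal_ids) | set(config.composite_ids)
    missing = sorted(required - present)
    if missing:
        raise ValueError(f"atlas is missing required region ids: {missing}")
    ento = region_statistic(suvr, labels, config.entorhinal_ids, "mean")
    composite = region_statistic(suvr, labels, config.composite_ids, "median")
    amyloid_positive = None
    if amyloid_suvr is not None:
        amyloid_positive = bool(amyloid_suvr > config.amyloid_threshold)
    return RegionalMeasures(
        entorhinal_suvr=ento,
        composite_suvr=composite,
        tau_positive=bool(composite > config.tau_threshold),
        amyloid_suvr=amyloid_suvr,
        amyloid_positive=amyloid_positive,
    )
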