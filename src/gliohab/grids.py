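"""Volumes, masks and grid bookkeeping.

All spatial data live on a single shared voxel grid: volumes are never
resampled here, only checked for compatibility. World coordinates (the
affine) are carried along for I/O and reporting but all indexing is 0-based
voxel space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "VolumeGrid",
    "MaskVolume",
    "GridMismatchError",
    "read_volume",
    "write_volume",
    "check_same_grid",
    "binarize_probabilistic_mask",
    "mirror_contralateral_mask",
]


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


@dataclass
class VolumeGrid:
    """A 3-D (or 4-D, for BOLD) scalar image on a voxel grid.

    Parameters
    ----------
    data
        Array of voxel values; no NaN allowed after construction.
    affine
        4x4 voxel-to-world transform.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {self.affine.shape}")
        if not np.all(np.isfinite(self.affine)):
            raise ValueError("affine contains non-finite entries")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm per spatial axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))


@dataclass
class MaskVolume:
    """A strictly binary mask on the shared grid."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def indices(self) -> np.ndarray:
        """(n, 3) array of voxel indices of the true voxels, in C order."""
        return np.argwhere(self.data)


def check_same_grid(*volumes: VolumeGrid | MaskVolume) -> None:
    """Reject any pair of volumes with different spatial shape or affine."""
    if not volumes:
        return
    ref = volumes[0]
    ref_shape = ref.shape[:3]
    for v in volumes[1:]:
        if v.shape[:3] != ref_shape:
            raise GridMismatchError(
                f"spatial shapes differ: {v.shape[:3]} vs {ref_shape}"
            )
        if not np.allclose(v.affine, ref.affine, atol=1e-4):
            raise GridMismatchError("affines differ beyond tolerance")


def read_volume(path: str | Path, nan_policy: str = "error") -> VolumeGrid:
    """Read a 3-D or 4-D NIfTI volume.

    Parameters
    ----------
    path
        Path to a ``.nii`` / ``.nii.gz`` file.
    nan_policy
        "error" (default) refuses non-finite voxels; "zero" replaces them
        with 0 and logs the count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim not in (3, 4):
        raise ValueError(f"{path}: expected 3-D or 4-D image, got {data.ndim}-D")
    bad = ~np.isfinite(data)
    if bad.any():
        if nan_policy == "zero":
            logger.info("%s: replacing %d non-finite voxels with 0", path, bad.sum())
            data = np.where(bad, 0.0, data)
        else:
            raise ValueError(
                f"{path}: {bad.sum()} non-finite voxels (nan_policy='error')"
            )
    return VolumeGrid(data=data, affine=np.asarray(img.affine))


def write_volume(vol: VolumeGrid | MaskVolume, path: str | Path) -> None:
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, vol.affine), str(path))


def binarize_probabilistic_mask(
    prob: VolumeGrid, threshold: float = 0.5
) -> MaskVolume:
    """Binarize a probabilistic mask: voxel kept iff probability > threshold.

    The inequality is strict, so a voxel exactly at the threshold is
    excluded.
    """
    data = prob.data
    if data.min() < 0 or data.max() > 1:
        raise ValueError("probabilistic mask values must lie in [0, 1]")
    mask = data > threshold
    if not mask.any():
        raise ValueError(f"empty mask after thresholding at {threshold}")
    out = MaskVolume(data=mask, affine=prob.affine)
    logger.info("binarized mask: %d voxels at threshold %g", out.n_voxels, threshold)
    return out


def mirror_contralateral_mask(
    tumour: MaskVolume,
    lr_axis: int = 0,
    max_overlap_fraction: float = 0.05,
) -> MaskVolume:
    """Reflect the tumour mask across the mid-plane of the left-right axis.

    The mirrored mask serves as the contralateral reference region. Tumours
    crossing the midline make the reflection overlap itself; above
    ``max_overlap_fraction`` this errors and an explicit contralateral mask
    must be supplied instead.
    """
    mirrored = np.flip(tumour.data, axis=lr_axis)
    overlap = int((mirrored & tumour.data).sum())
    frac = overlap / max(tumour.n_voxels, 1)
    logger.info(
        "contralateral mirror: %d voxels, overlap with tumour %.1f%%",
        int(mirrored.sum()), 100 * frac,
    )
    if frac > max_overlap_fraction:
        raise ValueError(
            f"mirrored mask overlaps tumour by {100 * frac:.1f}% "
            f"(> {100 * max_overlap_fraction:.0f}%): tumour crosses the midline; "
            "supply an explicit contralateral mask"
        )
    return MaskVolume(data=mirrored, affine=tumour.affine)
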