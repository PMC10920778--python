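"""Isotropic/anisotropic tensor components and normalized feature spaces.

The diffusion tensor at each voxel, summarized by its eigenvalues
(l1 >= l2 >= l3), is split into an isotropic magnitude p and an anisotropic
(deviatoric) magnitude q:

    MD = (l1 + l2 + l3) / 3
    p  = sqrt(3) * MD
    q  = sqrt((l1 - MD)^2 + (l2 - MD)^2 + (l3 - MD)^2)

which is the Euclidean decomposition of the tensor into its isotropic part
and the deviation from it; it satisfies p^2 + q^2 = l1^2 + l2^2 + l3^2.

Feature maps (p, q, or NODDI neurite density / orientation dispersion) are
normalized by dividing by the mean value over a contralateral reference
region, so that values near 1 indicate tissue similar to the unaffected
hemisphere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grids import MaskVolume, VolumeGrid, check_same_grid

logger = logging.getLogger(__name__)

__all__ = [
    "TensorEigenmap",
    "NormalizationReference",
    "FeatureSpaceSample",
    "compute_pq",
    "contralateral_reference",
    "normalize_and_extract",
]


@dataclass
class TensorEigenmap:
    """Per-voxel diffusion-tensor eigenvalue maps (mm^2/s), co-registered."""

    l1: VolumeGrid
    l2: VolumeGrid
    l3: VolumeGrid

    def __post_init__(self) -> None:
        check_same_grid(self.l1, self.l2, self.l3)

    def stacked(self) -> np.ndarray:
        """Eigenvalues canonically sorted descending, shape (..., 3)."""
        lam = np.stack([self.l1.data, self.l2.data, self.l3.data], axis=-1)
        return np.sort(lam, axis=-1)[..., ::-1]


@dataclass
class NormalizationReference:
    """Contralateral-region mean of one raw feature."""

    mean: float
    n_reference_voxels: int

    def __post_init__(self) -> None:
        if self.n_reference_voxels <= 0:
            raise ValueError("reference region is empty")
        if not np.isfinite(self.mean) or self.mean <= 0:
            raise ValueError(
                f"reference mean {self.mean} is not positive; normalization undefined"
            )


@dataclass
class FeatureSpaceSample:
    """In-mask voxels as points in a normalized 2-D feature plane.

    ``points[i]`` is the (f1, f2) value of the voxel at ``voxel_indices[i]``;
    the pairing is a bijection with the mask support, so labels assigned in
    feature space can be projected back onto the grid.
    """

    points: np.ndarray            # (n, 2) float
    voxel_indices: np.ndarray     # (n, 3) int
    feature_names: tuple[str, str]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.voxel_indices = np.asarray(self.voxel_indices, dtype=int)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2)")
        if self.voxel_indices.shape != (self.points.shape[0], 3):
            raise ValueError("voxel_indices must be (n, 3) matching points")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def subset(self, keep: np.ndarray) -> "FeatureSpaceSample":
        return FeatureSpaceSample(
            points=self.points[keep],
            voxel_indices=self.voxel_indices[keep],
            feature_names=self.feature_names,
        )

    def back_project(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Binary support volume of the sample on the given grid shape."""
        vol = np.zeros(shape, dtype=bool)
        vol[tuple(self.voxel_indices.T)] = True
        return vol


def compute_pq(
    eig: TensorEigenmap, negative_policy: str = "clamp"
) -> tuple[VolumeGrid, VolumeGrid]:
    """Compute the isotropic (p) and anisotropic (q) component maps.

    Negative eigenvalues are un-physical noise; with the default
    ``negative_policy="clamp"`` they are set to 0 before the mean
    diffusivity is formed (count logged), with "error" they raise.
    """
    lam = eig.stacked()
    n_neg = int((lam < 0).sum())
    if n_neg:
        if negative_policy == "clamp":
            logger.warning("clamping %d negative eigenvalues to 0", n_neg)
            lam = np.clip(lam, 0, None)
        else:
            raise ValueError(f"{n_neg} negative eigenvalues (policy='error')")
    md = lam.mean(axis=-1)
    p = np.sqrt(3.0) * md
    q = np.sqrt(((lam - md[..., None]) ** 2).sum(axis=-1))
    return (
        VolumeGrid(data=p, affine=eig.l1.affine),
        VolumeGrid(data=q, affine=eig.l1.affine),
    )


def contralateral_reference(
    feature: VolumeGrid, contra_mask: MaskVolume
) -> NormalizationReference:
    """Arithmetic mean of a raw feature over the contralateral region."""
    check_same_grid(feature, contra_mask)
    n = contra_mask.n_voxels
    if n == 0:
        raise ValueError("contralateral mask is empty")
    mean = float(feature.data[contra_mask.data].mean())
    return NormalizationReference(mean=mean, n_reference_voxels=n)


def normalize_and_extract(
    f1: VolumeGrid,
    f2: VolumeGrid,
    tumour: MaskVolume,
    ref1: NormalizationReference,
    ref2: NormalizationReference,
    feature_names: tuple[str, str] = ("p", "q"),
) -> FeatureSpaceSample:
    """Build the normalized in-tumour 2-D feature space.

    Each in-tumour voxel contributes the point (f1/ref1.mean, f2/ref2.mean).
    """
    check_same_grid(f1, f2, tumour)
    if tumour.n_voxels == 0:
        raise ValueError("tumour mask is empty")
    idx = tumour.indices()
    sel = tuple(idx.T)
    points = np.column_stack(
        [f1.data[sel] / ref1.mean, f2.data[sel] / ref2.mean]
    )
    logger.info(
        "feature space %s: %d points, refs (%.4g, %.4g)",
        feature_names, len(points), ref1.mean, ref2.mean,
    )
    return FeatureSpaceSample(
        points=points, voxel_indices=idx, feature_names=feature_names
    )
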