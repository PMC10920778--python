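"""Quadrant partition of the normalized p-q feature plane.

The plane is split around the (1, 1) point, where both components equal the
contralateral reference:

    group I   : p <= 1, q <= 1   (decreased p, decreased q)
    group II  : p <= 1, q >  1   (decreased p, increased q)
    group III : p >  1, q >  1   (increased p, increased q)
    group IV  : p >  1, q <= 1   (increased p, decreased q)

Values exactly at 1 are assigned to the "decreased" side so the four
predicates are exhaustive on finite-precision data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .diffusion import FeatureSpaceSample
from .grids import MaskVolume

__all__ = ["PQ_GROUPS", "SubregionSet", "assign_quadrants", "occupancy_percentages"]

PQ_GROUPS = ("I", "II", "III", "IV")


@dataclass
class SubregionSet:
    """Integer label volume over the tumour support plus per-label masks.

    ``label_volume`` is 0 outside any subregion; labels are 1-based indices
    into ``names``. Occupancy is the percentage of tumour voxels carrying
    each label; in the quadrant scheme labels cover the tumour exactly, in
    the mixture scheme outlier/unmatched voxels carry no label so the
    occupancies sum to <= 100.
    """

    label_volume: np.ndarray
    names: tuple[str, ...]
    tumour: MaskVolume
    scheme: str
    masks: dict[str, MaskVolume] = field(init=False)
    occupancy: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.masks = {}
        self.occupancy = {}
        n_tum = self.tumour.n_voxels
        if n_tum == 0:
            raise ValueError("empty tumour mask")
        if (self.label_volume[~self.tumour.data] != 0).any():
            raise ValueError("labels outside the tumour support")
        for i, name in enumerate(self.names, start=1):
            m = self.label_volume == i
            self.masks[name] = MaskVolume(data=m, affine=self.tumour.affine)
            self.occupancy[name] = 100.0 * m.sum() / n_tum

    @property
    def presence(self) -> dict[str, bool]:
        return {name: self.masks[name].n_voxels > 0 for name in self.names}


def quadrant_of(p: float, q: float) -> str:
    """Classify one normalized (p, q) point; boundary values count as decreased."""
    if p <= 1:
        return "I" if q <= 1 else "II"
    return "IV" if q <= 1 else "III"


def assign_quadrants(
    sample: FeatureSpaceSample, shape: tuple[int, int, int] | None = None,
    tumour: MaskVolume | None = None,
) -> SubregionSet:
    """Label every feature point by its quadrant and back-project to a volume.

    ``tumour`` defaults to the support of the sample itself.
    """
    if sample.n_points == 0:
        raise ValueError("empty feature-space sample")
    p, q = sample.points[:, 0], sample.points[:, 1]
    labels = np.where(
        p <= 1,
        np.where(q <= 1, 1, 2),      # I / II
        np.where(q <= 1, 4, 3),      # IV / III
    )
    if tumour is None:
        if shape is None:
            shape = tuple(sample.voxel_indices.max(axis=0) + 1)
        tumour = MaskVolume(data=sample.back_project(shape))
    label_volume = np.zeros(tumour.shape, dtype=np.int16)
    label_volume[tuple(sample.voxel_indices.T)] = labels
    return SubregionSet(
        label_volume=label_volume, names=PQ_GROUPS, tumour=tumour, scheme="pq"
    )


def occupancy_percentages(subregions: SubregionSet) -> dict[str, float]:
    """Percentage of tumour voxels in each subregion (0 for empty labels)."""
    return dict(subregions.occupancy)
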