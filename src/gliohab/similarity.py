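"""Spatial agreement between subregion masks from the two segmentation schemes.

Two complementary overlap measures: the symmetric Sorensen-Dice coefficient
2|A∩B|/(|A|+|B|) and the directional percent occupancy, the share of one
mask's voxels that lie inside the other. When overlap is positive the three
are tied by a harmonic-mean identity:
dice = 2 / (100/occ_in_A + 100/occ_in_B).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import MaskVolume, check_same_grid
from .pq import SubregionSet

logger = logging.getLogger(__name__)

__all__ = ["SimilarityReport", "dice", "percent_occupancy", "cross_scheme_table"]


@dataclass
class SimilarityReport:
    dice: float
    occ_in_a: float      # % of A's voxels shared with B
    occ_in_b: float      # % of B's voxels shared with A
    n_a: int
    n_b: int
    n_overlap: int


def dice(a: MaskVolume, b: MaskVolume) -> float:
    """Sorensen-Dice coefficient 2|A∩B|/(|A|+|B|)."""
    check_same_grid(a, b)
    denom = a.n_voxels + b.n_voxels
    if denom == 0:
        raise ValueError("both masks are empty")
    return 2.0 * int((a.data & b.data).sum()) / denom


def percent_occupancy(a: MaskVolume, b: MaskVolume, denominator: str = "b") -> float:
    """Overlap voxels as a percentage of one mask's size.

    ``denominator`` names the subregion of interest: "a" or "b".
    """
    check_same_grid(a, b)
    denom_mask = {"a": a, "b": b}[denominator]
    if denom_mask.n_voxels == 0:
        raise ValueError("denominator mask is empty")
    return 100.0 * int((a.data & b.data).sum()) / denom_mask.n_voxels


def compare_masks(a: MaskVolume, b: MaskVolume) -> SimilarityReport:
    """Dice plus both directional occupancies for one mask pair."""
    check_same_grid(a, b)
    n_overlap = int((a.data & b.data).sum())
    return SimilarityReport(
        dice=dice(a, b),
        occ_in_a=100.0 * n_overlap / a.n_voxels if a.n_voxels else 0.0,
        occ_in_b=100.0 * n_overlap / b.n_voxels if b.n_voxels else 0.0,
        n_a=a.n_voxels,
        n_b=b.n_voxels,
        n_overlap=n_overlap,
    )


def cross_scheme_table(pq: SubregionSet, noddi: SubregionSet) -> pd.DataFrame:
    """Similarity of every (quadrant group, canonical class) pair of one subject.

    Both occupancy directions are reported explicitly; pairs where either
    mask is absent in this subject are skipped.
    """
    check_same_grid(pq.tumour, noddi.tumour)
    rows = []
    for g, gm in pq.masks.items():
        for c, cm in noddi.masks.items():
            if gm.n_voxels == 0 or cm.n_voxels == 0:
                continue
            rep = compare_masks(gm, cm)
            rows.append(
                {
                    "pq_group": g,
                    "class": c,
                    "dice": rep.dice,
                    "occ_of_pair_in_pq_group": rep.occ_in_a,
                    "occ_of_pair_in_class": rep.occ_in_b,
                    "n_pq": rep.n_a,
                    "n_class": rep.n_b,
                    "n_overlap": rep.n_overlap,
                }
            )
    if not rows:
        logger.info("no co-present subregion pairs for this subject")
        return pd.DataFrame(
            columns=["pq_group", "class", "dice", "occ_of_pair_in_pq_group",
                     "occ_of_pair_in_class", "n_pq", "n_class", "n_overlap"]
        )
    return pd.DataFrame(rows)
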