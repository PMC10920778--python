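"""Synthetic glioma cohort with fully known ground truth.

Emulates the statistical structure the pipeline expects from a real
cohort — nothing more: lateralized connected tumour blobs on a shared
grid; in-tumour diffusion features drawn from planted mixtures on the
normalized [0, 2]^2 feature plane (quadrant-structured for the p-q arm,
Gaussian classes with known centroids for the ND-ODI arm); contralateral
reference tissue whose in-mask mean is exactly 1 after normalization; BOLD
series in which each habitat's voxels follow beta * GS plus regional and
voxel noise; and cognitive z-scores whose pre-to-post decline is a linear
function of the occupancy of one designated "eloquent" habitat.

Every random draw derives from one integer seed, so identical
(spec, seed) pairs produce identical cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter, label as cc_label

from .cognition import DOMAINS
from .coupling import band_filter
from .grids import MaskVolume, VolumeGrid, binarize_probabilistic_mask, write_volume
from .pq import PQ_GROUPS, quadrant_of

logger = logging.getLogger(__name__)

__all__ = ["HabitatClass", "SyntheticCohortSpec", "GroundTruth", "SubjectData",
           "Cohort", "generate_subject", "generate_cohort"]


@dataclass
class HabitatClass:
    """One planted feature-space component."""

    name: str
    centroid: tuple[float, float]     # normalized units (reference tissue = 1)
    presence_prob: float = 1.0        # chance a subject carries the class
    weight: float = 1.0               # relative share of tumour voxels when present
    beta: float = 0.0                 # planted BOLD coupling slope with the GS


def _default_pq_classes() -> list[HabitatClass]:
    # Quadrant-structured mixture: occupancies ordered IV > III > I > II,
    # the ordering a glioma cohort typically shows; higher-diffusivity
    # quadrants (III, IV) couple more strongly with the global signal.
    return [
        HabitatClass("I", (0.85, 0.85), weight=0.112, beta=0.2),
        HabitatClass("II", (0.85, 1.25), weight=0.043, beta=0.2),
        HabitatClass("III", (1.30, 1.30), weight=0.279, beta=0.6),
        HabitatClass("IV", (1.35, 0.80), weight=0.566, beta=0.6),
    ]


def _default_noddi_classes() -> list[HabitatClass]:
    # Centroids and presence probabilities chosen as realistic values for
    # normalized neurite density / orientation dispersion in glioma tissue.
    return [
        HabitatClass("A", (0.34, 0.63), presence_prob=0.875, weight=0.45),
        HabitatClass("B", (0.41, 1.11), presence_prob=0.75, weight=0.23),
        HabitatClass("C", (0.56, 0.79), presence_prob=0.3125, weight=0.25),
        HabitatClass("D", (0.16, 0.46), presence_prob=0.3125, weight=0.75),
        HabitatClass("E", (0.12, 0.28), presence_prob=0.125, weight=0.73),
    ]


@dataclass
class SyntheticCohortSpec:
    """All knobs of the generator, with study-scale defaults."""

    n_subjects: int = 16
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 2.0
    tumour_size_range: tuple[int, int] = (800, 3000)     # voxels
    pq_classes: list[HabitatClass] = field(default_factory=_default_pq_classes)
    noddi_classes: list[HabitatClass] = field(default_factory=_default_noddi_classes)
    pq_within_sd: float = 0.10          # spread of points around a quadrant centroid
    occupancy_concentration: float = 14.0   # Dirichlet concentration: lower =
                                            # more between-subject occupancy spread
    noddi_shared_cov: tuple[tuple[float, float], tuple[float, float]] = (
        (0.0025, 0.0), (0.0, 0.0025))   # within-tumour cluster covariance
    noddi_centroid_jitter_sd: float = 0.03   # between-subject centroid wobble
    background_sd: float = 0.05         # healthy-tissue spread around 1
    ref_scale: tuple[float, float] = (1.0, 1.0)   # raw units per normalized unit
    # cognition
    eloquent_class: str = "III"
    decline_effect_overall: float = 0.022    # mean Delta z per % occupancy
    decline_effect_verbal: float = 0.037     # verbal-skills Delta z per % occupancy
    noise_sd_cognition: float = 0.45
    n_missing_post: int = 3
    idh_mutation_prob: float = 0.6875
    # BOLD
    bold_length: int = 300
    tr: float = 1.06
    gs_band: tuple[float, float] = (0.03, 0.12)   # Hz
    beta_contralateral: float = 0.9
    beta_gm: float = 1.0
    bold_voxel_noise_sd: float = 0.1
    bold_regional_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bold_length and self.bold_length < 100:
            raise ValueError("bold_length must be 0 (disabled) or >= 100 frames")
        cov = np.asarray(self.noddi_shared_cov, float)
        if not np.allclose(cov, cov.T) or np.linalg.eigvalsh(cov).min() <= 0:
            raise ValueError("noddi_shared_cov must be symmetric positive-definite")

    def domain_effects(self) -> dict[str, float]:
        """Per-domain decline per % occupancy; averages to the overall effect."""
        other = (len(DOMAINS) * self.decline_effect_overall
                 - self.decline_effect_verbal) / (len(DOMAINS) - 1)
        return {d: self.decline_effect_verbal if d == "verbal_skills" else other
                for d in DOMAINS}


@dataclass
class GroundTruth:
    """What the generator planted for one subject."""

    pq_labels: np.ndarray                 # label volume, 1..4 on tumour support
    pq_occupancy: dict[str, float]
    noddi_labels: np.ndarray              # 1-based into present_classes, on support
    noddi_present_classes: list[str]
    noddi_centroids: dict[str, np.ndarray]   # subject-level true centroids
    noddi_occupancy: dict[str, float]
    betas: dict[str, float]               # per quadrant class + "contralateral"
    true_delta: dict[str, float]          # decline before noise, per domain
    gs: np.ndarray | None


@dataclass
class SubjectData:
    subject: str
    tumour_prob: VolumeGrid
    tumour_mask: MaskVolume
    contra_mask: MaskVolume
    gm_mask: MaskVolume
    p_map: VolumeGrid
    q_map: VolumeGrid
    nd_map: VolumeGrid
    odi_map: VolumeGrid
    bold: VolumeGrid | None
    fd: np.ndarray | None
    record: dict
    truth: GroundTruth


@dataclass
class Cohort:
    spec: SyntheticCohortSpec
    subjects: list[SubjectData]
    manifest: pd.DataFrame


def _tumour_blob(
    shape: tuple[int, int, int], size_target: int, rng: np.random.Generator
) -> np.ndarray:
    """A connected, irregular blob confined to the low-x hemisphere.

    An ellipsoid around a random centre is perturbed by a smoothed random
    field and reduced to its largest connected component.
    """
    nx, ny, nz = shape
    mid = nx // 2
    # radius budget from the target volume of an ellipsoid
    r_mean = (3.0 * size_target / (4.0 * np.pi)) ** (1.0 / 3.0)
    for _ in range(20):
        radii = r_mean * rng.uniform(0.7, 1.4, size=3)
        radii = np.minimum(radii, [0.5 * (mid - 3), 0.45 * ny, 0.45 * nz])
        lo = radii + 1
        hi = np.array([mid, ny, nz]) - radii - 2
        if (lo >= hi).any() or (radii < 1).any():
            continue
        cx, cy, cz = (rng.uniform(l, h) for l, h in zip(lo, hi))
        xi, yi, zi = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        quad = (((xi - cx) / radii[0]) ** 2 + ((yi - cy) / radii[1]) ** 2
                + ((zi - cz) / radii[2]) ** 2)
        noise = gaussian_filter(rng.standard_normal(shape), sigma=3)
        noise /= max(noise.std(), 1e-12)
        blob = (quad + 0.4 * noise) < 1.0
        blob[mid:] = False                     # enforce lateralization
        labels, n = cc_label(blob)
        if n == 0:
            continue
        sizes = np.bincount(labels.ravel())[1:]
        blob = labels == (1 + int(np.argmax(sizes)))
        if blob.sum() >= 30:
            return blob
    raise ValueError(f"could not fit a tumour blob of ~{size_target} voxels in {shape}")


def _sample_quadrant_points(
    group: str, centroid: np.ndarray, sd: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian draws rejection-sampled into the group's quadrant."""
    out = np.empty((0, 2))
    while len(out) < n:
        draw = rng.normal(centroid, sd, size=(max(2 * (n - len(out)), 16), 2))
        ok = np.array([quadrant_of(p, q) == group for p, q in draw])
        out = np.vstack([out, draw[ok]])
    return out[:n]


def _affine(voxel_size: float) -> np.ndarray:
    aff = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    return aff


def _band_noise(n: int, tr: float, band: tuple[float, float],
                rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise restricted to the analysis frequency band."""
    ts = band_filter(rng.standard_normal(n), tr=tr, low=band[0], high=band[1])
    return ts / max(ts.std(), 1e-12)


def generate_subject(
    spec: SyntheticCohortSpec, subject_index: int, rng: np.random.Generator
) -> SubjectData:
    """Generate all volumes, series and scores for one synthetic participant."""
    shape = tuple(spec.grid_shape)
    affine = _affine(spec.voxel_size_mm)
    size_target = int(rng.integers(spec.tumour_size_range[0],
                                   spec.tumour_size_range[1] + 1))
    blob = _tumour_blob(shape, size_target, rng)

    # probabilistic mask whose >0.5 binarization defines the true tumour
    prob = gaussian_filter(blob.astype(float), sigma=1.0)
    prob = np.clip(prob, 0.0, 1.0)
    tumour_prob = VolumeGrid(data=prob, affine=affine)
    tumour = binarize_probabilistic_mask(tumour_prob, 0.5)
    contra = MaskVolume(data=np.flip(tumour.data, axis=0), affine=affine)

    # brain = centred ellipsoid (symmetric in x, so the mirror region is inside)
    xi, yi, zi = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    centre = (np.array(shape) - 1) / 2.0
    brain = (((xi - centre[0]) / (0.48 * shape[0])) ** 2
             + ((yi - centre[1]) / (0.48 * shape[1])) ** 2
             + ((zi - centre[2]) / (0.48 * shape[2])) ** 2) < 1.0
    brain |= tumour.data | contra.data
    gm = MaskVolume(data=brain, affine=affine)

    idx = tumour.indices()
    n_vox = len(idx)

    # ---- p-q arm: quadrant-structured mixture ----
    # subject-level Dirichlet around the cohort occupancies, so occupancy
    # varies between subjects the way it does across patients; conditioned
    # on every quadrant group appearing (the quadrant scheme covers the
    # whole plane, and real tumours show voxels in all four)
    base = np.array([c.weight for c in spec.pq_classes], float)
    base /= base.sum()
    for _ in range(50):
        probs = rng.dirichlet(spec.occupancy_concentration * base)
        draw = rng.choice(len(spec.pq_classes), size=n_vox, p=probs)
        if len(np.unique(draw)) == len(spec.pq_classes):
            break
    else:
        raise ValueError("could not draw a tumour containing every quadrant group")
    pq_points = np.empty((n_vox, 2))
    for gi, cls in enumerate(spec.pq_classes):
        sel = draw == gi
        if sel.any():
            pq_points[sel] = _sample_quadrant_points(
                cls.name, np.asarray(cls.centroid), spec.pq_within_sd,
                int(sel.sum()), rng)
    pq_labels = np.zeros(shape, dtype=np.int16)
    pq_labels[tuple(idx.T)] = draw + 1
    pq_occ = {c.name: 100.0 * float((draw == gi).sum()) / n_vox
              for gi, c in enumerate(spec.pq_classes)}

    # ---- ND-ODI arm: Gaussian classes, subset present per subject ----
    present = [c for c in spec.noddi_classes
               if rng.random() < c.presence_prob]
    if not present:
        present = [spec.noddi_classes[int(rng.integers(len(spec.noddi_classes)))]]
    centroids = {c.name: np.asarray(c.centroid)
                 + rng.normal(0, spec.noddi_centroid_jitter_sd, 2)
                 for c in present}
    w = np.array([c.weight for c in present], float)
    w /= w.sum()
    if len(present) > 1:
        w = rng.dirichlet(spec.occupancy_concentration * w)
    nd_draw = rng.choice(len(present), size=n_vox, p=w)
    cov = np.asarray(spec.noddi_shared_cov, float)
    noddi_points = np.empty((n_vox, 2))
    for ci, cls in enumerate(present):
        sel = nd_draw == ci
        if sel.any():
            noddi_points[sel] = rng.multivariate_normal(
                centroids[cls.name], cov, size=int(sel.sum()))
    noddi_points = np.abs(noddi_points)    # physical maps are non-negative
    noddi_labels = np.zeros(shape, dtype=np.int16)
    noddi_labels[tuple(idx.T)] = nd_draw + 1
    noddi_occ = {c.name: 100.0 * float((nd_draw == ci).sum()) / n_vox
                 for ci, c in enumerate(present)}

    # ---- raw feature maps: background ~ N(1, sd), exact contralateral mean 1
    def _feature_map(tumour_vals: np.ndarray, scale: float) -> VolumeGrid:
        data = np.zeros(shape)
        bg = rng.normal(1.0, spec.background_sd, size=int(brain.sum()))
        data[brain] = bg
        cvals = data[contra.data]
        data[contra.data] = cvals - cvals.mean() + 1.0   # exact reference mean
        data[tuple(idx.T)] = tumour_vals
        return VolumeGrid(data=data * scale, affine=affine)

    p_map = _feature_map(pq_points[:, 0], spec.ref_scale[0])
    q_map = _feature_map(pq_points[:, 1], spec.ref_scale[1])
    nd_map = _feature_map(noddi_points[:, 0], spec.ref_scale[0])
    odi_map = _feature_map(noddi_points[:, 1], spec.ref_scale[1])

    # ---- BOLD ----
    betas = {c.name: c.beta for c in spec.pq_classes}
    betas["contralateral"] = spec.beta_contralateral
    bold = None
    fd = None
    gs = None
    if spec.bold_length:
        t = spec.bold_length
        gs = _band_noise(t, spec.tr, spec.gs_band, rng)
        data = np.zeros(shape + (t,), dtype=np.float32)
        # regional (shared, band-limited) noise per habitat keeps region-mean
        # series noisy even after voxel averaging
        regional = {
            name: spec.bold_regional_noise_sd * _band_noise(t, spec.tr, spec.gs_band, rng)
            for name in list(betas)
        }
        healthy = brain & ~tumour.data & ~contra.data
        n_h = int(healthy.sum())
        data[healthy] = (spec.beta_gm * gs)[None, :] + rng.normal(
            0, spec.bold_voxel_noise_sd, size=(n_h, t)).astype(np.float32)
        for gi, cls in enumerate(spec.pq_classes):
            vox = idx[draw == gi]
            if not len(vox):
                continue
            base = cls.beta * gs + regional[cls.name]
            data[tuple(vox.T)] = base[None, :] + rng.normal(
                0, spec.bold_voxel_noise_sd, size=(len(vox), t)).astype(np.float32)
        cvox = np.argwhere(contra.data)
        base = spec.beta_contralateral * gs + regional["contralateral"]
        data[tuple(cvox.T)] = base[None, :] + rng.normal(
            0, spec.bold_voxel_noise_sd, size=(len(cvox), t)).astype(np.float32)
        bold = VolumeGrid(data=data, affine=affine)
        fd = np.zeros(t)

    # ---- cognition ----
    effects = spec.domain_effects()
    occ_eloquent = pq_occ.get(spec.eloquent_class, 0.0)
    true_delta = {d: effects[d] * occ_eloquent for d in DOMAINS}
    pre = {d: float(rng.standard_normal()) for d in DOMAINS}
    delta = {d: true_delta[d] + float(rng.normal(0, spec.noise_sd_cognition))
             for d in DOMAINS}
    post = {d: pre[d] - delta[d] for d in DOMAINS}

    vol_cm3 = tumour.n_voxels * (spec.voxel_size_mm ** 3) / 1000.0
    record = {
        "subject": f"sub-{subject_index:03d}",
        "tumour_volume_cm3": vol_cm3,
        "tumour_volume_post_cm3": vol_cm3 * float(rng.lognormal(0.0, 0.3)),
        "idh_mutated": bool(rng.random() < spec.idh_mutation_prob),
        "grade": int(rng.integers(1, 5)),
        "age": float(rng.uniform(20, 60)),
        "years_education": float(rng.uniform(9, 20)),
        "hippocampus_vol_pre": float(rng.normal(3.5, 0.4)),
        "hippocampus_act_pre": float(rng.normal(0.0, 1.0)),
        **{f"pre_{d}": pre[d] for d in DOMAINS},
        **{f"post_{d}": post[d] for d in DOMAINS},
    }

    truth = GroundTruth(
        pq_labels=pq_labels,
        pq_occupancy=pq_occ,
        noddi_labels=noddi_labels,
        noddi_present_classes=[c.name for c in present],
        noddi_centroids=centroids,
        noddi_occupancy=noddi_occ,
        betas=betas,
        true_delta=true_delta,
        gs=gs,
    )
    return SubjectData(
        subject=record["subject"],
        tumour_prob=tumour_prob,
        tumour_mask=tumour,
        contra_mask=contra,
        gm_mask=gm,
        p_map=p_map,
        q_map=q_map,
        nd_map=nd_map,
        odi_map=odi_map,
        bold=bold,
        fd=fd,
        record=record,
        truth=truth,
    )


def generate_cohort(
    spec: SyntheticCohortSpec,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> Cohort:
    """Generate the whole cohort; optionally write NIfTI volumes + manifest CSV.

    Deterministic: the same (spec, seed) always yields the same cohort.
    ``seed`` defaults to ``spec.seed``.
    """
    if spec.n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    seed = spec.seed if seed is None else seed
    streams = np.random.SeedSequence(seed).spawn(spec.n_subjects + 1)
    subjects = [
        generate_subject(spec, i, np.random.default_rng(streams[i]))
        for i in range(spec.n_subjects)
    ]
    # pick who lacks post-operative scores (excluded from cognition analyses)
    rng = np.random.default_rng(streams[-1])
    missing = rng.choice(spec.n_subjects, size=min(spec.n_missing_post,
                                                   spec.n_subjects), replace=False)
    records = []
    for i, s in enumerate(subjects):
        rec = dict(s.record)
        if i in missing:
            for d in DOMAINS:
                rec[f"post_{d}"] = np.nan
        records.append(rec)
        subjects[i].record = rec
    manifest = pd.DataFrame(records)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for s in subjects:
            sd = out / s.subject
            sd.mkdir(exist_ok=True)
            write_volume(s.tumour_prob, sd / "tumour_prob.nii.gz")
            write_volume(s.gm_mask, sd / "gm_mask.nii.gz")
            write_volume(s.p_map, sd / "p.nii.gz")
            write_volume(s.q_map, sd / "q.nii.gz")
            write_volume(s.nd_map, sd / "nd.nii.gz")
            write_volume(s.odi_map, sd / "odi.nii.gz")
            if s.bold is not None:
                write_volume(s.bold, sd / "bold.nii.gz")
        manifest.to_csv(out / "manifest.csv", index=False)
        with open(out / "cohort_spec.yaml", "w") as fh:
            yaml.safe_dump(_spec_to_dict(spec), fh, sort_keys=False)
        logger.info("wrote cohort of %d subjects to %s", len(subjects), out)
    return Cohort(spec=spec, subjects=subjects, manifest=manifest)


def _spec_to_dict(spec: SyntheticCohortSpec) -> dict:
    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        return obj

    return _clean(asdict(spec))
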