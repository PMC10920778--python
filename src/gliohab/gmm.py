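"""Data-driven feature-space segmentation and cross-subject class matching.

Per subject, the normalized ND-ODI cloud is segmented with a Gaussian
mixture whose components share one full covariance matrix, fitted by EM
with several random restarts; the number of components (1-7) is chosen by
maximizing the mean silhouette of the hard labelling. Because subjects need
not share the same number or location of components, a cohort-level
matching step then merges per-subject components whose centroids lie
within a Euclidean distance threshold (0.3 in normalized units) into
canonical classes C1, C2, ..., ordered by how many subjects carry them;
components that never match are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation
from sklearn.metrics import silhouette_score

from .diffusion import FeatureSpaceSample
from .grids import MaskVolume
from .pq import SubregionSet

logger = logging.getLogger(__name__)

__all__ = [
    "GMMFit",
    "PartitionMatchTable",
    "remove_outliers",
    "fit_gmm",
    "select_k",
    "match_partitions",
    "to_subregions",
    "prevalence_percentages",
]


def remove_outliers(
    sample: FeatureSpaceSample, n_mad: float = 3.0
) -> FeatureSpaceSample:
    """Drop points outside median +/- n_mad * scaled MAD on either feature.

    The MAD is scaled to be consistent with the normal SD, so the default
    band removes ~0.5% of a clean Gaussian sample. More than half the
    points removed signals a pathological sample and raises.
    """
    if sample.n_points < 30:
        raise ValueError(f"need >= 30 points, got {sample.n_points}")
    pts = sample.points
    med = np.median(pts, axis=0)
    mad = median_abs_deviation(pts, axis=0, scale="normal")
    keep = np.all(np.abs(pts - med) <= n_mad * mad, axis=1)
    n_drop = int((~keep).sum())
    if n_drop > 0.5 * sample.n_points or sample.n_points - n_drop < 30:
        raise ValueError(
            f"outlier removal dropped {n_drop}/{sample.n_points} points; "
            "sample is pathological"
        )
    logger.info("outlier removal: dropped %d of %d points", n_drop, sample.n_points)
    return sample.subset(keep)


@dataclass
class GMMFit:
    """A converged shared-covariance Gaussian mixture fit."""

    k: int
    means: np.ndarray              # (k, 2)
    covariance: np.ndarray         # (2, 2), shared across components
    weights: np.ndarray            # (k,)
    responsibilities: np.ndarray   # (n, k)
    labels: np.ndarray             # (n,) hard labels = argmax responsibility
    log_likelihood: float
    ll_trajectory: np.ndarray      # per-iteration total log-likelihood
    best_replicate: int
    n_iter: int

    def __post_init__(self) -> None:
        if not np.allclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        # symmetric positive-definite shared covariance
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValueError("covariance not symmetric")
        np.linalg.cholesky(self.covariance)
        # EM guarantees a monotone likelihood; a decrease marks a bug
        diffs = np.diff(self.ll_trajectory)
        if (diffs < -1e-8 * max(1.0, abs(self.log_likelihood))).any():
            raise AssertionError("EM log-likelihood decreased across iterations")


def _log_gauss(x: np.ndarray, means: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log density of each point under each component, shape (n, k).

    Specialized for the 2-D feature plane: the precision matrix and log
    determinant are closed-form, and the Mahalanobis term is evaluated with
    broadcasting only (EM spends nearly all its time here).
    """
    det = cov[0, 0] * cov[1, 1] - cov[0, 1] * cov[1, 0]
    if det <= 0:
        raise np.linalg.LinAlgError("singular shared covariance")
    a, b, c = cov[1, 1] / det, -cov[0, 1] / det, cov[0, 0] / det
    dx = x[:, 0:1] - means[None, :, 0]            # (n, k)
    dy = x[:, 1:2] - means[None, :, 1]
    maha = a * dx * dx + 2.0 * b * dx * dy + c * dy * dy
    return -0.5 * (2.0 * np.log(2 * np.pi) + np.log(det) + maha)


def _kmeanspp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ style seeding of component means."""
    n = x.shape[0]
    centers = [x[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min(
            ((x[:, None, :] - np.array(centers)[None]) ** 2).sum(-1), axis=1
        )
        probs = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
        centers.append(x[rng.choice(n, p=probs)])
    return np.array(centers)


def _em_once(
    x: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    reg_covar: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[float]]:
    n, d = x.shape
    means = _kmeanspp_init(x, k, rng)
    cov = np.cov(x.T, bias=True) + reg_covar * np.eye(d)
    weights = np.full(k, 1.0 / k)
    lls: list[float] = []
    resp = np.full((n, k), 1.0 / k)
    for _ in range(max_iter):
        # E step (manual logsumexp: this loop is the hot path)
        log_prob = _log_gauss(x, means, cov) + np.log(weights)[None, :]
        m = log_prob.max(axis=1)
        resp = np.exp(log_prob - m[:, None])
        tot = resp.sum(axis=1)
        norm = m + np.log(tot)
        resp /= tot[:, None]
        ll = float(norm.sum())
        if lls and abs(ll - lls[-1]) < tol * max(1.0, abs(ll)):
            lls.append(ll)
            break
        lls.append(ll)
        # M step (shared full covariance: responsibility-weighted pooled
        # scatter; responsibilities sum to 1 per point, so the pooled
        # second moment is just X'X minus the component-mean outer products)
        nk = resp.sum(axis=0) + 1e-12
        weights = nk / n
        means = (resp.T @ x) / nk[:, None]
        cov = (x.T @ x - (means.T * nk) @ means) / n + reg_covar * np.eye(d)
    return means, cov, weights, resp, lls


def fit_gmm(
    sample: FeatureSpaceSample | np.ndarray,
    k: int,
    n_replicates: int = 5,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    reg_covar: float = 1e-6,
) -> GMMFit:
    """Fit a k-component Gaussian mixture with one shared full covariance.

    The best of ``n_replicates`` random EM initializations (by final
    log-likelihood) is returned; hard labels are the argmax
    responsibilities. Deterministic given ``seed``.
    """
    x = sample.points if isinstance(sample, FeatureSpaceSample) else np.asarray(sample)
    if k < 1:
        raise ValueError("k must be >= 1")
    if x.shape[0] <= 10 * k:
        raise ValueError(f"need > {10 * k} points for k={k}, got {x.shape[0]}")
    root = np.random.default_rng(seed)
    best = None
    for rep in range(n_replicates):
        rng = np.random.default_rng(root.integers(2**31))
        means, cov, weights, resp, lls = _em_once(x, k, rng, max_iter, tol, reg_covar)
        if best is None or lls[-1] > best[0]:
            best = (lls[-1], rep, means, cov, weights, resp, lls)
    ll, rep, means, cov, weights, resp, lls = best
    return GMMFit(
        k=k,
        means=means,
        covariance=cov,
        weights=weights,
        responsibilities=resp,
        labels=np.argmax(resp, axis=1),
        log_likelihood=ll,
        ll_trajectory=np.array(lls),
        best_replicate=rep,
        n_iter=len(lls),
    )


def select_k(
    sample: FeatureSpaceSample | np.ndarray,
    k_range: range = range(1, 8),
    n_replicates: int = 5,
    seed: int = 0,
    silhouette_floor: float = 0.5,
    silhouette_sample_size: int | None = 2000,
) -> tuple[int, GMMFit, dict[int, float]]:
    """Choose the component count maximizing the mean silhouette index.

    The silhouette (Euclidean, on hard labels) is undefined for a single
    cluster; one component is selected only when no k >= 2 reaches
    ``silhouette_floor``. Large samples are subsampled (seeded) for the
    silhouette computation only.
    """
    x = sample.points if isinstance(sample, FeatureSpaceSample) else np.asarray(sample)
    n = x.shape[0]
    fits: dict[int, GMMFit] = {}
    scores: dict[int, float] = {}
    for k in k_range:
        if n <= 10 * k:
            break
        fit = fit_gmm(sample, k, n_replicates=n_replicates, seed=seed + k)
        fits[k] = fit
        if k == 1:
            continue
        if len(np.unique(fit.labels)) < 2:
            scores[k] = -1.0
            continue
        kwargs = {}
        if silhouette_sample_size is not None and n > silhouette_sample_size:
            kwargs = dict(
                sample_size=silhouette_sample_size,
                random_state=np.random.default_rng(seed).integers(2**31),
            )
        scores[k] = float(silhouette_score(x, fit.labels, **kwargs))
    if not fits:
        raise ValueError("sample too small for any k in range")
    if scores and max(scores.values()) >= silhouette_floor:
        k_star = max(scores, key=lambda k: (scores[k], -k))
    else:
        k_star = 1
    if k_star not in fits:
        k_star = min(fits)
    logger.info("selected k=%d (silhouettes: %s)", k_star, scores)
    return k_star, fits[k_star], scores


@dataclass
class PartitionMatchTable:
    """Cohort-level assignment of per-subject components to canonical classes.

    ``table`` has one row per (subject, component) with the matched class
    name or "excluded" and the Euclidean distance to the class centroid at
    assignment time. Class names C1, C2, ... are ordered by descending
    number of member subjects.
    """

    table: pd.DataFrame
    class_centroids: dict[str, np.ndarray]
    tau: float

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(self.class_centroids)

    def assignment_for(self, subject: object) -> dict[int, str]:
        rows = self.table[self.table["subject"] == subject]
        return dict(zip(rows["component"], rows["class"]))


def match_partitions(
    fits: dict[object, GMMFit], tau: float = 0.3
) -> PartitionMatchTable:
    """Greedily merge per-subject mixture components into canonical classes.

    All (component, component) and (component, class) centroid distances
    across subjects are considered; the globally closest admissible pair is
    merged, class centroids are recomputed as member means, and the process
    repeats until no distance below ``tau`` remains. A merge is refused when
    it would put two components of one subject in the same class. Ties are
    broken by subject then component order, making the result independent
    of dict ordering.
    """
    if len(fits) < 2:
        raise ValueError("matching needs at least 2 subjects")
    subjects = sorted(fits, key=str)
    comps = [
        {"subject": s, "component": j, "centroid": fits[s].means[j]}
        for s in subjects
        for j in range(fits[s].k)
    ]
    unassigned = list(range(len(comps)))
    classes: list[dict] = []  # {"members": [comp_idx], "centroid": ...}

    def _class_centroid(members: list[int]) -> np.ndarray:
        return np.mean([comps[i]["centroid"] for i in members], axis=0)

    def _subjects_of(members: list[int]) -> set:
        return {comps[m]["subject"] for m in members}

    dist_at_merge = {}
    while True:
        candidates = []
        # unassigned-unassigned pairs seed a new class
        for a_pos, a in enumerate(unassigned):
            for b in unassigned[a_pos + 1:]:
                if comps[a]["subject"] == comps[b]["subject"]:
                    continue
                d = float(np.linalg.norm(comps[a]["centroid"] - comps[b]["centroid"]))
                if d < tau:
                    candidates.append((d, 0, a, b))
            # unassigned component joins an existing class
            for ci, cl in enumerate(classes):
                if comps[a]["subject"] in _subjects_of(cl["members"]):
                    continue
                d = float(np.linalg.norm(comps[a]["centroid"] - cl["centroid"]))
                if d < tau:
                    candidates.append((d, 1, a, ci))
        # two classes with disjoint subject sets fuse (keeps one canonical
        # class per true cluster regardless of merge order)
        for ci in range(len(classes)):
            for cj in range(ci + 1, len(classes)):
                if _subjects_of(classes[ci]["members"]) & _subjects_of(
                    classes[cj]["members"]
                ):
                    continue
                d = float(np.linalg.norm(
                    classes[ci]["centroid"] - classes[cj]["centroid"]))
                if d < tau:
                    candidates.append((d, 2, ci, cj))
        if not candidates:
            break
        candidates.sort()
        d, kind, a, other = candidates[0]
        if kind == 0:
            classes.append({"members": [a, other], "centroid": None})
            dist_at_merge[a] = d
            dist_at_merge[other] = d
            unassigned.remove(a)
            unassigned.remove(other)
            classes[-1]["centroid"] = _class_centroid(classes[-1]["members"])
        elif kind == 1:
            classes[other]["members"].append(a)
            dist_at_merge[a] = d
            unassigned.remove(a)
            classes[other]["centroid"] = _class_centroid(classes[other]["members"])
        else:
            classes[a]["members"].extend(classes[other]["members"])
            classes[a]["centroid"] = _class_centroid(classes[a]["members"])
            del classes[other]

    # canonical naming: most prevalent class first; centroid breaks ties
    classes.sort(
        key=lambda c: (-len(c["members"]), c["centroid"][0], c["centroid"][1])
    )
    names = [f"C{i + 1}" for i in range(len(classes))]
    rows = []
    for name, cl in zip(names, classes):
        for m in cl["members"]:
            rows.append(
                {
                    "subject": comps[m]["subject"],
                    "component": comps[m]["component"],
                    "class": name,
                    "distance": dist_at_merge[m],
                }
            )
    for m in unassigned:
        rows.append(
            {
                "subject": comps[m]["subject"],
                "component": comps[m]["component"],
                "class": "excluded",
                "distance": np.nan,
            }
        )
    table = (
        pd.DataFrame(rows, columns=["subject", "component", "class", "distance"])
        .sort_values(["subject", "component"], key=lambda s: s.map(str))
        .reset_index(drop=True)
    )
    n_excl = int((table["class"] == "excluded").sum())
    logger.info("matched %d classes, %d components excluded", len(classes), n_excl)
    return PartitionMatchTable(
        table=table,
        class_centroids={n: c["centroid"] for n, c in zip(names, classes)},
        tau=tau,
    )


def to_subregions(
    fit: GMMFit,
    sample: FeatureSpaceSample,
    assignment: dict[int, str],
    class_names: tuple[str, ...],
    tumour: MaskVolume,
) -> SubregionSet:
    """Project matched component labels back onto the tumour grid.

    ``sample`` must be the (outlier-filtered) point set the fit was run on.
    Voxels of excluded components, like removed outliers, carry no label, so
    occupancies are relative to the full tumour and may sum below 100%.
    """
    if fit.labels.shape[0] != sample.n_points:
        raise ValueError("fit labels do not align with sample points")
    label_volume = np.zeros(tumour.shape, dtype=np.int16)
    name_to_id = {n: i + 1 for i, n in enumerate(class_names)}
    for comp, cls in assignment.items():
        if cls == "excluded":
            continue
        vox = sample.voxel_indices[fit.labels == comp]
        label_volume[tuple(vox.T)] = name_to_id[cls]
    return SubregionSet(
        label_volume=label_volume, names=class_names, tumour=tumour, scheme="noddi"
    )


def prevalence_percentages(
    presence: pd.DataFrame | dict[str, list[bool]]
) -> dict[str, float]:
    """Percent of subjects carrying each class (columns = classes)."""
    df = pd.DataFrame(presence)
    return {c: 100.0 * df[c].mean() for c in df.columns}
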