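import numpy as np
import pytest

from gliohab.diffusion import FeatureSpaceSample
from gliohab.gmm import (
    GMMFit,
    fit_gmm,
    match_partitions,
    prevalence_percentages,
    remove_outliers,
    select_k,
    to_subregions,
)
from gliohab.grids import MaskVolume


def _sample(points, shape=(20, 20, 20)):
    points = np.asarray(points)
    flat = np.random.default_rng(0).choice(
        np.prod(shape), size=len(points), replace=False
    )
    idx = np.column_stack(np.unravel_index(flat, shape))
    return FeatureSpaceSample(points=points, voxel_indices=idx,
                              feature_names=("ND", "ODI"))


def _fake_fit(centroids):
    centroids = np.atleast_2d(centroids)
    k = len(centroids)
    return GMMFit(
        k=k,
        means=centroids,
        covariance=0.0025 * np.eye(2),
        weights=np.full(k, 1.0 / k),
        responsibilities=np.full((k * 20, k), 1.0 / k),
        labels=np.zeros(k * 20, int),
        log_likelihood=0.0,
        ll_trajectory=np.array([0.0]),
        best_replicate=0,
        n_iter=1,
    )


class TestOutlierRemoval:
    def test_extreme_point_removed(self, rng):
        pts = rng.normal([0.4, 0.6], 0.05, size=(200, 2))
        pts[0] = [40.0, 0.6]
        out = remove_outliers(_sample(pts, shape=(30, 30, 30)))
        assert out.n_points == 199
        assert (out.points[:, 0] < 10).all()

    def test_clean_gaussian_loses_at_most_two_percent(self, rng):
        pts = rng.normal([0.4, 0.6], 0.08, size=(1000, 2))
        out = remove_outliers(_sample(pts, shape=(30, 30, 30)))
        assert out.n_points >= 980

    def test_pathological_sample_errors(self):
        pts = np.vstack([np.full((10, 2), 0.5),
                         np.random.default_rng(1).uniform(50, 60, (20, 2))])
        with pytest.raises(ValueError, match="pathological"):
            remove_outliers(_sample(pts))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 30"):
            remove_outliers(_sample(np.full((10, 2), 0.5)))


class TestFit:
    def test_single_component_closed_form(self, rng):
        x = rng.normal([0.5, 0.8], [0.1, 0.2], size=(500, 2))
        fit = fit_gmm(x, k=1, seed=0)
        np.testing.assert_allclose(fit.means[0], x.mean(axis=0), atol=1e-8)
        np.testing.assert_allclose(
            fit.covariance, np.cov(x.T, bias=True), atol=1e-6
        )
        assert fit.weights[0] == pytest.approx(1.0)

    def test_two_component_recovery(self, rng):
        truth = np.array([[0.35, 0.60], [0.16, 0.46]])
        x = np.vstack([
            rng.multivariate_normal(truth[0], 0.01 * np.eye(2), 1000),
            rng.multivariate_normal(truth[1], 0.01 * np.eye(2), 1000),
        ])
        fit = fit_gmm(x, k=2, seed=0)
        err = min(
            np.linalg.norm(fit.means - truth, axis=1).max(),
            np.linalg.norm(fit.means[::-1] - truth, axis=1).max(),
        )
        assert err <= 0.05

    def test_determinism(self, rng):
        x = rng.uniform(0, 1, size=(300, 2))
        a = fit_gmm(x, k=3, seed=42)
        b = fit_gmm(x, k=3, seed=42)
        np.testing.assert_array_equal(a.means, b.means)
        assert a.log_likelihood == b.log_likelihood

    def test_log_likelihood_monotone(self, rng):
        x = rng.uniform(0, 1, size=(400, 2))
        fit = fit_gmm(x, k=4, seed=1)
        assert (np.diff(fit.ll_trajectory) >= -1e-6 * abs(fit.log_likelihood)).all()

    def test_matches_sklearn_tied_covariance(self, rng):
        from sklearn.mixture import GaussianMixture

        truth = np.array([[0.3, 0.4], [0.3, 1.2]])
        x = np.vstack([
            rng.multivariate_normal(truth[0], 0.005 * np.eye(2), 800),
            rng.multivariate_normal(truth[1], 0.005 * np.eye(2), 800),
        ])
        mine = fit_gmm(x, k=2, seed=0)
        ref = GaussianMixture(
            n_components=2, covariance_type="tied", n_init=5, random_state=0
        ).fit(x)
        order = np.argsort(mine.means[:, 1])
        ref_order = np.argsort(ref.means_[:, 1])
        np.testing.assert_allclose(
            mine.means[order], ref.means_[ref_order], atol=0.02
        )
        np.testing.assert_allclose(mine.covariance, ref.covariances_, atol=0.005)
        # mean per-point log-likelihood agrees
        assert mine.log_likelihood / len(x) == pytest.approx(
            ref.score(x), abs=0.01
        )

    def test_sample_size_contract(self, rng):
        with pytest.raises(ValueError, match="points"):
            fit_gmm(rng.uniform(0, 1, (25, 2)), k=3)


class TestSelectK:
    def test_two_separated_clusters(self, rng):
        x = np.vstack([
            rng.normal([0.3, 0.5], 0.05, (800, 2)),
            rng.normal([0.3, 1.0], 0.05, (800, 2)),
        ])
        k, _, scores = select_k(x, seed=0)
        assert k == 2

    def test_single_cloud_selects_one(self, rng):
        x = rng.normal([0.5, 0.7], 0.1, size=(1200, 2))
        k, fit, scores = select_k(x, seed=0)
        assert k == 1
        assert all(s < 0.5 for s in scores.values())

    def test_three_clusters(self, rng):
        x = np.vstack([
            rng.normal([0.2, 0.3], 0.04, (600, 2)),
            rng.normal([0.6, 0.5], 0.04, (600, 2)),
            rng.normal([0.4, 1.1], 0.04, (600, 2)),
        ])
        k, _, scores = select_k(x, seed=0)
        assert k == 3
        assert scores[3] > scores[2]


class TestMatching:
    def test_identical_centroids_distance_zero(self):
        fits = {"a": _fake_fit([[0.3, 0.5]]), "b": _fake_fit([[0.3, 0.5]])}
        match = match_partitions(fits)
        assert set(match.table["class"]) == {"C1"}
        assert (match.table["distance"] == 0).all()

    def test_jittered_cohort_fully_recovered(self, rng):
        truth = np.array([[0.34, 0.63], [0.41, 1.11]])
        fits = {
            f"s{i}": _fake_fit(truth + rng.normal(0, 0.03, truth.shape))
            for i in range(10)
        }
        match = match_partitions(fits)
        assert len(match.class_names) == 2
        # component j of every subject lands in the same class, no cross-talk
        for j in range(2):
            classes = {
                match.assignment_for(f"s{i}")[j] for i in range(10)
            }
            assert len(classes) == 1
        assert "excluded" not in set(match.table["class"])

    def test_far_component_excluded(self, rng):
        truth = np.array([[0.34, 0.63], [0.41, 1.11]])
        fits = {
            f"s{i}": _fake_fit(truth + rng.normal(0, 0.02, truth.shape))
            for i in range(6)
        }
        fits["s0"] = _fake_fit(
            np.vstack([fits["s0"].means, [1.9, 1.9]])
        )
        match = match_partitions(fits)
        assert match.assignment_for("s0")[2] == "excluded"
        assert len(match.class_names) == 2

    def test_subject_permutation_invariance(self, rng):
        truth = np.array([[0.3, 0.4], [0.5, 0.9], [0.2, 1.2]])
        cents = {i: truth + rng.normal(0, 0.02, truth.shape) for i in range(5)}
        fits_a = {f"s{i}": _fake_fit(cents[i]) for i in range(5)}
        fits_b = {f"s{4 - i}": _fake_fit(cents[4 - i]) for i in range(5)}

        def partition(match):
            out = {}
            for r in match.table.itertuples(index=False):
                out.setdefault(r[2], set()).add((r[0], r[1]))
            return {frozenset(v) for v in out.values()}

        assert partition(match_partitions(fits_a)) == partition(match_partitions(fits_b))

    def test_canonical_order_by_prevalence(self, rng):
        common = [0.3, 0.5]
        rare = [0.9, 1.4]
        fits = {f"s{i}": _fake_fit([common]) for i in range(6)}
        fits["s0"] = _fake_fit([common, rare])
        fits["s1"] = _fake_fit([common, rare])
        match = match_partitions(fits)
        members = match.table.groupby("class")["subject"].count()
        assert members["C1"] == 6 and members["C2"] == 2

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError, match="2 subjects"):
            match_partitions({"a": _fake_fit([[0.3, 0.5]])})


class TestToSubregions:
    def test_bookkeeping(self, rng):
        pts = np.vstack([
            rng.normal([0.3, 0.5], 0.03, (100, 2)),
            rng.normal([0.7, 1.1], 0.03, (100, 2)),
        ])
        sample = _sample(pts)
        fit = fit_gmm(sample, k=2, seed=0)
        tumour = MaskVolume(data=sample.back_project((20, 20, 20)))
        low = int(np.argmin(fit.means[:, 0]))
        assignment = {low: "C1", 1 - low: "excluded"}
        subs = to_subregions(fit, sample, assignment, ("C1", "C2"), tumour)
        assert subs.presence == {"C1": True, "C2": False}
        assert subs.occupancy["C1"] == pytest.approx(50.0, abs=2.0)
        assert sum(subs.occupancy.values()) <= 100.0 + 1e-9
        # excluded component's voxels carry no label
        assert (subs.label_volume > 0).sum() == (fit.labels == low).sum()


def test_prevalence_arithmetic_exact():
    presence = {
        "C1": [True] * 14 + [False] * 2,
        "C3": [True] * 5 + [False] * 11,
        "C5": [True] * 2 + [False] * 14,
    }
    prev = prevalence_percentages(presence)
    assert prev == {"C1": 87.5, "C3": 31.25, "C5": 12.5}
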