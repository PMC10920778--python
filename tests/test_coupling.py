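import numpy as np
import pandas as pd
import pytest

from gliohab.coupling import (
    CouplingEstimate,
    band_filter,
    compare_coupling,
    coupling_beta,
    global_signal,
    per_voxel_beta,
    scrub_frames,
    zero_nonsignificant,
)
from gliohab.grids import MaskVolume, VolumeGrid

TR = 1.06


def _bl_noise(rng, n=300, sd=1.0):
    ts = band_filter(rng.standard_normal(n), tr=TR)
    return sd * ts / ts.std()


class TestGlobalSignal:
    def _volumes(self, rng, t=80):
        shape = (6, 6, 6)
        bold = VolumeGrid(data=rng.standard_normal(shape + (t,)))
        gm = MaskVolume(data=np.ones(shape, bool))
        tum = np.zeros(shape, bool)
        tum[:2] = True
        return bold, gm, MaskVolume(data=tum)

    def test_constant_bold_gives_constant_gs(self, rng):
        bold, gm, tum = self._volumes(rng)
        bold.data[:] = 3.5
        gs = global_signal(bold, gm, tum)
        np.testing.assert_allclose(gs, 3.5)

    def test_gm_equals_tumour_errors(self, rng):
        bold, gm, _ = self._volumes(rng)
        with pytest.raises(ValueError, match="healthy"):
            global_signal(bold, gm, gm)

    def test_exclusion_mask_respected(self, rng):
        bold, gm, tum = self._volumes(rng)
        extra = np.zeros(gm.shape, bool)
        extra[2:4] = True
        gs_all = global_signal(bold, gm, tum)
        gs_excl = global_signal(bold, gm, tum, also_exclude=MaskVolume(data=extra))
        keep = gm.data & ~tum.data & ~extra
        np.testing.assert_allclose(gs_excl, bold.data[keep].mean(axis=0))
        assert not np.allclose(gs_all, gs_excl)

    def test_recovers_planted_generator_gs(self, small_cohort):
        s = small_cohort.subjects[0]
        gs = global_signal(s.bold, s.gm_mask, s.tumour_mask)
        gs = band_filter(gs, tr=small_cohort.spec.tr)
        r = np.corrcoef(gs, s.truth.gs)[0, 1]
        assert r > 0.99


class TestBandFilter:
    def test_out_of_band_sinusoid_suppressed(self):
        t = np.arange(300) * TR
        ts = np.sin(2 * np.pi * 0.25 * t)
        out = band_filter(ts, tr=TR)
        assert out.std() <= 0.1 * ts.std()          # RMS amplitude
        assert np.abs(out[30:-30]).max() <= 0.05    # settled response

    def test_in_band_sinusoid_retained(self):
        t = np.arange(300) * TR
        ts = np.sin(2 * np.pi * 0.06 * t)
        out = band_filter(ts, tr=TR)
        assert out.std() >= 0.9 * ts.std()

    def test_linearity_zero_maps_to_zero(self):
        np.testing.assert_allclose(band_filter(np.zeros(100), tr=TR), 0.0)

    def test_infeasible_band_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            band_filter(np.zeros(100), tr=30.0, low=0.03, high=0.12)


class TestScrub:
    def test_no_motion_retains_all(self):
        retained, flagged = scrub_frames(np.zeros(100))
        assert len(retained) == 100 and not flagged

    def test_threshold_drops_frame(self):
        retained, flagged = scrub_frames(np.array([0.1, 0.9, 0.1]))
        assert retained.tolist() == [0, 2] and not flagged

    def test_excess_motion_flags_subject(self):
        fd = np.array([0.9] * 60 + [0.1] * 40)
        _, flagged = scrub_frames(fd)
        assert flagged


class TestCouplingBeta:
    def test_identity_series(self, rng):
        gs = _bl_noise(rng)
        est = coupling_beta(gs, gs)
        assert est.beta == pytest.approx(1.0)
        assert est.p == 0.0

    def test_affine_series_under_both_conventions(self, rng):
        gs = _bl_noise(rng)
        reg = 2 * gs + 3
        assert coupling_beta(reg, gs).beta == pytest.approx(1.0)
        assert coupling_beta(reg, gs, standardized=False).beta == pytest.approx(2.0)

    def test_recovery_of_planted_slope(self, rng):
        betas = []
        for _ in range(200):
            gs = _bl_noise(rng)
            reg = 0.5 * gs + _bl_noise(rng, sd=0.3) + rng.normal(0, 0.1, 300)
            betas.append(coupling_beta(reg, gs, standardized=False).beta)
        mean = np.mean(betas)
        se = np.std(betas, ddof=1) / np.sqrt(len(betas))
        assert abs(mean - 0.5) <= 2 * se

    def test_short_series_rejected(self, rng):
        with pytest.raises(ValueError, match="frames"):
            coupling_beta(np.ones(30), np.ones(30))

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError, match="variance"):
            coupling_beta(np.ones(100), _bl_noise(rng, 100))


class TestPerVoxelBeta:
    def test_all_voxels_equal_gs(self, rng):
        shape = (5, 5, 5)
        gs = _bl_noise(rng, 100)
        tum = np.zeros(shape, bool)
        tum[1:3] = True
        data = np.zeros(shape + (100,))
        data[tum] = gs
        bmap = per_voxel_beta(VolumeGrid(data=data), MaskVolume(data=tum), gs)
        np.testing.assert_allclose(bmap.data[tum], 1.0, atol=1e-10)
        np.testing.assert_allclose(bmap.data[~tum], 0.0)

    def test_subregion_mean_matches_regionwise_beta(self, rng):
        # homogeneous voxel noise: mean per-voxel slope ~ region-level slope
        shape = (4, 4, 4)
        t = 300
        gs = _bl_noise(rng, t)
        tum = np.ones(shape, bool)
        data = 0.5 * gs + rng.normal(0, 0.2, size=shape + (t,))
        bmap = per_voxel_beta(VolumeGrid(data=data), MaskVolume(data=tum), gs,
                              standardized=False)
        region = coupling_beta(data[tum].mean(axis=0), gs, standardized=False)
        n = tum.sum()
        se = bmap.data[tum].std(ddof=1) / np.sqrt(n)
        assert abs(bmap.data[tum].mean() - region.beta) <= 2 * se + 1e-6


class TestZeroing:
    def test_significant_estimate_unchanged(self):
        est = [CouplingEstimate(region="a", beta=0.8, p=0.001)]
        out = zero_nonsignificant(est)
        assert out[0].beta == 0.8 and not out[0].zeroed

    def test_nonsignificant_zeroed_with_provenance(self):
        est = [CouplingEstimate(region="a", beta=0.4, p=0.9)]
        out = zero_nonsignificant(est)
        assert out[0].beta == 0.0 and out[0].zeroed
        assert out[0].raw_beta == 0.4

    def test_zeroing_never_increases_magnitude(self, rng):
        ests = [CouplingEstimate(region=str(i), beta=rng.normal(),
                                 p=rng.uniform())
                for i in range(50)]
        raw = [e.beta for e in ests]
        out = zero_nonsignificant(ests)
        assert all(abs(e.beta) <= abs(r) for e, r in zip(out, raw))


class TestCompareCoupling:
    def test_identical_conditions_give_zero_chi2(self):
        table = pd.DataFrame({c: np.arange(8.0) for c in "abc"})
        rep = compare_coupling(table)
        assert rep.chi2 == 0.0
        assert (rep.posthoc["p"] == 1.0).all()

    def test_planted_ordering_detected(self, rng):
        n = 16
        base = rng.normal(0, 1.0, (n, 5))
        means = np.array([0.0, 0.0, 1.0, 1.0, 2.0])
        table = pd.DataFrame(base + means,
                             columns=["I", "II", "III", "IV", "contralateral"])
        rep = compare_coupling(table)
        assert rep.p < 0.01
        assert rep.df == 4

    def test_incomplete_rows_name_subjects(self):
        table = pd.DataFrame({"a": [1.0, np.nan], "b": [1.0, 2.0],
                              "c": [0.5, 0.1]}, index=["s0", "s1"])
        with pytest.raises(ValueError, match="s1"):
            compare_coupling(table)

    def test_two_condition_case_matches_sign_test(self, rng):
        # with two conditions the Wilcoxon reduces to a paired location
        # test; on an exhaustive small instance its decision agrees in
        # direction with the sign pattern
        diff = np.array([0.5, 0.4, 0.6, 0.3, 0.45, 0.55, 0.35, 0.5])
        from scipy import stats

        res = stats.wilcoxon(diff, method="approx")
        assert res.pvalue < 0.05  # all signs positive: strongest evidence
        res2 = stats.wilcoxon(diff * np.array([1, -1] * 4), method="approx")
        assert res2.pvalue > res.pvalue
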