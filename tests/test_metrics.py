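import numpy as np
import pytest
from scipy import stats

from ctvi.metrics import (
    FunctionalRegions,
    VoxelSeries,
    dsc,
    evaluate_case,
    functional_regions,
    low_attenuation_mask,
    matched_volume_low_region,
    mse_masked,
    non_defect_fraction,
    region_mean_cv,
    spearman_rs,
    summarize_cohort,
)
from ctvi.volumes import VolumeGrid


def grid(data):
    return VolumeGrid(data=np.asarray(data, dtype=float))


def full_mask(shape):
    return VolumeGrid(data=np.ones(shape, dtype=np.uint8))


class TestSpearman:
    def test_perfect_agreement(self, rng):
        y = rng.permutation(20).astype(float)
        assert spearman_rs(VoxelSeries(y, y * 3 + 1)) == pytest.approx(1.0)

    def test_perfect_reversal(self, rng):
        y = rng.permutation(20).astype(float)
        assert spearman_rs(VoxelSeries(y, -y)) == pytest.approx(-1.0)

    def test_hand_example(self):
        y = np.array([1, 2, 3, 4, 5], dtype=float)
        p = np.array([2, 1, 3, 5, 4], dtype=float)
        # rank-difference closed form: 1 - 6·Σd²/(n(n²-1)), Σd² = 4
        assert spearman_rs(VoxelSeries(y, p)) == pytest.approx(1 - 6 * 4 / (5 * 24))

    def test_matches_scipy_with_ties(self, rng):
        y = rng.integers(0, 5, size=200).astype(float)
        p = y + rng.normal(0, 1, size=200)
        ours = spearman_rs(VoxelSeries(y, p))
        ref = stats.spearmanr(y, p).statistic
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rs(VoxelSeries(np.ones(5), np.arange(5.0)))


class TestDSC:
    def test_identical_nonempty(self):
        a = grid([[[1, 0], [1, 1]], [[0, 0], [1, 0]]])
        assert dsc(a, a) == 1.0

    def test_disjoint(self):
        a = grid(np.eye(2)[None].repeat(2, 0))
        b = grid(1 - np.eye(2)[None].repeat(2, 0))
        assert dsc(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((2, 2, 2)); a.ravel()[:4] = 1
        b = np.zeros((2, 2, 2)); b.ravel()[2:6] = 1
        assert dsc(grid(a), grid(b)) == 0.5

    def test_symmetry(self, rng):
        a = (rng.random((4, 4, 4)) > 0.5).astype(float)
        b = (rng.random((4, 4, 4)) > 0.5).astype(float)
        assert dsc(grid(a), grid(b)) == dsc(grid(b), grid(a))

    def test_both_empty_rejected(self):
        z = grid(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError, match="empty"):
            dsc(z, z)


class TestFunctionalRegions:
    def test_exact_tertiles_of_nine(self):
        vol = grid(np.arange(1.0, 10.0).reshape(3, 3, 1))
        regions = functional_regions(vol, full_mask((3, 3, 1)))
        assert set(vol.data[regions.low.data == 1]) == {1, 2, 3}
        assert set(vol.data[regions.moderate.data == 1]) == {4, 5, 6}
        assert set(vol.data[regions.high.data == 1]) == {7, 8, 9}

    def test_partition_always_holds(self, rng):
        vol = grid(rng.random((10, 10, 10)))
        mask = VolumeGrid(data=(rng.random((10, 10, 10)) > 0.4).astype(np.uint8))
        regions = functional_regions(vol, mask)
        total = regions.high.data + regions.moderate.data + regions.low.data
        assert np.array_equal(total, mask.data)

    def test_all_tied_rejected(self):
        vol = grid(np.ones((3, 3, 3)))
        with pytest.raises(ValueError, match="tied"):
            functional_regions(vol, full_mask((3, 3, 3)))

    def test_near_equal_thirds(self, rng):
        vals = rng.permutation(3000) / 3000.0
        vol = grid(np.r_[vals, np.zeros(375)].reshape(15, 15, 15))
        mask = VolumeGrid(data=(np.arange(3375) < 3000).astype(np.uint8).reshape(15, 15, 15))
        regions = functional_regions(vol, mask)
        for r in (regions.low, regions.moderate, regions.high):
            assert abs(int(r.data.sum()) - 1000) <= 1


class TestMSE:
    def test_identical_is_zero(self, rng):
        y = rng.random(50)
        assert mse_masked(VoxelSeries(y, y)) == 0.0

    def test_constant_offset(self, rng):
        y = rng.random(50)
        assert mse_masked(VoxelSeries(y, y + 0.3)) == pytest.approx(0.09)

    def test_affine_invariance_of_rank_metrics_not_mse(self, rng):
        y = rng.random(100)
        p = rng.random(100)
        s0 = spearman_rs(VoxelSeries(y, p))
        s1 = spearman_rs(VoxelSeries(2 * y + 1, 2 * p + 1))
        assert s0 == pytest.approx(s1, abs=1e-12)
        assert mse_masked(VoxelSeries(2 * y + 1, 2 * p + 1)) != pytest.approx(
            mse_masked(VoxelSeries(y, p))
        )


class TestNonDefectFraction:
    def test_uniform_positive_is_100(self):
        vol = grid(np.full((3, 3, 3), 2.0))
        assert non_defect_fraction(vol, full_mask((3, 3, 3))) == 100.0

    def test_half_zero_half_positive(self):
        data = np.zeros((2, 2, 2)); data.ravel()[:4] = 5.0
        assert non_defect_fraction(grid(data), full_mask((2, 2, 2))) == 50.0


class TestLowAttenuation:
    def test_healthy_parenchyma_empty(self):
        ct = grid(np.full((3, 3, 3), -820.0))
        assert low_attenuation_mask(ct, full_mask((3, 3, 3))).data.sum() == 0

    def test_single_emphysematous_voxel(self):
        data = np.full((3, 3, 3), -820.0); data[1, 1, 1] = -900.0
        out = low_attenuation_mask(grid(data), full_mask((3, 3, 3)))
        assert out.data.sum() == 1 and out.data[1, 1, 1] == 1

    def test_subset_of_phantom_defects(self, phantom_triplet):
        ct, _, mask, _ = phantom_triplet
        laa = low_attenuation_mask(ct, mask)
        assert np.all(mask.data[laa.data == 1] == 1)


class TestMatchedVolumeLowRegion:
    def test_whole_lung(self, rng):
        vol = grid(rng.random((4, 4, 4)))
        mask = full_mask((4, 4, 4))
        out = matched_volume_low_region(vol, mask, 64)
        assert np.all(out.data == 1)

    def test_lowest_three_of_nine(self):
        vol = grid(np.arange(1.0, 10.0).reshape(3, 3, 1))
        out = matched_volume_low_region(vol, full_mask((3, 3, 1)), 3)
        assert set(vol.data[out.data == 1]) == {1, 2, 3}

    def test_matches_sort_oracle(self, rng):
        vol = grid(rng.random((6, 6, 6)))
        mask = VolumeGrid(data=(rng.random((6, 6, 6)) > 0.3).astype(np.uint8))
        n = 20
        out = matched_volume_low_region(vol, mask, n)
        assert int(out.data.sum()) == n
        inside_vals = vol.data[mask.data == 1]
        cutoff = np.sort(inside_vals)[n - 1]
        assert vol.data[out.data == 1].max() <= cutoff

    def test_out_of_range_rejected(self):
        vol = grid(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            matched_volume_low_region(vol, full_mask((2, 2, 2)), 9)


class TestRegionMeanCV:
    @pytest.fixture
    def regions(self, rng):
        vol = grid(rng.random((6, 6, 6)))
        return functional_regions(vol, full_mask((6, 6, 6)))

    def test_constant_map(self, regions):
        cv = grid(np.full((6, 6, 6), 0.27))
        out = region_mean_cv(cv, regions)
        assert out == {"high": pytest.approx(0.27), "moderate": pytest.approx(0.27),
                       "low": pytest.approx(0.27)}

    def test_matches_masked_mean_oracle(self, rng, regions):
        cv = grid(rng.random((6, 6, 6)) + 0.05)
        out = region_mean_cv(cv, regions)
        for name, region in regions.as_dict().items():
            assert out[name] == pytest.approx(cv.data[region.data == 1].mean())

    def test_guard_zeros_excluded(self, regions):
        data = np.full((6, 6, 6), 0.5)
        data[0, 0, 0] = 0.0  # guard-zeroed voxel
        out = region_mean_cv(grid(data), regions)
        assert all(v == pytest.approx(0.5) for v in out.values())


class TestEvaluateCase:
    def test_self_comparison_is_perfect(self, rng):
        data = rng.random((8, 8, 8)) + 0.1
        mask = VolumeGrid(data=(rng.random((8, 8, 8)) > 0.3).astype(np.uint8))
        vol = grid(data * mask.data)
        m = evaluate_case(vol, vol, mask, case_id="self")
        assert m.spearman_rs == pytest.approx(1.0)
        assert m.dsc_high == m.dsc_moderate == m.dsc_low == 1.0
        assert m.mse == 0.0

    def test_shuffled_prediction_near_chance(self, rng):
        """A spatially shuffled prediction has r_s ≈ 0 and region DSC ≈ 1/3."""
        rs_vals, dsc_vals = [], []
        mask = full_mask((12, 12, 12))
        for _ in range(5):
            ref = grid(rng.random((12, 12, 12)) + 0.1)
            pred = grid(rng.permutation(ref.data.ravel()).reshape(12, 12, 12))
            m = evaluate_case(pred, ref, mask)
            rs_vals.append(m.spearman_rs)
            dsc_vals += [m.dsc_high, m.dsc_moderate, m.dsc_low]
        assert abs(np.mean(rs_vals)) < 0.1
        assert np.mean(dsc_vals) == pytest.approx(1 / 3, abs=0.05)

    def test_phantom_metrics_match_per_metric_oracles(self, phantom_triplet, rng):
        from ctvi.preprocess import normalize_spect

        ct, vent, mask, truth = phantom_triplet
        ref = normalize_spect(truth, mask)
        pred = normalize_spect(vent, mask)
        m = evaluate_case(pred, ref, mask, ct_hu=ct, case_id="ph")
        inside = mask.data == 1
        assert m.spearman_rs == pytest.approx(
            stats.spearmanr(ref.data[inside], pred.data[inside]).statistic, abs=1e-12
        )
        assert m.mse == pytest.approx(np.mean((pred.data[inside] - ref.data[inside]) ** 2))
        rr = functional_regions(ref, mask)
        rp = functional_regions(pred, mask)
        assert m.dsc_low == pytest.approx(dsc(rp.low, rr.low))
        assert 0 < m.non_defect_pct < 100
        assert "laa_dsc_pred" in m.extras


class TestSummarizeCohort:
    def test_mean_sd_rows_appended(self, rng):
        mask = full_mask((6, 6, 6))
        ms = []
        for i in range(3):
            ref = grid(rng.random((6, 6, 6)) + 0.1)
            pred = grid(ref.data + rng.normal(0, 0.05, ref.shape))
            ms.append(evaluate_case(pred, ref, mask, case_id=f"c{i}"))
        df = summarize_cohort(ms)
        assert list(df["case_id"].iloc[-2:]) == ["mean", "sd"]
        rs = [m.spearman_rs for m in ms]
        assert df["spearman_rs"].iloc[-2] == pytest.approx(np.mean(rs))
        assert df["spearman_rs"].iloc[-1] == pytest.approx(np.std(rs, ddof=1))
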