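import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctvi.preprocess import (
    PreprocessConfig,
    crop_or_pad,
    mask_centroid,
    normalize_spect,
    preprocess_case,
    resample,
    rescale_ct,
    spect_lung_mask,
)
from ctvi.volumes import VolumeGrid


class TestRescaleCT:
    """Linear HU rescale anchored at −999 HU → 0 and −250 HU → 1."""

    @pytest.mark.parametrize(
        "hu,expected",
        [(-999.0, 0.0), (-250.0, 1.0), (-624.5, 0.5), (-1050.0, 0.0)],
    )
    def test_anchor_points(self, hu, expected):
        vol = VolumeGrid(data=np.full((2, 2, 2), hu))
        out = rescale_ct(vol)
        assert out.data == pytest.approx(expected, abs=1e-12)

    def test_values_above_upper_anchor_not_clipped(self):
        vol = VolumeGrid(data=np.full((2, 2, 2), 0.0))  # water
        out = rescale_ct(vol)
        assert np.all(out.data > 1.0)

    @given(st.floats(min_value=-1200, max_value=200), st.floats(min_value=0.1, max_value=300))
    @settings(max_examples=50, deadline=None)
    def test_monotone_non_decreasing(self, hu, delta):
        lo = rescale_ct(VolumeGrid(data=np.full((1, 1, 1), hu))).data
        hi = rescale_ct(VolumeGrid(data=np.full((1, 1, 1), hu + delta))).data
        assert hi >= lo

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            PreprocessConfig(ct_hu_lo=-100, ct_hu_hi=-999)


class TestNormalizeSpect:
    def test_median_three_values(self):
        vent = VolumeGrid(data=np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1))
        mask = VolumeGrid(data=np.ones((3, 1, 1), dtype=np.uint8))
        out = normalize_spect(vent, mask)
        assert np.allclose(out.data.ravel(), [0.5, 1.0, 1.5])

    def test_constant_becomes_ones(self):
        vent = VolumeGrid(data=np.full((4, 4, 4), 7.3))
        mask = VolumeGrid(data=np.ones((4, 4, 4), dtype=np.uint8))
        assert np.allclose(normalize_spect(vent, mask).data, 1.0)

    def test_in_mask_median_is_one(self, rng):
        for _ in range(10):
            vent = VolumeGrid(data=rng.random((6, 6, 6)) + 0.2)
            mask = VolumeGrid(data=(rng.random((6, 6, 6)) > 0.3).astype(np.uint8))
            out = normalize_spect(vent, mask)
            assert np.median(out.data[mask.data == 1]) == pytest.approx(1.0, abs=1e-12)

    def test_empty_mask_rejected(self):
        vent = VolumeGrid(data=np.ones((2, 2, 2)))
        mask = VolumeGrid(data=np.zeros((2, 2, 2), dtype=np.uint8))
        with pytest.raises(ValueError, match="empty"):
            normalize_spect(vent, mask)

    def test_nonpositive_median_rejected(self):
        vent = VolumeGrid(data=np.zeros((2, 2, 2)))
        mask = VolumeGrid(data=np.ones((2, 2, 2), dtype=np.uint8))
        with pytest.raises(ValueError, match="median"):
            normalize_spect(vent, mask)

    def test_mask_normalize_order_invariance(self, rng):
        """Masking after normalization equals normalizing the masked volume."""
        from ctvi.volumes import apply_mask

        vent = VolumeGrid(data=rng.random((6, 6, 6)) + 0.2)
        mask = VolumeGrid(data=(rng.random((6, 6, 6)) > 0.3).astype(np.uint8))
        a = apply_mask(normalize_spect(vent, mask), mask)
        b = normalize_spect(apply_mask(vent, mask), mask)
        assert np.allclose(a.data, b.data)


class TestResample:
    def test_constant_preserved(self):
        vol = VolumeGrid(data=np.full((8, 8, 8), 3.7), spacing=(1.0, 1.0, 1.0))
        out = resample(vol, 2.0)
        assert out.data == pytest.approx(3.7)
        assert out.shape == (4, 4, 4)

    def test_shape_arithmetic(self):
        vol = VolumeGrid(data=np.zeros((8, 8, 8)), spacing=(1.0, 1.0, 1.0))
        assert resample(vol, 2.0).shape == (4, 4, 4)
        assert resample(vol, 0.5).shape == (16, 16, 16)

    def test_nearest_preserves_binarity(self, rng):
        mask = VolumeGrid(
            data=(rng.random((20, 20, 20)) > 0.5).astype(np.uint8),
            spacing=(0.977, 0.977, 0.977),
        )
        out = resample(mask, 2.5, mode="nearest")
        assert set(np.unique(out.data)) <= {0, 1}

    def test_rejects_non_positive_spacing(self):
        vol = VolumeGrid(data=np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            resample(vol, -1.0)


class TestCropOrPad:
    def test_identity(self, random_grid):
        vol = random_grid((4, 4, 4))
        out = crop_or_pad(vol, (4, 4, 4))
        assert np.array_equal(out.data, vol.data)

    def test_pure_padding_counts(self):
        vol = VolumeGrid(data=np.ones((2, 2, 2)))
        out = crop_or_pad(vol, (4, 4, 4))
        assert out.shape == (4, 4, 4)
        assert out.data.sum() == 8
        assert (out.data == 0).sum() == 56

    def test_centroid_crop_keeps_whole_lung(self, rng):
        mask = np.zeros((50, 50, 50), dtype=np.uint8)
        # lung blob inside a 24³ bounding box at an off-center position
        mask[5:25, 20:44, 9:30] = (rng.random((20, 24, 21)) > 0.3).astype(np.uint8)
        grid = VolumeGrid(data=mask)
        out = crop_or_pad(grid, (24, 24, 24), center=mask_centroid(grid), lung_mask=grid)
        assert int(out.data.sum()) == int(mask.sum())

    def test_truncation_warns(self):
        mask = np.ones((10, 10, 10), dtype=np.uint8)
        grid = VolumeGrid(data=mask)
        with pytest.warns(UserWarning, match="truncates"):
            out = crop_or_pad(grid, (4, 4, 4), lung_mask=grid)
        assert out.shape == (4, 4, 4)

    def test_centroid_tie_breaks_toward_lower_index(self):
        mask = np.zeros((4, 4, 4), dtype=np.uint8)
        mask[1:3, 1:3, 1:3] = 1  # centroid exactly at 1.5
        assert mask_centroid(VolumeGrid(data=mask)) == (1, 1, 1)


class TestSpectLungMask:
    def test_direct_threshold(self):
        vent = VolumeGrid(data=np.array([0.0, 10.0, 100.0]).reshape(3, 1, 1))
        out = spect_lung_mask(vent)
        assert list(out.data.ravel()) == [0, 0, 1]

    def test_uniform_positive_all_ones(self):
        vent = VolumeGrid(data=np.full((3, 3, 3), 5.0))
        assert np.all(spect_lung_mask(vent).data == 1)

    def test_matches_bruteforce_oracle(self, rng):
        data = rng.exponential(scale=2.0, size=(10, 10, 10))
        vent = VolumeGrid(data=data)
        out = spect_lung_mask(vent)
        oracle = np.zeros_like(data, dtype=np.uint8)
        thr = 0.15 * data.max()
        for idx in np.ndindex(data.shape):
            oracle[idx] = 1 if data[idx] >= thr else 0
        assert np.array_equal(out.data, oracle)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            spect_lung_mask(VolumeGrid(data=np.zeros((2, 2, 2))))


class TestPreprocessCase:
    def test_phantom_case_satisfies_invariants(self, phantom_triplet):
        ct, vent, mask, _ = phantom_triplet
        cfg = PreprocessConfig(target_spacing=ct.spacing, target_shape=(32, 32, 32))
        case = preprocess_case(ct, vent, mask, cfg, case_id="p0")
        assert case.ct.shape == cfg.target_shape
        assert case.ct.spacing == cfg.target_spacing
        assert case.lung_mask.is_binary()
        case.validate_masked()
        inside = case.lung_mask.data == 1
        assert np.median(case.ventilation.data[inside]) == pytest.approx(1.0, abs=1e-12)

    def test_inference_only_path(self, phantom_triplet):
        ct, _, mask, _ = phantom_triplet
        cfg = PreprocessConfig(target_spacing=ct.spacing, target_shape=(32, 32, 32))
        case = preprocess_case(ct, None, mask, cfg, case_id="p1")
        assert case.ventilation is None
        case.validate_masked()

    def test_grids_share_target_geometry(self, phantom_triplet):
        ct, vent, mask, _ = phantom_triplet
        cfg = PreprocessConfig(target_spacing=(5.0, 5.0, 5.0), target_shape=(16, 16, 16))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            case = preprocess_case(ct, vent, mask, cfg)
        for vol in (case.ct, case.ventilation, case.lung_mask):
            assert vol.shape == (16, 16, 16)
            assert vol.spacing == (5.0, 5.0, 5.0)
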