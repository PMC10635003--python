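"""Slice selection, context tiling, foreground-guaranteed crops, augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vemseg.sampling import (
    CropBatch,
    SamplerConfig,
    augment,
    dihedral,
    downsample_labels,
    extract_context_tile,
    sample_crops,
    sample_training_batch,
    select_labeled_slices,
)


class TestSelectLabeledSlices:
    @pytest.mark.parametrize(
        "n_train,n_slices,expected",
        [
            (1, 10, [5]),
            (7, 757, [54, 162, 270, 378, 486, 594, 702]),
            (4, 4, [0, 1, 2, 3]),
            (2, 10, [2, 7]),
        ],
    )
    def test_centered_convention_examples(self, n_train, n_slices, expected):
        assert select_labeled_slices(n_train, n_slices).tolist() == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            select_labeled_slices(11, 10)
        with pytest.raises(ValueError):
            select_labeled_slices(0, 10)

    @given(
        n_slices=st.integers(1, 2000),
        frac=st.floats(0.001, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_gaps_differ_by_at_most_one(self, n_slices, frac):
        n_train = max(1, min(n_slices, int(round(frac * n_slices))))
        idx = select_labeled_slices(n_train, n_slices)
        assert len(idx) == n_train
        assert (np.diff(idx) > 0).all()
        assert idx[0] >= 0 and idx[-1] < n_slices
        # consecutive inter-pick gaps are balanced (floor/ceil of the ideal
        # spacing), and the volume ends sit about half a gap from the
        # outermost picks — the centered-quantile layout
        gaps = np.diff(idx)
        if len(gaps):
            assert gaps.max() - gaps.min() <= 1
            half = gaps.max() // 2 + 1
        else:
            half = n_slices // 2 + 1
        assert idx[0] <= half
        assert (n_slices - 1 - idx[-1]) <= half

    def test_endpoint_convention_includes_ends(self):
        idx = select_labeled_slices(5, 100, spacing="endpoint")
        assert idx[0] == 0 and idx[-1] == 99


class TestContextTile:
    def test_constant_image_gives_constant_tile(self):
        cfg = SamplerConfig(context_size=32, out_size=8)
        img = np.full((64, 64), 0.7, dtype=np.float32)
        tile = extract_context_tile(img, 10, 10, cfg)
        assert tile.shape == (8, 8)
        np.testing.assert_allclose(tile, 0.7, rtol=1e-6)

    def test_production_geometry_factor(self):
        cfg = SamplerConfig(context_size=2048, out_size=512)
        assert cfg.factor == 4

    def test_checkerboard_block_average(self):
        # 4-periodic checkerboard of 0/1 blocks averages to exactly 0.5
        cfg = SamplerConfig(context_size=32, out_size=8)
        tiles = np.indices((64, 64)).sum(axis=0)
        img = (((np.indices((64, 64))[0] // 2) + (np.indices((64, 64))[1] // 2)) % 2).astype(np.float32)
        tile = extract_context_tile(img, 0, 0, cfg)
        np.testing.assert_allclose(tile, 0.5)

    def test_border_padding(self):
        cfg = SamplerConfig(context_size=16, out_size=16)
        img = np.arange(64, dtype=np.float32).reshape(8, 8)
        tile = extract_context_tile(img, -4, -4, cfg)
        assert tile.shape == (16, 16)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            SamplerConfig(context_size=10, out_size=4).validate()
        with pytest.raises(ValueError):
            SamplerConfig(context_size=8, out_size=16).validate()
        with pytest.raises(ValueError, match="foreground_fraction"):
            SamplerConfig(foreground_fraction=1.5).validate()


class TestDownsampleLabels:
    def test_all_ones_stays_ones(self):
        out = downsample_labels(np.ones((16, 16)), 4)
        assert out.shape == (4, 4) and (out == 1).all()

    def test_single_pixel_vanishes_at_factor_four(self):
        win = np.zeros((16, 16))
        win[3, 3] = 1  # block mean 1/16 < 0.5
        assert downsample_labels(win, 4).sum() == 0

    def test_half_filled_block_is_foreground(self):
        win = np.zeros((4, 4))
        win[:2, :] = 1  # exactly 8/16 -> mean 0.5, ties go to foreground
        assert downsample_labels(win, 4).item() == 1

    def test_output_is_binary(self, rng):
        win = (rng.random((32, 32)) > 0.4).astype(float)
        out = downsample_labels(win, 2)
        assert set(np.unique(out)) <= {0, 1}


class TestSampleBatch:
    def test_single_foreground_pixel_always_captured(self, small_volume):
        vol = small_volume.with_labeled_slices([3])
        mask = np.zeros_like(vol.labels["nuclei"])
        mask[3, 40, 41] = 1
        cfg = SamplerConfig(
            context_size=16, out_size=16, foreground_fraction=1.0, rng_seed=7
        )
        batch = sample_crops(
            vol.intensities, mask, [3], 16, cfg, np.random.default_rng(7)
        )
        assert batch.has_foreground.all()
        for z, y0, x0, f in batch.provenance:
            assert z == 3
            assert y0 <= 40 < y0 + 16 and x0 <= 41 < x0 + 16

    def test_no_constraint_without_foreground_fraction(self, small_volume, rng):
        cfg = SamplerConfig(context_size=32, out_size=16, foreground_fraction=0.0)
        batch = sample_training_batch(small_volume, "nucleoli", 8, cfg, rng)
        assert len(batch) == 8
        assert batch.labels.shape == (8, 16, 16)

    def test_error_when_no_foreground_exists(self, small_volume, rng):
        vol = small_volume.with_labeled_slices([0])
        empty = np.zeros_like(vol.labels["nuclei"])
        cfg = SamplerConfig(context_size=32, out_size=16, foreground_fraction=0.5)
        with pytest.raises(ValueError, match="foreground"):
            sample_crops(vol.intensities, empty, [0], 4, cfg, rng)

    def test_crops_come_only_from_labeled_slices(self, small_volume, rng):
        vol = small_volume.with_labeled_slices([2, 9, 23])
        cfg = SamplerConfig(context_size=32, out_size=16, foreground_fraction=0.9)
        for _ in range(5):
            batch = sample_training_batch(vol, "nuclei", 6, cfg, rng)
            assert {z for z, *_ in batch.provenance} <= {2, 9, 23}

    def test_guaranteed_fraction_on_sparse_structure(self, small_volume, rng):
        """Nucleoli cover well under 1% of pixels, yet nearly every crop must
        contain some after the guarantee."""
        cfg = SamplerConfig(context_size=32, out_size=16, foreground_fraction=0.99)
        batch = sample_training_batch(small_volume, "nucleoli", 200, cfg, rng)
        assert batch.has_foreground.mean() >= 0.99

    def test_imbalance_direction_preserved_by_tiling(self, small_volume, rng):
        cfg = SamplerConfig(context_size=32, out_size=16, foreground_fraction=0.0)
        nuc = sample_training_batch(small_volume, "nuclei", 64, cfg, np.random.default_rng(3))
        ncl = sample_training_batch(small_volume, "nucleoli", 64, cfg, np.random.default_rng(3))
        assert ncl.labels.mean() < nuc.labels.mean()


class TestAugment:
    def test_identity_transform_keeps_batch(self, small_volume):
        cfg = SamplerConfig(context_size=32, out_size=16)
        batch = sample_training_batch(
            small_volume, "nuclei", 4, cfg, np.random.default_rng(0)
        )

        class _IdentityRng:
            def integers(self, lo, hi, size=None):
                return np.zeros(size, dtype=np.int64)

        out = augment(batch, _IdentityRng())
        np.testing.assert_array_equal(out.images, batch.images)
        np.testing.assert_array_equal(out.labels, batch.labels)

    def test_rot180_is_an_involution(self, rng):
        img = rng.random((1, 12, 12)).astype(np.float32)
        assert np.array_equal(dihedral(dihedral(img, 2), 2), img)

    @pytest.mark.parametrize("t", range(8))
    def test_foreground_count_invariant(self, t, rng):
        mask = (rng.random((14, 14)) > 0.7).astype(np.uint8)
        assert dihedral(mask, t).sum() == mask.sum()

    def test_dihedral_transforms_are_distinct(self, rng):
        img = rng.random((6, 6)).astype(np.float32)
        outs = {dihedral(img, t).tobytes() for t in range(8)}
        assert len(outs) == 8

    def test_image_and_label_transformed_together(self, small_volume, rng):
        cfg = SamplerConfig(
            context_size=32, out_size=16, foreground_fraction=1.0, augment=True
        )
        batch = sample_training_batch(small_volume, "nuclei", 8, cfg, rng)
        assert batch.has_foreground.all()  # augmentation preserves foreground
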