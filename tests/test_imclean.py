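"""Artifact-correction operators: stated examples, brute-force equivalence on
random images, and the non-amplification / non-negativity invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from imcpheno import (
    AggregateParams,
    ChannelImage,
    NoiseParams,
    SpilloverParams,
    binarize,
    build_stack,
    cap_intensities,
    denoise,
    gaussian_smooth,
    preprocess_channel,
    remove_aggregates,
    spillover_correct,
    spillover_mask,
)
from imcpheno.errors import ConfigurationError, DimensionError, ParameterError

from conftest import random_count_image
from oracles import (
    binarize_oracle,
    cap_oracle,
    denoise_oracle,
    gaussian_smooth_oracle,
    remove_aggregates_oracle,
    spillover_oracle,
)

nonneg_images = hnp.arrays(
    dtype=float,
    shape=hnp.array_shapes(min_dims=2, max_dims=2, min_side=1, max_side=12),
    elements=st.floats(0, 100, allow_nan=False),
)


class TestCap:
    def test_elementwise_min(self):
        out = cap_intensities(np.array([[1.0, 5.0, 9.0]]), 5)
        assert out.tolist() == [[1.0, 5.0, 5.0]]

    def test_cap_above_max_is_identity(self, rng):
        img = random_count_image(rng)
        assert np.array_equal(cap_intensities(img, img.max() + 1), img)

    def test_all_zero_unchanged(self):
        assert not cap_intensities(np.zeros((4, 4)), 3.0).any()

    def test_nonpositive_cap_rejected(self):
        with pytest.raises(ParameterError):
            cap_intensities(np.ones((2, 2)), 0)


class TestGaussianSmooth:
    def test_radius_zero_identity(self, rng):
        img = random_count_image(rng)
        assert np.array_equal(gaussian_smooth(img, 0), img)

    def test_constant_preserved(self):
        out = gaussian_smooth(np.full((9, 9), 3.5), 1.2)
        assert np.allclose(out, 3.5)

    def test_impulse_mass_conserved(self):
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        assert abs(gaussian_smooth(img, 2.0).sum() - 1.0) < 1e-6

    def test_negative_radius_rejected(self):
        with pytest.raises(ParameterError):
            gaussian_smooth(np.ones((2, 2)), -1)


class TestBinarize:
    def test_strict_greater_than_with_tie(self):
        out = binarize(np.array([[0.0, 0.5, 1.0]]), 0.5)
        assert out.tolist() == [[0, 0, 1]]

    def test_threshold_below_min_all_ones(self, rng):
        img = random_count_image(rng) + 1.0
        assert binarize(img, 0.5).all()

    def test_threshold_above_max_all_zeros(self, rng):
        img = random_count_image(rng)
        assert not binarize(img, img.max() + 1).any()


class TestSpilloverCorrect:
    def test_center_pixel_arithmetic(self):
        target = np.full((3, 3), 5.0)
        mask = np.zeros((3, 3), dtype=np.uint8)
        mask[1, 1] = 1
        out = spillover_correct(target, mask, 2.0)
        assert out[1, 1] == 3.0
        assert (np.delete(out.ravel(), 4) == 5.0).all()

    def test_clamped_at_zero(self):
        out = spillover_correct(np.array([[5.0]]), np.array([[1]]), 10.0)
        assert out[0, 0] == 0.0

    def test_empty_mask_identity(self, rng):
        img = random_count_image(rng)
        assert np.array_equal(spillover_correct(img, np.zeros_like(img), 4.0), img)

    def test_all_ones_mask_is_global_clamped_subtraction(self, rng):
        img = random_count_image(rng)
        out = spillover_correct(img, np.ones_like(img), 3.0)
        assert np.array_equal(out, np.maximum(img - 3.0, 0.0))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            spillover_correct(np.ones((2, 2)), np.ones((3, 3)), 1.0)


class TestDenoise:
    def test_floor_zeroes_below_threshold(self):
        out = denoise(np.array([[1.0, 3.0]]), NoiseParams(floor_threshold=2, window_size=1))
        assert out.tolist() == [[0.0, 3.0]]

    def test_noop_configuration(self, rng):
        img = random_count_image(rng)
        out = denoise(img, NoiseParams(floor_threshold=0, window_size=1))
        assert np.array_equal(out, img)

    def test_isolated_pixel_survives_floored_pixel_stays_zero(self):
        img = np.zeros((7, 7))
        img[3, 3] = 5.0
        img[0, 0] = 0.5
        out = denoise(img, NoiseParams(floor_threshold=1.0, window_size=3))
        assert out[3, 3] == 5.0  # its own window mean is positive
        assert out[0, 0] == 0.0  # zeroed by the floor, stays zero
        assert out.sum() == 5.0

    def test_even_window_rejected(self):
        with pytest.raises(ParameterError):
            NoiseParams(floor_threshold=1, window_size=4)


class TestRemoveAggregates:
    def test_small_blob_zeroed_large_blob_kept(self):
        img = np.zeros((20, 20))
        img[1, 1:3] = 9.0  # 2-pixel blob
        img[8:15, 8:15] = 4.0  # 49-pixel blob
        out = remove_aggregates(
            img, AggregateParams(blur_radius=0, size_threshold=10)
        )
        assert out[1, 1:3].sum() == 0.0
        assert np.array_equal(out[8:15, 8:15], img[8:15, 8:15])

    def test_size_threshold_zero_is_identity(self, rng):
        img = random_count_image(rng)
        out = remove_aggregates(img, AggregateParams(blur_radius=0, size_threshold=0))
        assert np.array_equal(out, img)

    def test_empty_image(self):
        out = remove_aggregates(np.zeros((5, 5)), AggregateParams())
        assert not out.any()

    def test_connectivity_4_splits_diagonal(self):
        img = np.zeros((6, 6))
        img[1, 1] = img[2, 2] = 5.0  # diagonal pair
        p4 = AggregateParams(blur_radius=0, size_threshold=2, connectivity=4)
        p8 = AggregateParams(blur_radius=0, size_threshold=2, connectivity=8)
        assert not remove_aggregates(img, p4).any()  # two size-1 components
        assert remove_aggregates(img, p8).sum() == 10.0  # one size-2 component


class TestOracleEquivalence:
    """Each operator matches an independent per-pixel reference on random
    count images (full 100-image sweep lives in the acceptance suite)."""

    N = 15

    def test_cap(self, rng):
        for _ in range(self.N):
            img = random_count_image(rng, max_side=16)
            assert np.array_equal(cap_intensities(img, 7.5), cap_oracle(img, 7.5))

    def test_gaussian(self, rng):
        for _ in range(5):
            img = random_count_image(rng, max_side=12)
            assert np.allclose(
                gaussian_smooth(img, 1.3), gaussian_smooth_oracle(img, 1.3), atol=1e-10
            )

    def test_binarize(self, rng):
        for _ in range(self.N):
            img = random_count_image(rng, max_side=16)
            assert np.array_equal(binarize(img, 4.0), binarize_oracle(img, 4.0))

    def test_spillover(self, rng):
        for _ in range(self.N):
            img = random_count_image(rng, max_side=16)
            mask = (rng.random(img.shape) < 0.4).astype(np.uint8)
            assert np.array_equal(
                spillover_correct(img, mask, 5.0), spillover_oracle(img, mask, 5.0)
            )

    def test_denoise(self, rng):
        for _ in range(self.N):
            img = random_count_image(rng, max_side=16)
            got = denoise(img, NoiseParams(floor_threshold=3.0, window_size=3))
            assert np.array_equal(got, denoise_oracle(img, 3.0, 3))

    def test_remove_aggregates(self, rng):
        for _ in range(self.N):
            img = random_count_image(rng, max_side=16)
            got = remove_aggregates(
                img, AggregateParams(blur_radius=0, size_threshold=4)
            )
            assert np.array_equal(got, remove_aggregates_oracle(img, 0, 0, 4))


class TestComposite:
    def test_all_absent_is_identity(self, rng):
        img = random_count_image(rng)
        assert np.array_equal(preprocess_channel(img), img)

    def test_zero_removal_spillover_is_identity(self, rng):
        img = random_count_image(rng)
        spill = SpilloverParams("src", cap_threshold=5, gauss_radius=1,
                                binarize_threshold=0, removal_value=0)
        out = preprocess_channel(img, spill=spill, source=img)
        assert np.array_equal(out, img)

    def test_matches_manual_sequential_application(self, rng):
        img = random_count_image(rng, max_side=24)
        src = random_count_image(rng, max_side=24)
        src = np.resize(src, img.shape)
        spill = SpilloverParams("src", 10.0, 1.0, 2.0, 3.0)
        noise = NoiseParams(floor_threshold=2.0, window_size=3)
        agg = AggregateParams(blur_radius=0, size_threshold=4)
        manual = spillover_correct(img, spillover_mask(src, spill), 3.0)
        manual = denoise(manual, noise)
        manual = remove_aggregates(manual, agg)
        got = preprocess_channel(img, spill=spill, noise=noise, agg=agg, source=src)
        assert np.array_equal(got, manual)

    def test_spill_without_source_rejected(self):
        spill = SpilloverParams("src", 10.0, 1.0, 2.0, 3.0)
        with pytest.raises(ConfigurationError):
            preprocess_channel(np.ones((3, 3)), spill=spill)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(img=nonneg_images)
    def test_composite_never_amplifies_and_stays_nonnegative(self, img):
        src = np.flip(img)
        spill = SpilloverParams("s", 8.0, 0.8, 1.0, 2.5)
        noise = NoiseParams(floor_threshold=1.0, window_size=3)
        agg = AggregateParams(blur_radius=0.5, size_threshold=3)
        out = preprocess_channel(img, spill=spill, noise=noise, agg=agg, source=src)
        assert (out <= img + 1e-12).all()
        assert (out >= 0).all()


class TestBuildStack:
    def _channels(self):
        return [
            ChannelImage(np.full((4, 4), i), marker=m)
            for i, m in enumerate(["CD8", "CD4", "CD20"])
        ]

    def test_shuffled_channels_ordered_by_panel(self):
        stack = build_stack(self._channels(), ["CD4", "CD8", "CD20"])
        assert stack.panel == ["CD4", "CD8", "CD20"]
        assert [c.marker for c in stack.channels] == ["CD4", "CD8", "CD20"]
        assert stack.channel("CD8").pixels[0, 0] == 0

    def test_single_channel_stack(self):
        stack = build_stack(self._channels()[:1], ["CD8"])
        assert stack.pixels().shape == (1, 4, 4)

    def test_missing_channel_error_names_marker(self):
        with pytest.raises(ConfigurationError, match="CD68"):
            build_stack(self._channels(), ["CD4", "CD8", "CD68"])

    def test_duplicate_marker_rejected(self):
        with pytest.raises(ConfigurationError, match="duplicate"):
            build_stack(self._channels(), ["CD4", "CD4", "CD20"])

    def test_shape_mismatch_rejected(self):
        chans = self._channels()
        chans[1] = ChannelImage(np.zeros((5, 5)), marker="CD4")
        with pytest.raises(DimensionError):
            build_stack(chans, ["CD4", "CD8", "CD20"])
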