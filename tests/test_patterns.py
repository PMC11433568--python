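"""Circular sampling, quantization, riu2 mapping and the three label maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neutrotex import (
    CircularNeighborhood,
    compute_mstrp_map,
    compute_nrtxp_map,
    compute_ritxp_map,
    mean_local_difference_quantize,
    median_quantize,
    riu2_label,
    sample_circle,
    uniformity,
)
from neutrotex.patterns import circle_offsets

from conftest import all_bit_patterns, brute_force_riu2


class TestCircularSampling:
    @pytest.mark.parametrize("r", range(1, 10))
    def test_sample_count_is_8r(self, r):
        img = np.zeros((2 * r + 1, 2 * r + 1))
        nb = sample_circle(img, r, r, r)
        assert nb.samples.shape == (8 * r,)

    def test_constant_image_samples_constant(self):
        nb = sample_circle(np.full((9, 9), 5.5), 4, 4, 3)
        assert np.allclose(nb.samples, 5.5)

    def test_bilinear_exact_on_column_ramp(self):
        # f(row, col) = col is affine, so bilinear interpolation is exact
        img = np.tile(np.arange(16.0), (16, 1))
        r = 2
        nb = sample_circle(img, 8, 8, r)
        theta = 2 * np.pi * np.arange(8 * r) / (8 * r)
        expected = 8 + r * np.cos(theta)
        assert np.allclose(nb.samples, expected, atol=1e-9)

    def test_out_of_region_center_rejected(self):
        with pytest.raises(ValueError):
            sample_circle(np.zeros((10, 10)), 0, 5, 2)

    def test_offsets_snap_to_grid_on_axes(self):
        offs = circle_offsets(2)
        # n = 0 is due east; n = 4 (quarter turn at r=2) is due north
        assert tuple(offs[0]) == (0.0, 2.0)
        assert tuple(offs[4]) == (-2.0, 0.0)


class TestQuantization:
    def test_r1_median_is_identity(self, rng):
        samples = rng.uniform(0, 10, 8)
        nb = CircularNeighborhood(r=1, samples=samples, center_value=0.0)
        assert np.array_equal(median_quantize(nb), samples)

    def test_pairwise_median_is_mean_of_two(self):
        samples = np.array([10.0, 20.0] * 8)
        nb = CircularNeighborhood(r=2, samples=samples, center_value=0.0)
        mqp = median_quantize(nb)
        assert mqp.shape == (8,)
        assert np.allclose(mqp, 15.0)

    def test_triplet_median_rejects_outlier(self):
        samples = np.array([5.0, 100.0, 7.0] * 8)
        nb = CircularNeighborhood(r=3, samples=samples, center_value=0.0)
        assert np.allclose(median_quantize(nb), 7.0)

    def test_mldqp_zero_when_samples_equal_center(self):
        nb = CircularNeighborhood(r=2, samples=np.full(16, 3.0), center_value=3.0)
        assert np.allclose(mean_local_difference_quantize(nb), 0.0)

    def test_mldqp_r1_is_absolute_difference(self):
        deltas = np.array([1.0, -2.0, 3.0, -4.0, 5.0, -6.0, 7.0, -8.0])
        nb = CircularNeighborhood(r=1, samples=10.0 + deltas, center_value=10.0)
        assert np.allclose(mean_local_difference_quantize(nb), np.abs(deltas))

    def test_mldqp_pairwise_hand_value(self):
        # center 10, first arc samples (12, 6): mean(|2|, |-4|) = 3
        samples = np.array([12.0, 6.0] + [10.0] * 14)
        nb = CircularNeighborhood(r=2, samples=samples, center_value=10.0)
        mldqp = mean_local_difference_quantize(nb)
        assert mldqp[0] == pytest.approx(3.0)
        assert np.allclose(mldqp[1:], 0.0)

    @pytest.mark.parametrize("r", range(1, 10))
    def test_quantized_vectors_always_length_8(self, rng, r):
        nb = CircularNeighborhood(r=r, samples=rng.uniform(0, 1, 8 * r),
                                  center_value=0.5)
        assert median_quantize(nb).shape == (8,)
        assert mean_local_difference_quantize(nb).shape == (8,)


class TestRiu2:
    @pytest.mark.parametrize(
        "bits,expected_u",
        [([0] * 8, 0), ([0, 0, 0, 0, 1, 1, 1, 1], 2), ([0, 1] * 4, 8)],
    )
    def test_uniformity_examples(self, bits, expected_u):
        assert uniformity(np.array(bits)) == expected_u

    @pytest.mark.parametrize(
        "bits,expected",
        [([1] * 8, 8), ([0, 0, 0, 0, 1, 1, 1, 1], 4), ([0, 1] * 4, 9)],
    )
    def test_riu2_examples(self, bits, expected):
        assert riu2_label(np.array(bits)) == expected

    def test_riu2_matches_brute_force_over_all_patterns(self):
        for bits in all_bit_patterns():
            assert riu2_label(bits) == brute_force_riu2(bits)

    def test_label_inventory(self):
        labels = {riu2_label(b) for b in all_bit_patterns()}
        uniform_labels = {
            riu2_label(b) for b in all_bit_patterns() if uniformity(b) <= 2
        }
        assert len(labels) == 10
        assert len(uniform_labels) == 9

    @given(code=st.integers(0, 255), shift=st.integers(0, 7))
    @settings(deadline=None, derandomize=True)
    def test_riu2_invariant_under_circular_shift(self, code, shift):
        bits = np.array([(code >> i) & 1 for i in range(8)])
        assert riu2_label(bits) == riu2_label(np.roll(bits, shift))

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError):
            uniformity(np.array([0, 1, 2, 0, 1, 0, 1, 0]))
        with pytest.raises(ValueError):
            riu2_label(np.array([0, 1, 0, 1]))


class TestLabelMaps:
    def test_constant_image_labels(self):
        img = np.full((12, 12), 7.0)
        for r in (1, 2, 3):
            ms = compute_mstrp_map(img, r)
            nr = compute_nrtxp_map(img, r)
            ri = compute_ritxp_map(img, r)
            assert set(np.unique(ms.labels[ms.valid_mask])) == {8}
            assert set(np.unique(nr.labels[nr.valid_mask])) == {8}
            assert set(np.unique(ri.labels[ri.valid_mask])) == {1}

    def test_valid_region_and_sentinel(self, random_image):
        r = 3
        m = compute_mstrp_map(random_image, r)
        assert np.all(m.labels[:r, :] == -1) and np.all(m.labels[:, :r] == -1)
        assert np.all(m.labels[-r:, :] == -1) and np.all(m.labels[:, -r:] == -1)
        assert np.all(m.labels[m.valid_mask] >= 0)

    def test_label_ranges(self, random_image):
        for r in (1, 2):
            assert set(np.unique(
                compute_mstrp_map(random_image, r).labels)) <= set(range(-1, 10))
            assert set(np.unique(
                compute_nrtxp_map(random_image, r).labels)) <= set(range(-1, 10))
            assert set(np.unique(
                compute_ritxp_map(random_image, r).labels)) <= {-1, 0, 1}

    def test_dark_center_bright_ring_gives_zero(self):
        img = np.full((5, 5), 200.0)
        img[2, 2] = 10.0
        ri = compute_ritxp_map(img, 1)
        assert ri.labels[2, 2] == 0

    def test_bright_impulse_nrtxp_label_is_8(self):
        # the impulse pixel's mldqp is uniformly positive while the ring
        # threshold stays smaller, so all 8 bits are set
        img = np.full((5, 5), 50.0)
        img[2, 2] = 250.0
        nr = compute_nrtxp_map(img, 1)
        assert nr.labels[2, 2] == 8

    def test_image_too_small_for_scale_rejected(self):
        with pytest.raises(ValueError):
            compute_mstrp_map(np.zeros((4, 4)), 2)

    def test_determinism(self, random_image):
        a = compute_nrtxp_map(random_image, 2).labels
        b = compute_nrtxp_map(random_image.copy(), 2).labels
        assert np.array_equal(a, b)

    @pytest.mark.parametrize(
        "compute", [compute_mstrp_map, compute_nrtxp_map, compute_ritxp_map]
    )
    def test_rot90_equivariance_of_label_histograms(self, rng, compute):
        # a quarter turn shifts the 8r samples by 2r positions, so riu2
        # labels rotate with the image; on square images the valid region
        # maps onto itself and histograms agree exactly
        img = rng.uniform(0, 255, (24, 24))
        r = 2
        m1 = compute(img, r)
        m2 = compute(np.rot90(img), r)
        h1 = np.bincount(m1.labels[m1.valid_mask], minlength=10)
        h2 = np.bincount(m2.labels[m2.valid_mask], minlength=10)
        assert np.array_equal(h1, h2)

    def test_mstrp_histogram_more_stable_under_noise_than_across_classes(self):
        """AWGN sigma=10 perturbs a texture's MsTrP histogram less than the
        gap between histograms of different texture classes (r=3)."""
        from neutrotex import extended_canberra

        rng = np.random.default_rng(7)

        def hist(img):
            m = compute_mstrp_map(img, 3)
            h = np.bincount(m.labels[m.valid_mask], minlength=10).astype(float)
            return h / h.sum()

        y, x = np.mgrid[0:48, 0:48].astype(float)
        class_a = 127.5 + 100 * np.sin(2 * np.pi * 4 * x / 48)
        class_b = 127.5 + 100 * np.sin(2 * np.pi * 9 * (x + y) / 48)
        between = extended_canberra(hist(class_a), hist(class_b))
        within = []
        for _ in range(20):
            noisy = np.clip(class_a + rng.normal(0, 10, class_a.shape), 0, 255)
            within.append(extended_canberra(hist(class_a), hist(noisy)))
        assert np.mean(within) < between
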