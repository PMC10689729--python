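"""Core descriptor blocks: sign/magnitude transform, the three binary
blocks, combination, and whole-image description."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lmfd import (
    CIRCLE16_OFFSETS,
    DescriptorParams,
    Keypoint,
    centroid_descriptor,
    circle16_offsets,
    combine,
    decompose,
    describe,
    difference_vector,
    mean_descriptor,
    reconstruct,
    split,
    symbolic_descriptor,
)
from lmfd.descriptors import ORDERS, window_ring_offsets

from oracles import centroid_naive, mean_naive, symbolic_naive

# The printed worked example: a 7x7 block's circular differences split into
# sign and magnitude vectors.
FIG_SIGN = [0, 0, 1, 1, 0, 0, 1, 1, 1, 0, 0, 1, 0, 0, 1, 1]
FIG_MAG = [70, 133, 23, 11, 48, 125, 121, 78, 32, 31, 113, 108, 57, 80, 69, 12]
FIG_D = [-70, -133, 23, 11, -48, -125, 121, 78, 32, -31, -113, 108, -57, -80, 69, 12]

# Standard published FAST-9 circle offsets (x, y) in the usual reference
# ordering (clockwise from 12 o'clock) for cross-checking our table.
REFERENCE_FAST_CIRCLE = {(-3, 0), (-3, 1), (-2, 2), (-1, 3), (0, 3), (1, 3),
                         (2, 2), (3, 1), (3, 0), (3, -1), (2, -2), (1, -3),
                         (0, -3), (-1, -3), (-2, -2), (-3, -1)}


class TestCircle:
    def test_offsets_sum_to_zero_and_contain_axis_points(self):
        offs = circle16_offsets()
        assert len(offs) == 16
        assert tuple(np.sum(offs, axis=0)) == (0, 0)
        for p in [(0, 3), (3, 0), (0, -3), (-3, 0)]:
            assert p in offs

    def test_matches_published_fast_circle(self):
        assert set(circle16_offsets()) == REFERENCE_FAST_CIRCLE
        # clockwise start at 12 o'clock
        assert circle16_offsets()[0] == (-3, 0)
        assert circle16_offsets()[1] == (-3, 1)


class TestDifferenceTransform:
    def test_constant_image_decomposes_to_zero_magnitudes_positive_signs(self):
        img = np.full((9, 9), 77, dtype=np.uint8)
        dec = difference_vector(img, (4, 4))
        assert np.all(dec.d == 0)
        assert np.all(dec.s == 1)
        assert np.all(dec.m == 0)

    def test_uniformly_darker_ring(self):
        img = np.full((9, 9), 90, dtype=np.uint8)
        img[4, 4] = 100
        dec = difference_vector(img, (4, 4))
        assert np.all(dec.d == -10)
        assert np.all(dec.s == 0)
        assert np.all(dec.m == 10)

    def test_border_center_rejected_with_margin_message(self):
        img = np.zeros((16, 16), dtype=np.uint8)
        with pytest.raises(ValueError, match="margin"):
            difference_vector(img, (2, 8))

    def test_printed_example_vectors_share_sign_pattern(self):
        """The two dissimilar difference vectors with identical signs."""
        v1 = np.array([3, 24, -5, 66, 13, -22, -9, 230])
        v2 = np.array([200, 200, -1, 200, 200, -1, -1, 200])
        s1, _ = decompose(v1)
        s2, _ = decompose(v2)
        expected = np.array([1, 1, 0, 1, 1, 0, 0, 1])  # (+,+,-,+,+,-,-,+)
        assert np.array_equal(s1, expected)
        assert np.array_equal(s2, expected)

    def test_printed_worked_decomposition_reconstructs(self):
        d = reconstruct(np.array(FIG_SIGN), np.array(FIG_MAG))
        assert d.tolist() == FIG_D
        s, m = decompose(d)
        assert s.tolist() == FIG_SIGN
        assert m.tolist() == FIG_MAG

    def test_all_ones_sign_returns_magnitudes(self):
        m = np.array([5, 0, 250, 1])
        assert np.array_equal(reconstruct(np.ones(4, dtype=int), m), m)

    def test_reconstruct_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            reconstruct(np.array([1, 0]), np.array([1, 2, 3]))
        with pytest.raises(ValueError):
            reconstruct(np.array([1, 0]), np.array([1, -2]))

    @given(st.lists(st.integers(min_value=-255, max_value=255), min_size=16,
                    max_size=16))
    @settings(deadline=None)
    def test_roundtrip_identity_over_full_difference_range(self, d):
        d = np.array(d)
        s, m = decompose(d)
        assert np.array_equal(reconstruct(s, m), d)
        assert np.array_equal(np.where(s == 1, 1, -1) * m, d)

    @given(st.lists(st.integers(min_value=1, max_value=255), min_size=16,
                    max_size=16),
           st.lists(st.integers(min_value=0, max_value=1), min_size=16,
                    max_size=16))
    @settings(deadline=None)
    def test_positive_magnitudes_roundtrip_through_decompose(self, m, s):
        d = reconstruct(np.array(s), np.array(m))
        s2, m2 = decompose(d)
        assert np.array_equal(s2, np.array(s))
        assert np.array_equal(m2, np.array(m))


class TestWindowOrdering:
    def test_w3_ring_is_clockwise_from_top_left(self):
        assert window_ring_offsets(3) == [(-1, -1), (-1, 0), (-1, 1), (0, 1),
                                          (1, 1), (1, 0), (1, -1), (0, -1)]

    def test_w7_has_48_offsets_rings_outward(self):
        offs = window_ring_offsets(7)
        assert len(offs) == 48
        assert offs[:8] == window_ring_offsets(3)  # inner ring first
        assert offs[8] == (-2, -2)                 # next ring starts top-left
        assert len(set(offs)) == 48

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            window_ring_offsets(4)


class TestSymbolicBlock:
    def test_constant_patch_is_all_zero(self):
        bits = symbolic_descriptor(np.full((5, 5), 5, dtype=np.uint8), kz=1)
        assert bits.size == 72
        assert not bits.any()

    def test_single_bright_centre_lights_only_central_window(self):
        patch = np.zeros((5, 5), dtype=np.uint8)
        patch[2, 2] = 255
        bits = symbolic_descriptor(patch, kz=1).reshape(9, 8)
        assert bits.sum() == 8
        assert bits[4].all()          # central window s_4 holds all 8 ones

    def test_matches_bruteforce_oracle(self, preset, rng):
        for _ in range(60):
            patch = rng.integers(0, 256, (preset.ps, preset.ps)).astype(np.uint8)
            got = symbolic_descriptor(patch, preset.kz).astype(int).tolist()
            assert got == symbolic_naive(patch, preset.kz)

    def test_patch_smaller_than_window_rejected(self):
        with pytest.raises(ValueError):
            symbolic_descriptor(np.zeros((3, 3), dtype=np.uint8), kz=2)


class TestMeanBlock:
    def test_constant_patch_all_zero(self):
        assert not mean_descriptor(np.full((5, 5), 9, dtype=np.uint8), 1).any()

    def test_column_ramp_marks_right_hand_windows(self):
        patch = (10 * np.arange(5))[None, :] * np.ones((5, 1))
        bits = mean_descriptor(patch.astype(np.uint8), 1).astype(int)
        assert bits.tolist() == [0, 0, 1, 0, 0, 1, 0, 0, 1]

    def test_matches_bruteforce_oracle(self, preset, rng):
        for _ in range(60):
            patch = rng.integers(0, 256, (preset.ps, preset.ps)).astype(np.uint8)
            got = mean_descriptor(patch, preset.kz).astype(int).tolist()
            assert got == mean_naive(patch, preset.kz)


class TestCentroidBlock:
    def test_constant_patch_with_matching_image_mean_all_zero(self):
        patch = np.full((5, 5), 80, dtype=np.uint8)
        assert not centroid_descriptor(patch, 1, 80.0).any()

    def test_single_bright_centre_forces_central_bit(self):
        patch = np.zeros((5, 5), dtype=np.uint8)
        patch[2, 2] = 255
        bits = centroid_descriptor(patch, 1, 0.0).reshape(3, 3)
        # c = (255/25 + 0)/2 = 5.1 and the central window's centroid sits on
        # the 255 pixel
        assert bits[1, 1]

    def test_matches_bruteforce_oracle(self, preset, rng):
        for _ in range(60):
            patch = rng.integers(0, 256, (preset.ps, preset.ps)).astype(np.uint8)
            image_mean = float(rng.uniform(0, 255))
            got = centroid_descriptor(patch, preset.kz, image_mean).astype(int)
            assert got.tolist() == centroid_naive(patch, preset.kz, image_mean)


class TestCombine:
    def _blocks(self, rng, params):
        S = rng.integers(0, 2, params.n_windows * params.code_len).astype(bool)
        M = rng.integers(0, 2, params.n_windows).astype(bool)
        C = rng.integers(0, 2, params.n_windows).astype(bool)
        return S, M, C

    def test_msc_concatenation_order(self, rng):
        p = DescriptorParams()
        S, M, C = self._blocks(rng, p)
        bits = combine(S, M, C, "MSC")
        assert np.array_equal(bits, np.concatenate([M, S, C]))

    def test_popcount_invariant_across_orders(self, rng, preset):
        S, M, C = self._blocks(rng, preset)
        counts = {o: combine(S, M, C, o).sum() for o in ORDERS}
        assert len(set(counts.values())) == 1

    def test_combine_split_roundtrip_every_order(self, rng, preset):
        S, M, C = self._blocks(rng, preset)
        for order in ORDERS:
            layout = DescriptorParams(r=preset.r, kz=preset.kz, ps=preset.ps,
                                      order=order).layout
            S2, M2, C2 = split(combine(S, M, C, order), layout)
            assert np.array_equal(S2, S)
            assert np.array_equal(M2, M)
            assert np.array_equal(C2, C)

    def test_inconsistent_lengths_rejected(self):
        with pytest.raises(ValueError):
            combine(np.zeros(71, bool), np.zeros(9, bool), np.zeros(9, bool))


class TestInvariances:
    def test_additive_shift_preserves_symbolic_and_mean_blocks(self, rng):
        for _ in range(50):
            patch = rng.integers(0, 200, (5, 5)).astype(np.int64)
            k = int(rng.integers(1, 56))
            assert np.array_equal(symbolic_descriptor(patch, 1),
                                  symbolic_descriptor(patch + k, 1))
            assert np.array_equal(mean_descriptor(patch, 1),
                                  mean_descriptor(patch + k, 1))

    def test_additive_shift_preserves_centroid_when_selection_stable(self, rng):
        """The centroid bit is stable under +k (with image_mean recomputed)
        whenever the shift does not change which pixel is nearest to the
        intensity-weighted centroid; the weighted location itself moves
        with k, so stability is conditional on that selection."""
        from lmfd.descriptors import _nearest_index, _windows
        checked = 0
        for _ in range(200):
            patch = rng.integers(0, 200, (5, 5)).astype(np.int64)
            im_mean = float(rng.uniform(0, 200))
            k = int(rng.integers(1, 56))
            if not np.array_equal(_centroid_pixels(patch),
                                  _centroid_pixels(patch + k)):
                continue
            checked += 1
            assert np.array_equal(centroid_descriptor(patch, 1, im_mean),
                                  centroid_descriptor(patch + k, 1, im_mean + k))
        assert checked > 100

    def test_positive_affine_contrast_preserves_symbolic_block(self, rng):
        for _ in range(50):
            patch = rng.integers(0, 120, (5, 5)).astype(np.int64)
            a = float(rng.uniform(1.1, 2.0))
            b = float(rng.uniform(0, 10))
            scaled = a * patch + b          # float patch: no clipping, no new ties
            assert np.array_equal(symbolic_descriptor(patch, 1),
                                  symbolic_descriptor(scaled, 1))

    def test_quarter_rotation_equivariance_law(self, rng):
        """Rotating the patch by 90 deg permutes the window grid and
        cyclically shifts each window's ring code by (w^2-1)/4 positions;
        mean and centroid bits follow the window permutation alone."""
        for _ in range(100):
            patch = rng.integers(0, 256, (5, 5)).astype(np.uint8)
            rot = np.rot90(patch)           # counter-clockwise
            S0 = symbolic_descriptor(patch, 1).reshape(3, 3, 8)
            S1 = symbolic_descriptor(rot, 1).reshape(3, 3, 8)
            assert np.array_equal(S1, np.roll(np.rot90(S0), -2, axis=2))
            M0 = mean_descriptor(patch, 1).reshape(3, 3)
            assert np.array_equal(mean_descriptor(rot, 1).reshape(3, 3),
                                  np.rot90(M0))
            C0 = centroid_descriptor(patch, 1, 128.0).reshape(3, 3)
            assert np.array_equal(centroid_descriptor(rot, 1, 128.0).reshape(3, 3),
                                  np.rot90(C0))


def _centroid_pixels(patch):
    """Index pair of the pixel selected as each window's centroid value."""
    from lmfd.descriptors import _nearest_index, _windows
    patch = np.asarray(patch, dtype=np.float64)
    win = _windows(patch, 1)
    total = win.sum(axis=(2, 3))
    idx = np.arange(3, dtype=np.float64)
    safe = np.where(total > 0, total, 1.0)
    rbar = np.where(total > 0, (win * idx[None, None, :, None]).sum(axis=(2, 3)) / safe, 1.0)
    cbar = np.where(total > 0, (win * idx[None, None, None, :]).sum(axis=(2, 3)) / safe, 1.0)
    return np.stack([_nearest_index(rbar, 1, 3), _nearest_index(cbar, 1, 3)])


class TestDescribe:
    def test_constant_image_centre_keypoint_gives_all_zero_bits(self):
        img = np.full((32, 32), 50, dtype=np.uint8)
        descs = describe(img, [Keypoint(16, 16)])
        assert len(descs) == 1
        assert descs[0].bit_width == 90
        assert not descs[0].bits.any()

    def test_deterministic_across_calls(self, rng):
        img = rng.integers(0, 256, (48, 48)).astype(np.uint8)
        kps = [Keypoint(20, 20), Keypoint(30, 15)]
        a = describe(img, kps)
        b = describe(img, kps)
        assert all(np.array_equal(x.packed, y.packed) for x, y in zip(a, b))

    def test_border_keypoints_dropped_not_error(self, rng):
        img = rng.integers(0, 256, (48, 48)).astype(np.uint8)
        descs = describe(img, [Keypoint(1, 1), Keypoint(24, 24)])
        assert len(descs) == 1
        assert descs[0].keypoint == Keypoint(24, 24)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            describe(np.zeros((0, 0), dtype=np.uint8), [])

    def test_translation_equivariance(self, rng):
        """Shifting the image content (circularly, so the global mean is
        unchanged) and the keypoint by the same offset reproduces the
        descriptor bit-for-bit."""
        img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        shifted = np.roll(img, (7, 7), axis=(0, 1))
        a = describe(img, [Keypoint(20, 20)])[0]
        b = describe(shifted, [Keypoint(27, 27)])[0]
        assert np.array_equal(a.packed, b.packed)

    def test_bit_width_presets(self):
        assert DescriptorParams(r=3, kz=1).bit_width == 90
        assert DescriptorParams(r=5, kz=3).bit_width == 450
        assert DescriptorParams(r=3, kz=1).n_windows == 9
        assert DescriptorParams(r=5, kz=3).n_windows == 9

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DescriptorParams(r=3, kz=1, ps=6)       # even patch
        with pytest.raises(ValueError):
            DescriptorParams(r=3, kz=2, ps=5)       # ps < w + 2
        with pytest.raises(ValueError):
            DescriptorParams(order="XYZ")
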