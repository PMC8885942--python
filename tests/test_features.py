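"""Descriptor correctness: identities, shape indices, oracles, invariances."""

import dataclasses

import numpy as np
import pytest

from dermoknn import (
    FEATURE_NAMES,
    FeatureVector,
    LesionSpec,
    ValidationError,
    area_and_holes,
    asymmetry_index,
    color_features,
    compactness_index,
    extract_features,
    generate_lesion_image,
    lesion_diameter,
    masked_stats,
    mean_via_fft,
    preprocess,
    to_grayscale,
)
from dermoknn.features import boundary_length
from oracles import digital_disk, feret_oracle, hole_count_oracle, random_blob


class TestMeanViaFft:
    def test_constant_image(self):
        assert mean_via_fft(np.full((5, 7), 42.0)) == pytest.approx(42.0)

    def test_hand_summed_raster(self):
        assert mean_via_fft(np.array([[0, 100], [100, 200]])) == pytest.approx(100.0)

    def test_equals_arithmetic_mean(self, rng):
        for _ in range(100):
            img = rng.integers(0, 256, size=(17, 23)).astype(float)
            assert mean_via_fft(img) == pytest.approx(img.mean(), rel=1e-9)


class TestMaskedStats:
    def test_uniform_region(self):
        img = np.full((10, 10), 77, dtype=np.uint8)
        mask = np.ones((10, 10), dtype=bool)
        std_i, hmean, hstd = masked_stats(img, mask)
        assert (std_i, hmean, hstd) == (0.0, 77.0, 0.0)

    def test_two_point_distribution(self):
        img = np.zeros((2, 10), dtype=np.uint8)
        img[1] = 255
        mask = np.ones_like(img, dtype=bool)
        std_i, hmean, _ = masked_stats(img, mask)
        assert std_i == pytest.approx(127.5)
        assert hmean == pytest.approx(127.5)

    def test_histogram_mean_equals_direct_mean_exactly(self, rng):
        for _ in range(20):
            img = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
            mask = rng.random((16, 16)) < 0.6
            if not mask.any():
                continue
            _, hmean, hstd = masked_stats(img, mask)
            assert hmean == img[mask].mean()
            assert hstd == pytest.approx(img[mask].std(), rel=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            masked_stats(np.zeros((4, 4), dtype=np.uint8),
                         np.zeros((4, 4), dtype=bool))


class TestAreaAndHoles:
    def test_solid_square(self):
        mask = np.zeros((14, 14), dtype=bool)
        mask[2:12, 2:12] = True
        assert area_and_holes(mask) == (100, 0)

    def test_square_with_interior_hole(self):
        mask = np.zeros((14, 14), dtype=bool)
        mask[2:12, 2:12] = True
        mask[5:7, 5:7] = False
        assert area_and_holes(mask) == (96, 4)

    def test_random_blobs_match_flood_fill_oracle(self, rng):
        for _ in range(100):
            mask = random_blob(rng)
            # punch random interior pixels out to create candidate holes
            punch = rng.random(mask.shape) < 0.1
            mask = mask & ~punch
            area, holes = area_and_holes(mask)
            assert area == int(mask.sum())
            assert holes == hole_count_oracle(mask)


class TestAsymmetry:
    def test_disk_nearly_symmetric(self, disk_case):
        _, mask, _ = disk_case
        assert asymmetry_index(mask) <= 0.02

    def test_half_disk_matches_continuous_geometry(self):
        """A half disk reflected about its principal axes: the long-axis
        XOR is 0.37 A (continuous-geometry value), the short-axis XOR 0,
        giving AI ~= 0.185 — an order of magnitude above a full disk's."""
        disk = digital_disk(30)
        half = disk.copy()
        half[: half.shape[0] // 2] = False
        ai = asymmetry_index(half)
        assert ai == pytest.approx(0.185, abs=0.03)
        assert ai > 10 * asymmetry_index(disk)

    def test_translation_and_rotation_invariance(self):
        spec = LesionSpec(base_radius=25, asymmetry_level=0.4,
                          border_irregularity=0.2, seed=13)
        _, mask, _ = generate_lesion_image(spec)
        base = asymmetry_index(mask)
        rolled = np.roll(np.roll(mask.pixels, 15, axis=0), -20, axis=1)
        assert asymmetry_index(rolled) == pytest.approx(base, abs=0.02)
        assert asymmetry_index(np.rot90(mask.pixels)) == pytest.approx(
            base, abs=0.02
        )

    def test_degenerate_mask_rejected(self):
        line = np.zeros((10, 10), dtype=bool)
        line[5, 2:8] = True
        with pytest.raises(ValidationError):
            asymmetry_index(line)


class TestCompactness:
    def test_disk_is_near_one(self, disk_case):
        _, mask, _ = disk_case
        assert 1.0 <= compactness_index(mask) <= 1.15

    def test_thin_bar_far_above_disk(self):
        bar = np.zeros((10, 110), dtype=bool)
        bar[5, 5:105] = True
        p = boundary_length(bar)
        assert 198 <= p <= 202
        assert 31 <= compactness_index(bar) <= 33

    def test_increases_with_border_irregularity(self):
        base = LesionSpec(base_radius=30, border_irregularity=0.05, seed=21)
        rough = dataclasses.replace(base, border_irregularity=0.45)
        _, m1, _ = generate_lesion_image(base)
        _, m2, _ = generate_lesion_image(rough)
        assert compactness_index(m2) > compactness_index(m1)


class TestDiameter:
    def test_single_pixel_is_zero(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        assert lesion_diameter(mask) == 0.0

    def test_disk_diameter(self, disk_case):
        _, mask, _ = disk_case
        d = lesion_diameter(mask)
        assert d == pytest.approx(80, abs=2)
        assert d == feret_oracle(mask.pixels)

    def test_hull_equals_all_pairs_oracle(self, rng):
        for _ in range(20):
            mask = random_blob(rng, size=30)
            assert lesion_diameter(mask) == pytest.approx(
                feret_oracle(mask), abs=1e-9
            )


class TestColorFeatures:
    def test_uniform_lesion(self):
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        img[...] = (120, 80, 60)
        mask = np.ones((8, 8), dtype=bool)
        assert color_features(img, mask) == (120, 80, 60, 0, 0, 0)

    def test_two_tone_lesion(self):
        img = np.zeros((2, 10, 3), dtype=np.uint8)
        img[0, :, 0] = 100
        img[1, :, 0] = 200
        mask = np.ones((2, 10), dtype=bool)
        feats = color_features(img, mask)
        assert feats[0] == 150.0 and feats[3] == 50.0

    def test_variegation_raises_channel_std(self):
        plain = LesionSpec(base_radius=30, seed=31,
                           lesion_colors=((110, 70, 50),), color_weights=(1.0,))
        varied = dataclasses.replace(
            plain,
            lesion_colors=((110, 70, 50), (60, 40, 30), (150, 100, 80)),
            color_weights=(0.4, 0.3, 0.3),
        )
        i1, m1, _ = generate_lesion_image(plain)
        i2, m2, _ = generate_lesion_image(varied)
        s1 = np.mean(color_features(i1.pixels, m1.pixels)[3:])
        s2 = np.mean(color_features(i2.pixels, m2.pixels)[3:])
        assert s2 > s1


class TestFeatureVector:
    def test_frozen_order_and_roundtrip(self, noisy_case):
        img, _, _ = noisy_case
        gray = to_grayscale(img)
        prep = preprocess(gray)
        from dermoknn import segment

        mask = segment(prep)
        fv = extract_features(img, prep.pixels, gray.pixels, mask)
        arr = fv.to_array()
        assert arr.shape == (len(FEATURE_NAMES),)
        assert FeatureVector.from_array(arr) == fv
        assert fv.log_area == pytest.approx(np.log1p(fv.area_count))
        assert fv.log_hole == pytest.approx(np.log1p(fv.hole_count))
        assert 0.0 <= fv.asymmetry_index <= 1.0
        assert fv.compactness_index >= 0.95
        assert fv.diameter <= np.hypot(*img.pixels.shape[:2])

    def test_shape_indices_scale_invariant(self):
        """Asymmetry and compactness agree across radii 20 vs 60."""
        vals = {}
        for r in (20, 60):
            spec = LesionSpec(base_radius=float(r), asymmetry_level=0.3,
                              border_irregularity=0.0, seed=99)
            _, mask, _ = generate_lesion_image(spec)
            vals[r] = (asymmetry_index(mask), compactness_index(mask))
        assert vals[20][0] == pytest.approx(vals[60][0], abs=0.05)
        assert vals[20][1] == pytest.approx(vals[60][1], abs=0.05)

    def test_translation_invariance_of_mask_features(self):
        spec = LesionSpec(base_radius=25, asymmetry_level=0.3,
                          border_irregularity=0.2, seed=17)
        _, mask, _ = generate_lesion_image(spec)
        moved = np.roll(np.roll(mask.pixels, 9, axis=0), -7, axis=1)
        assert area_and_holes(moved) == area_and_holes(mask)
        assert lesion_diameter(moved) == pytest.approx(lesion_diameter(mask))
        assert compactness_index(moved) == pytest.approx(
            compactness_index(mask)
        )
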