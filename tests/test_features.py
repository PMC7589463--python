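"""Radiomic features: count contracts, hand-computed values, brute-force
texture oracles and invariances."""

import itertools

import numpy as np
import pandas as pd
import pytest

from rimradiomics.core import ImageVolume, RoiMask
from rimradiomics.image_filters import filter_bank
from rimradiomics.radiomics_features import (FAMILY_COUNTS, FeatureConfig,
                                             discretise, extract_all,
                                             expanded_feature_names,
                                             histogram_features,
                                             morphology_features,
                                             statistical_features,
                                             texture_features)
from rimradiomics.radiomics_features.texture import (DIRECTIONS_13,
                                                     glcm_matrix,
                                                     glrlm_matrix,
                                                     glszm_matrix)
from rimradiomics.roi_geometry import resegment

from conftest import digital_sphere


# ------------------------------------------------------- brute-force oracles

def brute_glcm(grid, ng, d):
    m = np.zeros((ng, ng))
    shape = grid.shape
    for idx in np.ndindex(shape):
        if grid[idx] == 0:
            continue
        j = tuple(a + b for a, b in zip(idx, d))
        if all(0 <= j[k] < shape[k] for k in range(3)) and grid[j] > 0:
            m[grid[idx] - 1, grid[j] - 1] += 1
            m[grid[j] - 1, grid[idx] - 1] += 1
    return m


def brute_glrlm(grid, ng, d):
    """Enumerate maximal same-level runs along direction d."""
    shape = grid.shape
    runs = []
    for idx in np.ndindex(shape):
        if grid[idx] == 0:
            continue
        prev = tuple(a - b for a, b in zip(idx, d))
        if (all(0 <= prev[k] < shape[k] for k in range(3))
                and grid[prev] == grid[idx]):
            continue  # not a run start
        length, cur = 1, idx
        while True:
            nxt = tuple(a + b for a, b in zip(cur, d))
            if (all(0 <= nxt[k] < shape[k] for k in range(3))
                    and grid[nxt] == grid[idx]):
                length += 1
                cur = nxt
            else:
                break
        runs.append((grid[idx], length))
    max_len = max(l for _, l in runs)
    m = np.zeros((ng, max_len))
    for g, l in runs:
        m[g - 1, l - 1] += 1
    return m


def brute_zones(grid, ng):
    """26-connected same-level zones by BFS."""
    shape = grid.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    neigh = [d for d in itertools.product((-1, 0, 1), repeat=3)
             if d != (0, 0, 0)]
    for idx in np.ndindex(shape):
        if grid[idx] == 0 or seen[idx]:
            continue
        level, queue, size = grid[idx], [idx], 0
        seen[idx] = True
        while queue:
            cur = queue.pop()
            size += 1
            for d in neigh:
                j = tuple(a + b for a, b in zip(cur, d))
                if (all(0 <= j[k] < shape[k] for k in range(3))
                        and not seen[j] and grid[j] == level):
                    seen[j] = True
                    queue.append(j)
        zones.append((level, size))
    return sorted(zones)


# ------------------------------------------------------------------- counts

class TestCountContract:
    def test_family_counts(self):
        assert FAMILY_COUNTS == {"statistical": 18, "histogram": 38,
                                 "texture": 95, "morphology": 28}

    def test_expanded_total_is_1538(self):
        names = expanded_feature_names()
        assert len(names) == 1538
        assert len(set(names)) == 1538

    def test_member_function_output_sizes(self, small_roi_rng):
        vals = small_roi_rng.normal(size=64)
        assert len(statistical_features(vals)) == 18
        droi = discretise(vals, 8)
        mask = np.ones((4, 4, 4), dtype=bool)
        img = vals.reshape(4, 4, 4)
        assert len(histogram_features(droi, vals, img, mask, 1.0)) == 38
        assert len(texture_features(droi, mask)) == 95
        assert len(morphology_features(mask, img, 1.0)) == 28


# -------------------------------------------------------------- statistical

class TestStatistical:
    def test_hand_computed_example(self):
        f = statistical_features(np.array([1.0, 2.0, 3.0, 4.0]))
        assert f["mean"] == pytest.approx(2.5)
        assert f["variance"] == pytest.approx(1.25)  # population
        assert f["energy"] == pytest.approx(30.0)
        assert f["rms"] == pytest.approx(np.sqrt(7.5))
        assert f["range"] == pytest.approx(3.0)

    def test_constant_roi(self):
        f = statistical_features(np.full(10, 3.0))
        assert f["mean"] == 3.0
        assert f["variance"] == 0.0
        assert f["skewness"] == 0.0 and f["kurtosis"] == 0.0
        assert f["energy"] == pytest.approx(90.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            statistical_features(np.array([]))


# ---------------------------------------------------- discretise/histogram

class TestDiscretise:
    def test_constant_maps_to_level_one(self):
        d = discretise(np.full(5, 2.0), 32)
        assert np.all(d.levels == 1)

    def test_one_value_per_bin(self):
        d = discretise(np.arange(32.0), 32)
        assert np.array_equal(np.sort(d.levels), np.arange(1, 33))

    def test_four_values_four_bins(self):
        d = discretise(np.array([0.0, 10.0, 20.0, 30.0]), 4)
        assert np.array_equal(np.sort(d.levels), np.array([1, 2, 3, 4]))

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            discretise(np.arange(4.0), 1)


class TestHistogram:
    def test_two_level_entropy_and_uniformity(self):
        vals = np.array([1.0, 1.0, 2.0, 2.0])
        f = histogram_features(discretise(vals, 2), vals)
        assert f["ih_uniformity"] == pytest.approx(0.5)
        assert f["ih_entropy"] == pytest.approx(1.0)  # bits

    def test_constant_roi_degenerate_values(self):
        vals = np.full(8, 5.0)
        f = histogram_features(discretise(vals, 32), vals)
        assert f["ih_entropy"] == 0.0
        assert f["ih_uniformity"] == 1.0
        assert f["ivh_diff_v10_v90"] == 0.0
        assert f["ivh_diff_i10_i90"] == 0.0

    def test_peaks_with_spatial_context(self):
        img = np.zeros((15, 15, 15))
        img[7, 7, 7] = 100.0
        mask = np.ones((15, 15, 15), dtype=bool)
        f = histogram_features(discretise(img[mask], 8), img[mask],
                               img, mask, 1.0)
        # local peak = sphere mean at the bright voxel: 100 / n_sphere
        assert 0 < f["peak_local"] < 100.0
        assert f["peak_global"] >= f["peak_local"] - 1e-12


# ------------------------------------------------------------------ texture

class TestTextureOracles:
    def test_glcm_equals_brute_force_on_random_rois(self, small_roi_rng):
        for _ in range(3):
            grid = small_roi_rng.integers(0, 5, size=(4, 4, 4)).astype(int)
            ng = 4
            for d in DIRECTIONS_13:
                assert np.array_equal(glcm_matrix(grid, ng, d),
                                      brute_glcm(grid, ng, d)), d

    def test_glrlm_equals_brute_force_on_random_rois(self, small_roi_rng):
        for _ in range(3):
            grid = small_roi_rng.integers(0, 4, size=(4, 4, 4)).astype(int)
            ng = 3
            for d in DIRECTIONS_13:
                a = glrlm_matrix(grid, ng, d)
                b = brute_glrlm(grid, ng, d) if (grid > 0).any() else a
                # pad to common width
                w = max(a.shape[1], b.shape[1])
                a = np.pad(a, ((0, 0), (0, w - a.shape[1])))
                b = np.pad(b, ((0, 0), (0, w - b.shape[1])))
                assert np.array_equal(a, b), d

    def test_glszm_zone_sizes_match_bfs(self, small_roi_rng):
        grid = small_roi_rng.integers(0, 4, size=(4, 4, 4)).astype(int)
        m = glszm_matrix(grid, 3)
        zones = []
        for g in range(1, 4):
            for s in range(m.shape[1]):
                zones += [(g, s + 1)] * int(m[g - 1, s])
        assert sorted(zones) == brute_zones(grid, 3)

    def test_2x2_block_worked_example(self):
        grid = np.array([[[1], [2]], [[3], [4]]])
        m = glcm_matrix(grid, 4, (0, 1, 0))
        expected = np.zeros((4, 4))
        expected[0, 1] = expected[1, 0] = 1  # pair (1,2)
        expected[2, 3] = expected[3, 2] = 1  # pair (3,4)
        assert np.array_equal(m, expected)

    def test_constant_roi_degenerate_texture(self):
        vals = np.full(27, 9.0)
        mask = np.ones((3, 3, 3), dtype=bool)
        f = texture_features(discretise(vals, 32), mask)
        assert f["glcm_contrast"] == 0.0
        assert f["glcm_joint_max"] == 1.0
        assert f["ngtdm_coarseness"] == 1e6  # capped maximum

    def test_rotation_coherence(self, small_roi_rng):
        # 90-degree rotations permute the 13 directions: direction-averaged
        # features are invariant
        vals = small_roi_rng.normal(size=(5, 5, 5))
        mask = np.ones((5, 5, 5), dtype=bool)
        f0 = texture_features(discretise(vals[mask], 6), mask)
        rot = np.rot90(vals, k=1, axes=(0, 1))
        f1 = texture_features(discretise(rot[mask], 6), mask)
        for k in f0:
            assert f0[k] == pytest.approx(f1[k], rel=1e-9), k


# --------------------------------------------------------------- morphology

class TestMorphology:
    def test_sphere_is_spherical(self, sphere_r15):
        mask = sphere_r15.bool_array()
        img = np.full(mask.shape, 50.0)
        f = morphology_features(mask, img, 1.0)
        # marching cubes on a binary sphere overestimates the surface by
        # ~9% (staircase), which bounds sphericity below 1 accordingly
        assert 0.90 <= f["morph_sphericity"] <= 1.0
        analytic = 4.0 / 3.0 * np.pi * 15.0**3
        assert f["morph_vol_mesh"] == pytest.approx(analytic, rel=0.02)
        # corner-hull diameter: between 2R and 2R + sqrt(3)*spacing
        assert 30.0 <= f["morph_max_diameter"] <= 30.0 + np.sqrt(3)

    def test_cube_surface_and_diameter(self):
        mask = np.zeros((14, 14, 14), dtype=bool)
        mask[2:12, 2:12, 2:12] = True
        f = morphology_features(mask, np.ones(mask.shape), 1.0)
        # the chamfered marching-cubes mesh undershoots the sharp cube by
        # ~6%; the corner-hull diameter is exact
        assert f["morph_surface_area"] == pytest.approx(600.0, rel=0.08)
        assert f["morph_vol_mesh"] == pytest.approx(1000.0, rel=0.05)
        assert f["morph_max_diameter"] == pytest.approx(10 * np.sqrt(3),
                                                        abs=1e-9)

    def test_intensity_invariance_except_weighted_members(self, sphere_r15):
        mask = sphere_r15.bool_array()
        rng = np.random.default_rng(0)
        f0 = morphology_features(mask, rng.normal(size=mask.shape), 1.0)
        f1 = morphology_features(mask, rng.normal(size=mask.shape), 1.0)
        weighted = {"morph_integrated_intensity", "morph_moran_i",
                    "morph_geary_c", "morph_com_shift"}
        for k in f0:
            if k not in weighted:
                assert f0[k] == f1[k], k

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            morphology_features(np.zeros((3, 3, 3), dtype=bool),
                                np.zeros((3, 3, 3)), 1.0)


# ------------------------------------------------------------- extract_all

@pytest.fixture(scope="module")
def extraction(phantom_pair):
    image, mask = phantom_pair
    bank = filter_bank(image)
    df = extract_all(image, {"entire": mask}, bank=bank)
    return image, mask, bank, df


class TestExtractAll:
    def test_full_column_contract(self, extraction):
        _, _, _, df = extraction
        assert df.shape == (1, 1538)
        assert not df.isna().any().any()

    def test_deterministic(self, extraction):
        image, mask, bank, df = extraction
        df2 = extract_all(image, {"entire": mask}, bank=bank)
        pd.testing.assert_frame_equal(df, df2)

    def test_composition_consistency(self, extraction):
        image, mask, _, df = extraction
        reseg = resegment(image, mask)
        direct = statistical_features(image.values[reseg.bool_array()])
        for k, v in direct.items():
            assert df.iloc[0][f"base_stat_{k}"] == pytest.approx(v)

    def test_intensity_shift_moves_mean_not_levels(self, phantom_pair):
        image, mask = phantom_pair
        cfg = FeatureConfig(transforms=("base",),
                            families=("statistical", "histogram", "texture"))
        a = extract_all(image, {"entire": mask}, config=cfg)
        shifted = image.with_values(image.values + 25.0)
        b = extract_all(shifted, {"entire": mask}, config=cfg)
        assert b.iloc[0]["base_stat_mean"] == pytest.approx(
            a.iloc[0]["base_stat_mean"] + 25.0)
        # discretised-domain features are shift invariant (fixed bin number)
        for k in a.columns:
            if "_glcm_" in k or "_glrlm_" in k or k.endswith("ih_entropy"):
                assert b.iloc[0][k] == pytest.approx(a.iloc[0][k],
                                                     rel=1e-9), k

    def test_translation_invariance(self, phantom_pair):
        image, mask = phantom_pair
        cfg = FeatureConfig(transforms=("base",))
        a = extract_all(image, {"entire": mask}, config=cfg)
        tv = np.roll(image.values, 2, axis=1)
        tm = np.roll(mask.values, 2, axis=1)
        b = extract_all(ImageVolume(tv), {"entire": RoiMask(tm)}, config=cfg)
        for k in a.columns:
            assert b.iloc[0][k] == pytest.approx(a.iloc[0][k], rel=1e-6,
                                                 abs=1e-9), k

    def test_empty_resegmented_roi_omitted(self, phantom_pair):
        image, mask = phantom_pair
        air = ImageVolume(np.full(image.shape, -1000.0))
        df = extract_all(air, {"entire": mask},
                         config=FeatureConfig(transforms=("base",)))
        assert len(df) == 0
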