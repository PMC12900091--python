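"""Z-score normalization, percentile trimming, RGB-like extraction, ROI views."""

import numpy as np
import pytest

import retphasor as rp
from retphasor.preprocess import TrimPolicy, apply_roi, extract_rgb_like, \
    trim_percentiles, zscore_bands


def cube_from(vals, bands, stage="reflectance"):
    return rp.SpectralCube(np.asarray(vals, float), bands, stage=stage)


def full_scope(cube):
    return np.ones(cube.pixels.shape[:2], bool)


class TestZscore:
    def test_hand_worked_three_values(self, bands3):
        # band values {1,2,3}: mu=2, population sigma=sqrt(2/3)
        vals = np.zeros((3, 1, 3))
        vals[:, 0, :] = [[1, 1, 1], [2, 2, 2], [3, 3, 3]]
        z = zscore_bands(cube_from(vals, bands3), full_scope(cube_from(vals, bands3)))
        expected = np.array([-1.22474487, 0.0, 1.22474487])
        assert np.allclose(z.pixels[:, 0, 0], expected, atol=1e-8)
        assert z.stage == "zscored"

    def test_each_band_standardized(self, rng, bands12):
        cube = cube_from(rng.uniform(0, 1, (12, 11, 12)), bands12)
        z = zscore_bands(cube, full_scope(cube))
        flat = z.pixels.reshape(-1, 12)
        assert np.all(np.abs(flat.mean(axis=0)) < 1e-8)
        assert np.all(np.abs(flat.std(axis=0) - 1) < 1e-8)

    def test_idempotent_on_standardized_input(self, rng, bands3):
        cube = cube_from(rng.normal(size=(10, 10, 3)), bands3)
        z1 = zscore_bands(cube, full_scope(cube))
        z1_as_refl = rp.SpectralCube(z1.pixels, bands3, stage="reflectance")
        z2 = zscore_bands(z1_as_refl, full_scope(z1))
        assert np.allclose(z1.pixels, z2.pixels, atol=1e-12)

    def test_constant_band_rejected_with_band_name(self, rng, bands3):
        vals = rng.uniform(0, 1, (5, 5, 3))
        vals[:, :, 1] = 0.4
        with pytest.raises(ValueError, match="595"):
            zscore_bands(cube_from(vals, bands3), np.ones((5, 5), bool))

    def test_scope_dependence(self, rng, bands3):
        """Standardizing globally then restricting differs from restricting first."""
        vals = rng.uniform(0, 1, (8, 8, 3))
        vals[:4] += 2.0  # two distinct regions
        cube = cube_from(vals, bands3)
        roi = np.zeros((8, 8), bool)
        roi[:4] = True
        z_global = zscore_bands(cube, full_scope(cube))
        z_local = zscore_bands(cube, roi)
        assert not np.allclose(z_global.pixels[roi], z_local.pixels[roi], atol=1e-3)


class TestTrim:
    def _zcube(self, vals, bands):
        return rp.SpectralCube(np.asarray(vals, float), bands, stage="zscored")

    def test_ten_distinct_values_trim_two_each_side(self, bands3):
        # brute-force oracle: sort, check which values fall strictly outside
        # the interpolated 20th/80th percentiles
        vals = np.zeros((10, 1, 3))
        base = np.array([5, 1, 9, 3, 7, 0, 8, 2, 6, 4], float)
        for b in range(3):
            vals[:, 0, b] = base
        cube = self._zcube(vals, bands3)
        out = trim_percentiles(cube, TrimPolicy(20, 20), np.ones((10, 1), bool))
        lo, hi = np.percentile(base, [20, 80])
        expect_invalid = (base < lo) | (base > hi)
        assert expect_invalid.sum() == 4  # 2 lowest + 2 highest
        assert np.array_equal(~out.valid[:, 0], expect_invalid)

    def test_zero_policy_is_noop(self, rng, bands3):
        cube = self._zcube(rng.normal(size=(6, 6, 3)), bands3)
        out = trim_percentiles(cube, TrimPolicy(0, 0), np.ones((6, 6), bool))
        assert out.valid.all()

    def test_ties_not_trimmed_under_strict_inequality(self, bands3):
        cube = self._zcube(np.full((5, 5, 3), 0.7), bands3)
        out = trim_percentiles(cube, TrimPolicy(20, 20), np.ones((5, 5), bool))
        assert out.valid.all()

    def test_survivor_spectra_bitwise_unchanged(self, rng, bands3):
        # 3 bands: the union rule leaves plenty of survivors on iid values
        cube = self._zcube(rng.normal(size=(20, 20, 3)), bands3)
        out = trim_percentiles(cube, TrimPolicy(), np.ones((20, 20), bool))
        assert np.array_equal(out.pixels, cube.pixels)
        assert out.valid.sum() < cube.valid.sum()  # something was trimmed

    def test_union_rule_across_bands(self, bands3):
        # pixel extreme in only one band is still removed
        vals = np.zeros((10, 1, 3))
        vals[:, 0, :] = np.linspace(-1, 1, 10)[:, None]
        vals[4, 0, 2] = 50.0  # outlier in third band only
        cube = self._zcube(vals, bands3)
        out = trim_percentiles(cube, TrimPolicy(10, 10), np.ones((10, 1), bool))
        assert not out.valid[4, 0]

    def test_invalid_policy_rejected(self):
        with pytest.raises(ValueError):
            TrimPolicy(60, 10)


class TestRGBExtraction:
    def test_twelve_to_three_bands(self, rng, bands12):
        cube = cube_from(rng.uniform(0, 1, (4, 4, 12)), bands12)
        rgb = extract_rgb_like(cube)
        assert rgb.bands.centers == (471.0, 595.0, 732.0)
        idx = [bands12.index_of(c) for c in (471, 595, 732)]
        assert np.array_equal(rgb.pixels, cube.pixels[:, :, idx])

    def test_idempotent_on_rgb_cube(self, rng, bands3):
        cube = cube_from(rng.uniform(0, 1, (4, 4, 3)), bands3)
        rgb = extract_rgb_like(cube)
        assert np.array_equal(rgb.pixels, cube.pixels)

    def test_missing_band_listed(self, rng):
        bands = rp.BandSet((471.0, 595.0, 865.0), (20.0,) * 3)
        cube = cube_from(rng.uniform(0, 1, (4, 4, 3)), bands)
        with pytest.raises(ValueError, match="732"):
            extract_rgb_like(cube)

    def test_commutes_with_roi(self, rng, bands12):
        cube = cube_from(rng.uniform(0, 1, (6, 6, 12)), bands12)
        roi = rp.ROIMask("macula", rng.random((6, 6)) > 0.5)
        a = apply_roi(extract_rgb_like(cube), roi).spectra
        idx = [cube.bands.index_of(c) for c in (471, 595, 732)]
        b = apply_roi(cube, roi).spectra[:, idx]
        assert np.array_equal(a, b)


class TestApplyROI:
    def test_full_mask_returns_all_pixels(self, rng, bands3):
        cube = cube_from(rng.uniform(0, 1, (5, 4, 3)), bands3)
        ps = apply_roi(cube, np.ones((5, 4), bool))
        assert ps.n_pixels == 20

    def test_validity_intersection(self, rng, bands3):
        cube = cube_from(rng.uniform(0, 1, (5, 4, 3)), bands3)
        cube.valid[0, 0] = cube.valid[1, 1] = False
        roi = np.zeros((5, 4), bool)
        roi[0, 0] = roi[1, 1] = roi[2, 2] = roi[3, 3] = roi[4, 0] = True
        ps = apply_roi(cube, roi)
        assert ps.n_pixels == 3  # 5 in ROI, 2 invalidated

    def test_empty_intersection_rejected(self, rng, bands3):
        cube = cube_from(rng.uniform(0, 1, (4, 4, 3)), bands3)
        cube.valid[:] = False
        with pytest.raises(ValueError, match="empty"):
            apply_roi(cube, np.ones((4, 4), bool))
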