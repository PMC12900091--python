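"""Spectral phasor transform: closed forms, oracle equivalence, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import retphasor as rp
from retphasor.phasor import band_average_features, harmonics_available, \
    phasor_transform, summarize_phasor


def direct_phasor_oracle(spectrum, k):
    """Independent brute-force evaluation of the phasor sums (band-index phase)."""
    n = len(spectrum)
    num_g = num_s = den = 0.0
    for m in range(n):
        num_g += spectrum[m] * np.cos(2 * np.pi * k * m / n)
        num_s += spectrum[m] * np.sin(2 * np.pi * k * m / n)
        den += spectrum[m]
    return num_g / den, num_s / den


def cube_of(spectra, bands, stage="reflectance"):
    """Stack a list of spectra into a 1×N cube."""
    arr = np.asarray(spectra, float)[None, :, :]
    return rp.SpectralCube(arr, bands, stage=stage)


class TestHarmonics:
    def test_twelve_bands_give_harmonics_1_to_11(self):
        assert harmonics_available(12) == list(range(1, 12))

    @pytest.mark.parametrize("n,expected", [(3, [1, 2]), (2, [1])])
    def test_small_band_counts(self, n, expected):
        assert harmonics_available(n) == expected

    def test_fewer_than_two_bands_rejected(self):
        with pytest.raises(ValueError):
            harmonics_available(1)

    def test_out_of_range_harmonic_rejected(self, rng, bands12):
        cube = cube_of(rng.uniform(0.1, 1, (4, 12)), bands12)
        for bad_k in (0, 12):
            with pytest.raises(ValueError):
                phasor_transform(cube, bad_k)


class TestClosedForms:
    def test_flat_spectrum_maps_to_origin(self, bands12):
        cube = cube_of(np.full((3, 12), 0.7), bands12)
        for k in harmonics_available(12):
            f = phasor_transform(cube, k)
            assert np.allclose(f.g, 0, atol=1e-12) and np.allclose(f.s, 0, atol=1e-12)

    @pytest.mark.parametrize("m", [0, 3, 11])
    @pytest.mark.parametrize("k", [1, 2, 5])
    def test_delta_spectrum_lands_on_unit_circle(self, bands12, m, k):
        spec = np.zeros(12)
        spec[m] = 2.5
        f = phasor_transform(cube_of([spec], bands12), k)
        phi = 2 * np.pi * k * m / 12
        assert np.isclose(f.g[0, 0], np.cos(phi), atol=1e-12)
        assert np.isclose(f.s[0, 0], np.sin(phi), atol=1e-12)

    def test_matches_direct_sum_oracle(self, rng, bands12):
        spectra = rng.uniform(0.01, 1.0, size=(1000, 12))
        cube = cube_of(spectra, bands12)
        for k in (1, 4, 11):
            f = phasor_transform(cube, k)
            for i in range(0, 1000, 97):
                g0, s0 = direct_phasor_oracle(spectra[i], k)
                assert abs(f.g[0, i] - g0) < 1e-12
                assert abs(f.s[0, i] - s0) < 1e-12

    def test_fft_path_matches_direct(self, rng, bands12):
        cube = cube_of(rng.uniform(0.01, 1.0, (1000, 12)), bands12)
        for k in (1, 6, 11):
            fd = phasor_transform(cube, k, method="direct")
            ff = phasor_transform(cube, k, method="fft")
            assert np.allclose(fd.g, ff.g, atol=1e-10)
            assert np.allclose(fd.s, ff.s, atol=1e-10)


class TestInvariants:
    def test_unit_disk_bound_for_nonnegative_spectra(self, rng, bands12):
        cube = cube_of(rng.uniform(0, 1, (10000, 12)) ** 2, bands12)
        for k in (1, 5, 11):
            f = phasor_transform(cube, k)
            r2 = f.g[f.valid] ** 2 + f.s[f.valid] ** 2
            assert np.all(r2 <= 1 + 1e-12)

    def test_scale_invariance(self, rng, bands12):
        spectra = rng.uniform(0.05, 1, (50, 12))
        f1 = phasor_transform(cube_of(spectra, bands12), 3)
        f2 = phasor_transform(cube_of(37.5 * spectra, bands12), 3)
        assert np.allclose(f1.g, f2.g, atol=1e-12)
        assert np.allclose(f1.s, f2.s, atol=1e-12)

    def test_mixing_linearity(self, rng, bands12):
        """phasor(aA+bB) is the intensity-weighted mean of the two phasors."""
        A = rng.uniform(0.01, 1, (1000, 12))
        B = rng.uniform(0.01, 1, (1000, 12))
        a, b = 0.7, 1.9
        k = 1
        fA = phasor_transform(cube_of(A, bands12), k)
        fB = phasor_transform(cube_of(B, bands12), k)
        fM = phasor_transform(cube_of(a * A + b * B, bands12), k)
        wA = a * A.sum(axis=1)
        wB = b * B.sum(axis=1)
        g_mix = (wA * fA.g[0] + wB * fB.g[0]) / (wA + wB)
        s_mix = (wA * fA.s[0] + wB * fB.s[0]) / (wA + wB)
        assert np.allclose(fM.g[0], g_mix, atol=1e-12)
        assert np.allclose(fM.s[0], s_mix, atol=1e-12)

    def test_conjugate_symmetry(self, rng, bands12):
        spectra = rng.uniform(0.01, 1, (100, 12))
        for k in (1, 3, 5):
            fk = phasor_transform(cube_of(spectra, bands12), k)
            fnk = phasor_transform(cube_of(spectra, bands12), 12 - k)
            assert np.allclose(fk.g, fnk.g, atol=1e-12)
            assert np.allclose(fk.s, -fnk.s, atol=1e-12)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(1e-3, 1.0), min_size=12, max_size=12),
           st.floats(1e-3, 1e3), st.integers(1, 11))
    def test_scale_invariance_property(self, spectrum, c, k):
        bands = rp.BandSet.default_msi()
        f1 = phasor_transform(cube_of([spectrum], bands), k)
        f2 = phasor_transform(cube_of([np.asarray(spectrum) * c], bands), k)
        assert np.allclose(f1.g, f2.g, atol=1e-9)
        assert np.allclose(f1.s, f2.s, atol=1e-9)

    def test_near_zero_denominator_invalidated(self, bands3):
        vals = np.array([[[1.0, -1.0, 0.0], [0.5, 0.2, 0.3]]])
        cube = rp.SpectralCube(vals, bands3, stage="zscored")
        f = phasor_transform(cube, 1, eps=1e-6)
        assert not f.valid[0, 0] and f.valid[0, 1]

    def test_wavelength_axis_uses_bandwidth_weights(self, rng):
        # equal index spacing but unequal wavelength spacing: conventions differ
        bands = rp.BandSet((400.0, 420.0, 700.0), (10.0, 10.0, 40.0))
        cube = cube_of(rng.uniform(0.1, 1, (20, 3)), bands)
        fi = phasor_transform(cube, 1, phase_axis="index")
        fw = phasor_transform(cube, 1, phase_axis="wavelength")
        assert not np.allclose(fi.g, fw.g, atol=1e-3)


class TestSummaries:
    def _field(self, g, s):
        g = np.asarray(g, float)[None, :]
        s = np.asarray(s, float)[None, :]
        return rp.PhasorField(g, s, 1, np.ones_like(g, bool))

    def test_identical_pixels_zero_dispersion(self):
        f = self._field([0.3] * 5, [-0.1] * 5)
        summ = summarize_phasor(f, np.ones((1, 5), bool))
        assert summ.g_avg == pytest.approx(0.3)
        assert summ.s_avg == pytest.approx(-0.1)
        assert summ.std == pytest.approx(0.0)

    def test_two_point_hand_case(self):
        # pixels (0,0) and (1,0): mean (0.5,0), var_g=0.25 -> std=0.5
        f = self._field([0.0, 1.0], [0.0, 0.0])
        summ = summarize_phasor(f, np.ones((1, 2), bool))
        assert summ.g_avg == pytest.approx(0.5)
        assert summ.s_avg == pytest.approx(0.0)
        assert summ.std == pytest.approx(0.5)
        assert summ.n_pixels == 2

    def test_mixture_mean_is_weighted_mean_of_parts(self, rng):
        g = rng.normal(size=40)
        s = rng.normal(size=40)
        f = self._field(g, s)
        left = np.zeros((1, 40), bool)
        left[0, :15] = True
        right = ~left
        full = summarize_phasor(f, np.ones((1, 40), bool), with_std=False)
        a = summarize_phasor(f, left, with_std=False)
        b = summarize_phasor(f, right, with_std=False)
        g_w = (a.n_pixels * a.g_avg + b.n_pixels * b.g_avg) / 40
        s_w = (a.n_pixels * a.s_avg + b.n_pixels * b.s_avg) / 40
        assert full.g_avg == pytest.approx(g_w, abs=1e-12)
        assert full.s_avg == pytest.approx(s_w, abs=1e-12)

    def test_empty_scope_rejected(self):
        f = self._field([0.1], [0.2])
        with pytest.raises(ValueError):
            summarize_phasor(f, np.zeros((1, 1), bool))


class TestBandAverages:
    def test_constant_cube(self, bands12):
        cube = rp.SpectralCube(np.full((3, 3, 12), 0.4), bands12, stage="reflectance")
        v = band_average_features(cube, np.ones((3, 3), bool))
        assert v.shape == (12,) and np.allclose(v, 0.4)

    def test_vector_lengths_match_band_count(self, rng, bands12, bands3):
        for bands in (bands12, bands3):
            cube = rp.SpectralCube(rng.uniform(0, 1, (4, 4, bands.n)), bands,
                                   stage="reflectance")
            assert band_average_features(cube, np.ones((4, 4), bool)).shape == (bands.n,)

    def test_two_pixel_mean(self, bands3):
        vals = np.zeros((2, 1, 3))
        vals[0, 0] = [0.2, 0.2, 0.2]
        vals[1, 0] = [0.4, 0.4, 0.4]
        cube = rp.SpectralCube(vals, bands3, stage="reflectance")
        assert np.allclose(band_average_features(cube, np.ones((2, 1), bool)), 0.3)
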