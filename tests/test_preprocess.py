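"""Tests for I/O, wavelet preprocessing, normalization, splitting and CRI."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chilispec import (
    MinMaxNormalizer,
    SpectrumTable,
    compute_cri,
    cwt_preprocess,
    extract_rgb,
    ks_two_sample,
    read_spectra,
    stratified_split,
    write_spectra,
)
from chilispec.preprocess import wavelet_kernel
from chilispec.synthetic import DEFAULT_WAVELENGTHS_NM

from oracles import cwt_bruteforce, ks_D_bruteforce


def table_from(values, wavelengths=DEFAULT_WAVELENGTHS_NM):
    values = np.atleast_2d(values)
    ids = [f"S{i}" for i in range(values.shape[0])]
    return SpectrumTable(ids, np.asarray(wavelengths, float), values)


class TestSpectraIO:
    def test_roundtrip_preserves_matrix(self, tmp_path):
        rng = np.random.default_rng(0)
        t = table_from(rng.random((3, 19)))
        p = tmp_path / "s.csv"
        write_spectra(t, p)
        back = read_spectra(p)
        assert np.allclose(back.values, t.values, atol=1e-12)
        assert back.sample_ids == t.sample_ids
        assert np.array_equal(back.wavelengths_nm, t.wavelengths_nm)

    def test_missing_sample_id_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("id,400,500\nA,0.1,0.2\n")
        with pytest.raises(ValueError, match="missing sample_id"):
            read_spectra(p)

    def test_unsorted_wavelength_columns(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("sample_id,500,400\nA,0.1,0.2\n")
        with pytest.raises(ValueError, match="wavelengths not increasing"):
            read_spectra(p)

    def test_duplicate_sample_id(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("sample_id,400,500\nA,0.1,0.2\nA,0.3,0.4\n")
        with pytest.raises(ValueError, match="duplicated sample id"):
            read_spectra(p)

    def test_non_numeric_cell(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("sample_id,400,500\nA,oops,0.2\n")
        with pytest.raises(ValueError):
            read_spectra(p)


class TestWaveletPreprocess:
    def test_constant_spectrum_maps_to_zero(self):
        t = table_from(np.full((2, 19), 0.42))
        out = cwt_preprocess(t, scale=3.0)
        assert np.max(np.abs(out.values)) < 1e-8

    def test_additive_offset_removed_exactly(self):
        rng = np.random.default_rng(1)
        x = rng.random((1, 19))
        a = cwt_preprocess(table_from(x))
        b = cwt_preprocess(table_from(x + 0.3))
        assert np.allclose(a.values, b.values, atol=1e-12)

    def test_matches_bruteforce_reflected_convolution(self):
        rng = np.random.default_rng(2)
        spike = np.zeros((1, 19))
        spike[0, 9] = 1.0
        cases = [spike, rng.random((3, 19))]
        kern = wavelet_kernel(3.0, "mexh")
        for vals in cases:
            ours = cwt_preprocess(table_from(vals), scale=3.0).values
            ref = cwt_bruteforce(vals, kern)
            assert np.allclose(ours, ref, atol=1e-12)

    def test_translation_equivariance_away_from_boundary(self):
        # use a grid long enough that the kernel support (half-width 24 at
        # scale 3) stays clear of the boundaries in the compared window
        rng = np.random.default_rng(3)
        L = 80
        wl = np.linspace(365, 970, L)
        bump = np.zeros(L)
        bump[38:41] = rng.random(3)
        a = cwt_preprocess(table_from(bump, wl)).values[0]
        b = cwt_preprocess(table_from(np.roll(bump, 1), wl)).values[0]
        assert np.allclose(a[30:46], b[31:47], atol=1e-12)

    def test_invalid_scale(self):
        with pytest.raises(ValueError):
            cwt_preprocess(table_from(np.random.random((1, 19))), scale=0)

    def test_too_few_bands(self):
        with pytest.raises(ValueError):
            cwt_preprocess(table_from(np.random.random((1, 4)),
                                      wavelengths=[400, 500, 600, 700]))


class TestMinMaxNormalizer:
    def test_basic_column(self):
        X = np.array([[1.0], [2.0], [3.0]])
        out = MinMaxNormalizer().fit_transform(X)
        assert np.allclose(out[:, 0], [0, 0.5, 1])

    def test_constant_column_maps_to_half(self):
        X = np.array([[5.0, 1.0], [5.0, 2.0]])
        out = MinMaxNormalizer().fit_transform(X)
        assert np.allclose(out[:, 0], 0.5)

    def test_heldout_beyond_train_max_not_clipped(self):
        norm = MinMaxNormalizer().fit(np.array([[0.0], [1.0]]))
        assert norm.transform(np.array([[2.0]]))[0, 0] == pytest.approx(2.0)


class TestStratifiedSplit:
    def test_study_scale_counts(self):
        y = np.random.default_rng(4).lognormal(0, 0.9, 159)
        sp = stratified_split(y, n_test=33, n_bins=5, seed=0)
        assert sp.calibration_mask.sum() == 126
        assert sp.test_mask.sum() == 33
        folds = sp.loocv_fold[sp.calibration_mask]
        assert sorted(folds) == list(range(126))

    def test_deterministic_under_seed(self):
        y = np.random.default_rng(5).random(100)
        a = stratified_split(y, 20, 5, seed=9)
        b = stratified_split(y, 20, 5, seed=9)
        assert np.array_equal(a.labels, b.labels)

    def test_per_stratum_fraction_balanced(self):
        y = np.random.default_rng(6).random(1000)
        sp = stratified_split(y, n_test=200, n_bins=5, seed=1)
        qs = np.quantile(y, [0.2, 0.4, 0.6, 0.8])
        strata = np.digitize(y, qs)
        for b in range(5):
            frac = sp.test_mask[strata == b].mean()
            assert abs(frac - 0.2) <= 0.02

    def test_n_test_below_bins_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(np.random.random(50), n_test=3, n_bins=5, seed=0)


class TestKS:
    def test_identical_samples(self):
        d, _ = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == pytest.approx(0.0)

    def test_disjoint_supports(self):
        d, p = ks_two_sample([0, 1], [10, 11])
        assert d == pytest.approx(1.0)

    def test_half_overlap_enumerated(self):
        d, _ = ks_two_sample([1, 2], [1.5, 2.5])
        assert d == pytest.approx(0.5)

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            na, nb = rng.integers(2, 50, 2)
            a, b = rng.normal(0, 1, na), rng.normal(0.3, 1.2, nb)
            d, _ = ks_two_sample(a, b)
            assert d == pytest.approx(ks_D_bruteforce(a, b), abs=1e-12)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([1.0], [1.0, 2.0])


class TestCRI:
    def test_equal_bands(self):
        assert compute_cri(0.5, 0.5, 0.5) == pytest.approx(
            0.4 + 0.3 + 0.0 + 0.1 / 3, abs=1e-9)

    def test_hand_arithmetic_example(self):
        val = compute_cri(0.6, 0.3, 0.2)
        expected = 0.8 + 0.9 + 0.2 * (0.3 / 0.9) + 0.1 * (0.6 / 1.1)
        assert val == pytest.approx(expected, abs=1e-9)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.01, 1), st.floats(0.01, 1), st.floats(0.01, 1),
           st.floats(0.1, 10))
    def test_scale_invariance(self, r, g, b, k):
        assert compute_cri(k * r, k * g, k * b) == pytest.approx(
            compute_cri(r, g, b), rel=1e-9)

    def test_monotone_in_red(self):
        grid = np.linspace(0.1, 0.9, 20)
        vals = compute_cri(grid, 0.4, 0.3)
        assert np.all(np.diff(vals) > 0)

    def test_nonpositive_band_rejected(self):
        with pytest.raises(ValueError, match="non-positive band"):
            compute_cri(0.5, 0.0, 0.5)


class TestExtractRGB:
    def test_default_windows_average(self):
        rng = np.random.default_rng(8)
        t = table_from(rng.random((4, 19)))
        R, G, B = extract_rgb(t)
        wl = np.asarray(DEFAULT_WAVELENGTHS_NM)
        r_cols = np.isin(wl, [630, 645, 660])
        assert np.allclose(R, t.values[:, r_cols].mean(axis=1))

    def test_single_band_mapping(self):
        rng = np.random.default_rng(9)
        t = table_from(rng.random((2, 19)))
        wl = np.asarray(DEFAULT_WAVELENGTHS_NM)
        R, G, B = extract_rgb(t, {"R": (645, 645), "G": (540, 540), "B": (450, 450)})
        assert np.allclose(R, t.values[:, wl == 645][:, 0])
        assert np.allclose(B, t.values[:, wl == 450][:, 0])

    def test_flat_spectrum_gives_equal_bands(self):
        t = table_from(np.full((1, 19), 0.4))
        R, G, B = extract_rgb(t)
        assert R[0] == pytest.approx(G[0]) == pytest.approx(B[0]) == pytest.approx(0.4)

    def test_empty_window_rejected(self):
        t = table_from(np.random.random((1, 19)))
        with pytest.raises(ValueError, match="no bands"):
            extract_rgb(t, {"R": (700, 710), "G": (515, 570), "B": (430, 470)})
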