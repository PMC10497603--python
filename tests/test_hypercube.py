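"""Calibration, Savitzky-Golay smoothing, and cube I/O round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from specband import io
from specband.hypercube import (HyperCube, RawFrames, SGConfig,
                                ShapeMismatchError, calibrate_reflectance,
                                smooth_savitzky_golay)

WL9 = np.linspace(400, 700, 9)


def _frames(sample, dark, white, wl=None):
    return RawFrames(sample, dark, white,
                     wl if wl is not None else np.linspace(400, 700,
                                                           sample.shape[2]))


class TestCalibration:
    def test_white_equals_sample_gives_unit_reflectance(self, rng):
        white = rng.uniform(100, 200, size=(3, 4, 5))
        dark = np.zeros_like(white)
        cube = calibrate_reflectance(_frames(white, dark, white))
        assert np.allclose(cube.reflectance, 1.0)

    def test_sample_equals_dark_gives_zero_reflectance(self, rng):
        dark = rng.uniform(5, 10, size=(3, 4, 5))
        white = dark + 50
        cube = calibrate_reflectance(_frames(dark, dark, white))
        assert np.allclose(cube.reflectance, 0.0)

    def test_matches_scalar_loop_oracle(self, rng):
        s = rng.uniform(0, 100, size=(2, 2, 3))
        d = rng.uniform(0, 5, size=(2, 2, 3))
        w = rng.uniform(50, 150, size=(2, 2, 3))
        cube = calibrate_reflectance(_frames(s, d, w))
        for i in range(2):
            for j in range(2):
                for k in range(3):
                    expect = (s[i, j, k] - d[i, j, k]) / (w[i, j, k] - d[i, j, k])
                    assert cube.reflectance[i, j, k] == pytest.approx(
                        expect, abs=1e-12)

    def test_scale_invariance(self, rng):
        s = rng.uniform(10, 100, size=(2, 3, 4))
        d = rng.uniform(0, 5, size=(2, 3, 4))
        w = rng.uniform(120, 200, size=(2, 3, 4))
        r1 = calibrate_reflectance(_frames(s, d, w)).reflectance
        c = 7.31
        r2 = calibrate_reflectance(_frames(c * s, c * d, c * w)).reflectance
        assert np.allclose(r1, r2, atol=1e-12)

    def test_degenerate_white_pixels_flagged_not_nan(self, rng):
        s = rng.uniform(10, 100, size=(2, 2, 3))
        d = np.full((2, 2, 3), 5.0)
        w = d + 50
        w[0, 0, 1] = d[0, 0, 1]  # white == dark at one entry
        cube = calibrate_reflectance(_frames(s, d, w))
        assert not cube.valid[0, 0, 1]
        assert np.isfinite(cube.reflectance).all()

    def test_shape_mismatch_names_axis(self, rng):
        s = rng.uniform(size=(2, 3, 4))
        with pytest.raises(ShapeMismatchError, match="axis"):
            _frames(s, np.zeros((2, 3, 5)), np.ones((2, 3, 4)),
                    wl=np.linspace(400, 700, 4))

    def test_all_invalid_cube_raises(self):
        d = np.full((2, 2, 2), 5.0)
        with pytest.raises(ValueError, match="invalid"):
            calibrate_reflectance(_frames(d + 1, d, d,
                                          wl=np.array([400.0, 500.0])))

    def test_wavelengths_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            _frames(np.ones((1, 1, 3)), np.zeros((1, 1, 3)),
                    np.full((1, 1, 3), 2.0), wl=np.array([500.0, 400.0, 600.0]))


def _sg_window_ls_oracle(series, window, order):
    """Fit a degree-`order` polynomial in each centered window, evaluate
    at the center; mirror-pad the edges.  Independent of the implementation."""
    half = (window - 1) // 2
    padded = np.concatenate([series[1:half + 1][::-1], series,
                             series[-half - 1:-1][::-1]])
    out = np.empty_like(series, dtype=float)
    for i in range(len(series)):
        win = padded[i:i + window]
        coef = np.polynomial.polynomial.polyfit(
            np.arange(-half, half + 1), win, order)
        out[i] = coef[0]
    return out


class TestSavitzkyGolay:
    def test_constant_spectrum_unchanged(self):
        cube = HyperCube(np.full((2, 2, 15), 3.7), np.arange(15) + 400.0)
        sm = smooth_savitzky_golay(cube, SGConfig(5, 2))
        assert np.allclose(sm.reflectance, 3.7, atol=1e-12)
        assert sm.smoothed

    def test_linear_spectrum_interior_unchanged(self):
        wl = np.arange(20) + 400.0
        spec = 0.01 * wl - 2.0
        cube = HyperCube(np.tile(spec, (2, 2, 1)), wl)
        sm = smooth_savitzky_golay(cube, SGConfig(5, 2))
        assert np.allclose(sm.reflectance[:, :, 2:-2], spec[2:-2], atol=1e-10)

    def test_known_quadratic_window_coefficients(self):
        assert np.allclose(SGConfig(5, 2).coefficients,
                           np.array([-3, 12, 17, 12, -3]) / 35.0)

    def test_matches_per_window_least_squares_oracle(self, rng):
        series = rng.normal(size=10)
        cube = HyperCube(series.reshape(1, 1, -1), np.arange(10) + 400.0)
        sm = smooth_savitzky_golay(cube, SGConfig(5, 2))
        oracle = _sg_window_ls_oracle(series, 5, 2)
        assert np.allclose(sm.reflectance[0, 0], oracle, atol=1e-10)

    def test_linearity(self, rng):
        wl = np.arange(400.0, 430.0)
        x = rng.normal(size=(1, 1, 30))
        y = rng.normal(size=(1, 1, 30))
        cfg = SGConfig(7, 3)
        sm = lambda arr: smooth_savitzky_golay(
            HyperCube(arr, wl), cfg).reflectance
        assert np.allclose(sm(2.0 * x + 0.5 * y), 2.0 * sm(x) + 0.5 * sm(y),
                           atol=1e-10)

    @settings(derandomize=True, max_examples=25)
    @given(window=st.integers(1, 7).map(lambda k: 2 * k + 1),
           order=st.integers(0, 4))
    def test_coefficients_sum_to_one(self, window, order):
        if order >= window:
            return
        assert np.sum(SGConfig(window, order).coefficients) == pytest.approx(
            1.0, abs=1e-10)

    def test_window_longer_than_spectrum_raises(self):
        cube = HyperCube(np.ones((1, 1, 5)), np.arange(5) + 400.0)
        with pytest.raises(ValueError, match="window"):
            smooth_savitzky_golay(cube, SGConfig(7, 2))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            SGConfig(6, 2)

    def test_double_smoothing_rejected(self):
        cube = HyperCube(np.ones((1, 1, 15)), np.arange(15) + 400.0,
                         smoothed=True)
        with pytest.raises(ValueError, match="already"):
            smooth_savitzky_golay(cube)


class TestCubeIO:
    def test_hdf5_round_trip(self, rng, tmp_path):
        cube = HyperCube(rng.uniform(size=(3, 4, 6)),
                         np.linspace(400, 700, 6), smoothed=True)
        path = str(tmp_path / "cube.h5")
        io.write_cube(cube, path)
        back = io.read_cube(path)
        assert np.array_equal(back.reflectance, cube.reflectance)
        assert np.array_equal(back.wavelengths, cube.wavelengths)
        assert back.smoothed

    @pytest.mark.parametrize("interleave", ["bsq", "bil", "bip"])
    def test_envi_round_trip(self, rng, tmp_path, interleave):
        cube = HyperCube(
            rng.uniform(size=(3, 4, 5)).astype(np.float32).astype(float),
            np.linspace(400, 700, 5))
        path = str(tmp_path / "cube.hdr")
        io.write_envi(cube, path, interleave=interleave)
        back = io.read_envi(path)
        assert np.allclose(back.reflectance, cube.reflectance)
        assert np.allclose(back.wavelengths, cube.wavelengths)

    def test_envi_out_of_order_bands_sorted(self, rng, tmp_path):
        data = rng.uniform(size=(2, 2, 3)).astype(np.float32)
        path = tmp_path / "scrambled.hdr"
        data.transpose(2, 0, 1).tofile(tmp_path / "scrambled.img")
        path.write_text(
            "ENVI\nsamples = 2\nlines = 2\nbands = 3\ndata type = 4\n"
            "interleave = bsq\nwavelength = {600, 400, 500}\n")
        back = io.read_envi(str(path))
        assert np.array_equal(back.wavelengths, [400.0, 500.0, 600.0])
        # data must be permuted consistently with the wavelength sort
        assert np.allclose(back.reflectance[..., 0], data[..., 1])
        assert np.allclose(back.reflectance[..., 2], data[..., 0])

    def test_envi_missing_wavelengths_raises(self, tmp_path):
        path = tmp_path / "nowl.hdr"
        np.zeros((1, 1, 2), dtype=np.float32).tofile(tmp_path / "nowl.img")
        path.write_text(
            "ENVI\nsamples = 1\nlines = 1\nbands = 2\ndata type = 4\n"
            "interleave = bsq\n")
        with pytest.raises(io.FormatError, match="wavelength"):
            io.read_envi(str(path))

    def test_unknown_format_raises(self, tmp_path):
        with pytest.raises(io.FormatError, match="format"):
            io.read_cube(str(tmp_path / "cube.xyz"))
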