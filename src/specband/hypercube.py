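"""Reflectance hypercubes: radiometric calibration and spectral denoising.

A hypercube is a ``(W, L, Λ)`` reflectance array with an ascending
wavelength axis in nanometres.  Raw camera frames (sample, dark, white
reference) are converted to reflectance by dark subtraction and
white-board normalization; the spectra are then denoised with a
Savitzky–Golay filter along the band axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_coeffs


class ShapeMismatchError(ValueError):
    pass


def _check_wavelengths(wavelengths: np.ndarray) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1:
        raise ValueError("wavelength axis must be 1-D")
    if len(wl) >= 2 and not np.all(np.diff(wl) > 0):
        raise ValueError("wavelengths must be strictly increasing")
    return wl


@dataclass
class RawFrames:
    """Sample, dark and white-reference intensity frames (counts).

    All three arrays share one ``(W, L, Λ)`` shape; the wavelength list
    has length Λ and is strictly increasing.
    """

    sample: np.ndarray
    dark: np.ndarray
    white: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self):
        self.sample = np.asarray(self.sample, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        self.white = np.asarray(self.white, dtype=float)
        self.wavelengths = _check_wavelengths(self.wavelengths)
        for name, arr in (("dark", self.dark), ("white", self.white)):
            if arr.shape != self.sample.shape:
                bad = [i for i, (a, b) in
                       enumerate(zip(arr.shape, self.sample.shape)) if a != b]
                raise ShapeMismatchError(
                    f"{name} frame shape {arr.shape} differs from sample "
                    f"shape {self.sample.shape} on axis {bad}"
                )
        if self.sample.ndim != 3:
            raise ShapeMismatchError("frames must be 3-D (W, L, bands)")
        if self.sample.shape[2] != len(self.wavelengths):
            raise ShapeMismatchError(
                f"band axis length {self.sample.shape[2]} does not match "
                f"{len(self.wavelengths)} wavelengths"
            )


@dataclass
class HyperCube:
    """Calibrated (optionally smoothed) reflectance with wavelength axis.

    ``valid`` is a boolean mask, True where the calibration was
    well-conditioned; invalid entries hold 0 and are excluded from
    spatial statistics downstream.
    """

    reflectance: np.ndarray
    wavelengths: np.ndarray
    smoothed: bool = False
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.reflectance.ndim != 3:
            raise ValueError("reflectance must be 3-D (W, L, bands)")
        self.wavelengths = _check_wavelengths(self.wavelengths)
        if self.reflectance.shape[2] != len(self.wavelengths):
            raise ValueError("band axis does not match wavelength list")
        if self.valid is None:
            self.valid = np.ones(self.reflectance.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.reflectance.shape:
                raise ValueError("valid mask shape differs from reflectance")
        if not np.all(np.isfinite(self.reflectance[self.valid])):
            raise ValueError("non-finite reflectance on unmasked entries")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.reflectance.shape

    def valid_pixels(self) -> np.ndarray:
        """2-D mask of pixels valid in every band."""
        return self.valid.all(axis=2)


@dataclass
class SGConfig:
    """Savitzky–Golay settings: odd window (samples) and poly order.

    The derived least-squares convolution weights always sum to 1, so
    constant spectra pass through unchanged.
    """

    window_length: int = 11
    poly_order: int = 2
    edge_mode: str = "mirror"

    def __post_init__(self):
        if self.window_length < 3 or self.window_length % 2 == 0:
            raise ValueError(
                f"window_length must be odd and >= 3, got {self.window_length}"
            )
        if not 0 <= self.poly_order < self.window_length:
            raise ValueError("poly_order must satisfy 0 <= order < window")

    @property
    def coefficients(self) -> np.ndarray:
        return savgol_coeffs(self.window_length, self.poly_order)


def calibrate_reflectance(raw: RawFrames, eps: float = 1e-9) -> HyperCube:
    """Convert raw counts to reflectance: (I_S - I_D) / (I_w - I_D).

    Entries where the white and dark frames nearly coincide
    (|I_w - I_D| <= eps) are flagged invalid and zeroed rather than
    propagated as infinities.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    denom = raw.white - raw.dark
    valid = np.abs(denom) > eps
    if not valid.any():
        raise ValueError("entire cube invalid: white frame equals dark frame")
    refl = np.zeros_like(denom)
    np.divide(raw.sample - raw.dark, denom, out=refl, where=valid)
    return HyperCube(refl, raw.wavelengths, smoothed=False, valid=valid)


def smooth_savitzky_golay(cube: HyperCube,
                          cfg: SGConfig | None = None) -> HyperCube:
    """Denoise each pixel spectrum along the band axis.

    The spectrum is padded by (window-1)/2 samples using ``cfg.edge_mode``
    (mirror reflection by default) and convolved with the Savitzky–Golay
    least-squares weights.  The validity mask is carried through
    unchanged: smoothing does not un-flag bad calibration entries.
    """
    cfg = cfg or SGConfig()
    if cube.smoothed:
        raise ValueError("cube is already smoothed")
    n_bands = cube.shape[2]
    if n_bands < cfg.window_length:
        raise ValueError(
            f"window_length {cfg.window_length} exceeds band count {n_bands}"
        )
    half = (cfg.window_length - 1) // 2
    pad_spec = [(0, 0), (0, 0), (half, half)]
    mode = {"mirror": "reflect", "reflect": "reflect",
            "nearest": "edge"}.get(cfg.edge_mode)
    if mode is None:
        raise ValueError(f"unknown edge mode {cfg.edge_mode!r}")
    padded = np.pad(cube.reflectance, pad_spec, mode=mode)
    coeffs = cfg.coefficients
    # savgol_coeffs returns weights for convolution (already reversed)
    out = np.zeros_like(cube.reflectance)
    for k, c in enumerate(coeffs):
        out += c * padded[:, :, k:k + n_bands]
    return HyperCube(out, cube.wavelengths, smoothed=True,
                     valid=cube.valid.copy())
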