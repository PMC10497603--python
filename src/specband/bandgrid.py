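"""Multispectral band grids and hyperspectral-to-multispectral resampling.

A band grid is a set of center wavelengths λ_c, each owning a window
[λ_c − w/2, λ_c + w/2] of full bandwidth w.  Under the default *inset*
convention centers start at ``range_min + w/2`` and step by the full
bandwidth, tiling the spectral range without overlap; the band count is
the nearest integer to span/w, so when the span is not a multiple of w
the last window may protrude past the range edge by up to w/2.  An
*edge* convention (centers anchored at both range edges) is provided
for the narrowest simulated bandwidth, whose published band counts
follow that layout instead.

Resampling collapses each window to the mean integrated intensity

    R_M(λ_c) = ∫_{λ_a}^{λ_b} R(λ) dλ / (λ_b − λ_a)

evaluated by the trapezoid rule over the cube samples a..b falling
inside the window (λ_a, λ_b are the first/last such samples).  The
trapezoid quadrature preserves constant spectra exactly and integrates
linear spectra without discretization error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hypercube import HyperCube

#: spectral range labels (nm)
RANGES: dict[str, tuple[float, float]] = {
    "VIS": (400.0, 700.0),
    "VISNIR": (400.0, 1000.0),
    "SWIR": (900.0, 1700.0),
    "VISWIR": (400.0, 1700.0),
}


@dataclass
class BandGrid:
    """Center wavelengths (nm) sharing one half-bandwidth w/2 (nm)."""

    centers: np.ndarray
    half_bandwidth: float
    range_min: float | None = None
    range_max: float | None = None

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.ndim != 1 or len(self.centers) == 0:
            raise ValueError("centers must be a nonempty 1-D list")
        if np.any(np.diff(self.centers) <= 0):
            raise ValueError("centers must be strictly ascending")
        if self.half_bandwidth <= 0:
            raise ValueError("half_bandwidth must be positive")

    def __len__(self) -> int:
        return len(self.centers)

    @property
    def bandwidth(self) -> float:
        """Full bandwidth w (nm)."""
        return 2.0 * self.half_bandwidth

    def windows(self) -> np.ndarray:
        """(C, 2) array of window edges [λ_c − w/2, λ_c + w/2]."""
        hw = self.half_bandwidth
        return np.stack([self.centers - hw, self.centers + hw], axis=1)


@dataclass
class MultiCube:
    """Resampled band values (W × L × C) with their grid and provenance."""

    band_values: np.ndarray
    grid: BandGrid
    valid: np.ndarray | None = None
    provenance: str = ""

    def __post_init__(self):
        self.band_values = np.asarray(self.band_values, dtype=float)
        if self.band_values.ndim != 3:
            raise ValueError("band_values must be 3-D (W, L, C)")
        if self.band_values.shape[2] != len(self.grid):
            raise ValueError("band axis does not match grid length")
        if self.valid is None:
            self.valid = np.ones(self.band_values.shape, dtype=bool)
        if not np.all(np.isfinite(self.band_values[self.valid])):
            raise ValueError("non-finite band values on unmasked entries")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.band_values.shape


def make_band_grid(range_min: float, range_max: float,
                   half_bandwidth: float, mode: str = "inset") -> BandGrid:
    """Build the center-wavelength grid for a spectral range.

    mode="inset" (default): centers at range_min + w/2, stepping by w,
    with the band count rounded to the nearest integer of span/w — the
    rule that reproduces every published per-range band count.  When
    span/w rounds up, the last window protrudes past range_max by at
    most w/2; otherwise all windows lie inside the range.
    mode="edge": centers anchored at both range edges stepping by w,
    giving span/w + 1 bands (used for the narrowest bandwidth).
    """
    w = 2.0 * half_bandwidth
    span = range_max - range_min
    if span < w:
        raise ValueError(
            f"range [{range_min}, {range_max}] is narrower than one "
            f"band of full width {w}"
        )
    if mode == "inset":
        n = int(np.floor(span / w + 0.5 + 1e-9))
        centers = range_min + half_bandwidth + w * np.arange(n)
    elif mode == "edge":
        n = int(np.floor(span / w + 1e-9)) + 1
        centers = range_min + w * np.arange(n)
    else:
        raise ValueError(f"unknown grid mode {mode!r}")
    return BandGrid(centers, half_bandwidth, range_min, range_max)


def resample_to_bands(cube: HyperCube, grid: BandGrid) -> MultiCube:
    """Collapse a hypercube to per-window mean integrated reflectance.

    Every window must contain at least two cube samples; the normalizer
    is the span between the first and last sample inside the window.
    Validity masks propagate: a multispectral entry is valid only if all
    contributing hyperspectral entries were.
    """
    wl = cube.wavelengths
    w_px, l_px, _ = cube.shape
    out = np.empty((w_px, l_px, len(grid)))
    out_valid = np.empty((w_px, l_px, len(grid)), dtype=bool)
    refl = cube.reflectance
    for j, (lo, hi) in enumerate(grid.windows()):
        inside = np.nonzero((wl >= lo - 1e-9) & (wl <= hi + 1e-9))[0]
        if inside.size == 0:
            raise ValueError(
                f"band {grid.centers[j]:g} nm: no cube samples in window "
                f"[{lo:g}, {hi:g}] nm"
            )
        if inside.size == 1:
            raise ValueError(
                f"band {grid.centers[j]:g} nm: only one cube sample in "
                f"window [{lo:g}, {hi:g}] nm; need at least 2"
            )
        a, b = inside[0], inside[-1]
        dw = np.diff(wl[a:b + 1])  # (m-1,)
        norm = wl[b] - wl[a]
        pair_means = 0.5 * (refl[:, :, a:b] + refl[:, :, a + 1:b + 1])
        out[:, :, j] = pair_means @ dw / norm
        out_valid[:, :, j] = cube.valid[:, :, a:b + 1].all(axis=2)
    out[~out_valid] = 0.0
    return MultiCube(out, grid, valid=out_valid,
                     provenance="smoothed" if cube.smoothed else "raw")


def subset_range(obj: BandGrid | MultiCube, range_label: str):
    """Restrict a grid or multicube to a named spectral range.

    The target grid is re-generated for the labeled range (matching the
    published per-range band counts) rather than filtered; for a
    MultiCube every regenerated center must exist in the source grid.
    """
    if range_label not in RANGES:
        raise ValueError(
            f"unknown range label {range_label!r}; expected one of "
            f"{sorted(RANGES)}"
        )
    lo, hi = RANGES[range_label]
    if isinstance(obj, BandGrid):
        return make_band_grid(lo, hi, obj.half_bandwidth)
    if isinstance(obj, MultiCube):
        target = make_band_grid(lo, hi, obj.grid.half_bandwidth)
        src = obj.grid.centers
        idx = []
        for c in target.centers:
            hit = np.nonzero(np.isclose(src, c, atol=1e-6))[0]
            if hit.size == 0:
                raise ValueError(
                    f"regenerated center {c:g} nm for {range_label} is not "
                    "present in the source grid; re-resample from the "
                    "hypercube instead"
                )
            idx.append(hit[0])
        idx = np.array(idx)
        return MultiCube(obj.band_values[:, :, idx], target,
                         valid=obj.valid[:, :, idx],
                         provenance=obj.provenance)
    raise TypeError("subset_range expects a BandGrid or MultiCube")
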