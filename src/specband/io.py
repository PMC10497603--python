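"""Cube I/O: ENVI (header + raw binary) reading and HDF5 round trips.

HDF5 is the native format: dataset ``reflectance`` (W×L×Λ), dataset
``wavelengths_nm`` (Λ), boolean dataset ``valid`` and a ``smoothed``
attribute.  Multispectral cubes use ``band_values`` / ``band_centers_nm``
with a ``half_bandwidth_nm`` attribute.

The ENVI reader handles the classic text header (``key = value`` pairs,
brace-delimited lists) next to a raw BSQ/BIL/BIP binary, which is how
pushbroom hyperspectral instruments ship their cubes.  Wavelengths are
required; out-of-order bands are sorted with the data permuted to match.
"""

from __future__ import annotations

import os
import re

import h5py
import numpy as np

from .hypercube import HyperCube

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
                5: np.float64, 12: np.uint16, 13: np.uint32}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


class FormatError(ValueError):
    pass


def _parse_envi_header(path: str) -> dict:
    text = open(path, "r").read()
    if not text.lstrip().upper().startswith("ENVI"):
        raise FormatError(f"{path} is not an ENVI header")
    fields: dict[str, str] = {}
    # join brace-delimited multi-line values first
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, val = line.split("=", 1)
        fields[key.strip().lower()] = val.strip()
    return fields


def _parse_list(raw: str) -> list[float]:
    return [float(tok) for tok in raw.strip().strip("{}").split(",") if tok.strip()]


def read_envi(header_path: str) -> HyperCube:
    """Read an ENVI cube as (lines, samples, bands) reflectance."""
    fields = _parse_envi_header(header_path)
    for req in ("samples", "lines", "bands", "data type", "interleave"):
        if req not in fields:
            raise FormatError(f"ENVI header missing '{req}'")
    if "wavelength" not in fields:
        raise FormatError("ENVI header has no wavelength list")
    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    dtype = _ENVI_DTYPES.get(int(fields["data type"]))
    if dtype is None:
        raise FormatError(f"unsupported ENVI data type {fields['data type']}")
    interleave = fields["interleave"].lower()
    wavelengths = np.array(_parse_list(fields["wavelength"]))
    if len(wavelengths) != bands:
        raise FormatError("wavelength list length differs from band count")

    data_path = os.path.splitext(header_path)[0]
    for ext in ("", ".img", ".dat", ".raw", ".bsq", ".bil", ".bip"):
        if os.path.exists(data_path + ext):
            data_path = data_path + ext
            break
    else:
        raise FormatError(f"no binary file found next to {header_path}")
    flat = np.fromfile(data_path, dtype=dtype)
    if flat.size != samples * lines * bands:
        raise FormatError("binary size does not match header dimensions")
    if interleave == "bsq":
        cube = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = flat.reshape(lines, samples, bands)
    else:
        raise FormatError(f"unknown interleave {interleave!r}")

    order = np.argsort(wavelengths)
    if not np.array_equal(order, np.arange(bands)):
        wavelengths = wavelengths[order]
        cube = cube[:, :, order]
    smoothed = fields.get("description", "").find("smoothed") >= 0
    return HyperCube(np.ascontiguousarray(cube, dtype=float), wavelengths,
                     smoothed=smoothed)


def write_envi(cube: HyperCube, header_path: str,
               interleave: str = "bsq") -> None:
    """Write an ENVI header + float32 binary pair."""
    if interleave not in ("bsq", "bil", "bip"):
        raise FormatError(f"unknown interleave {interleave!r}")
    lines, samples, bands = cube.shape
    data = cube.reflectance.astype(np.float32)
    if interleave == "bsq":
        flat = data.transpose(2, 0, 1)
    elif interleave == "bil":
        flat = data.transpose(0, 2, 1)
    else:
        flat = data
    data_path = os.path.splitext(header_path)[0] + ".img"
    flat.tofile(data_path)
    wl = ", ".join(f"{w:g}" for w in cube.wavelengths)
    desc = "smoothed reflectance" if cube.smoothed else "reflectance"
    with open(header_path, "w") as fh:
        fh.write(
            "ENVI\n"
            f"description = {{{desc}}}\n"
            f"samples = {samples}\nlines = {lines}\nbands = {bands}\n"
            "header offset = 0\nfile type = ENVI Standard\n"
            f"data type = {_ENVI_CODES[data.dtype]}\n"
            f"interleave = {interleave}\nbyte order = 0\n"
            "wavelength units = Nanometers\n"
            f"wavelength = {{{wl}}}\n"
        )


def write_hdf5(cube: HyperCube, path: str) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("reflectance", data=cube.reflectance)
        fh.create_dataset("wavelengths_nm", data=cube.wavelengths)
        fh.create_dataset("valid", data=cube.valid)
        fh.attrs["smoothed"] = bool(cube.smoothed)


def read_hdf5(path: str) -> HyperCube:
    with h5py.File(path, "r") as fh:
        if "wavelengths_nm" not in fh:
            raise FormatError(f"{path} has no wavelengths_nm dataset")
        return HyperCube(
            fh["reflectance"][...],
            fh["wavelengths_nm"][...],
            smoothed=bool(fh.attrs.get("smoothed", False)),
            valid=fh["valid"][...] if "valid" in fh else None,
        )


def write_multicube(mc, path: str) -> None:
    """Serialize a MultiCube: band_values, band_centers_nm, half bandwidth."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("band_values", data=mc.band_values)
        fh.create_dataset("band_centers_nm", data=mc.grid.centers)
        fh.create_dataset("valid", data=mc.valid)
        fh.attrs["half_bandwidth_nm"] = float(mc.grid.half_bandwidth)
        fh.attrs["provenance"] = mc.provenance


def read_multicube(path: str):
    from .bandgrid import BandGrid, MultiCube
    with h5py.File(path, "r") as fh:
        if "band_centers_nm" not in fh:
            raise FormatError(f"{path} has no band_centers_nm dataset")
        grid = BandGrid(fh["band_centers_nm"][...],
                        float(fh.attrs["half_bandwidth_nm"]))
        return MultiCube(fh["band_values"][...], grid,
                         valid=fh["valid"][...] if "valid" in fh else None,
                         provenance=str(fh.attrs.get("provenance", "")))


def read_cube(path: str, format: str | None = None) -> HyperCube:
    """Dispatch on format ('envi' | 'hdf5'), inferred from extension."""
    fmt = format or _infer_format(path)
    if fmt == "envi":
        return read_envi(path)
    if fmt == "hdf5":
        return read_hdf5(path)
    raise FormatError(f"unknown cube format {fmt!r}")


def write_cube(cube: HyperCube, path: str, format: str | None = None) -> None:
    fmt = format or _infer_format(path)
    if fmt == "envi":
        write_envi(cube, path)
    elif fmt == "hdf5":
        write_hdf5(cube, path)
    else:
        raise FormatError(f"unknown cube format {fmt!r}")


def _infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".hdr",):
        return "envi"
    if ext in (".h5", ".hdf5"):
        return "hdf5"
    raise FormatError(f"cannot infer cube format from {path!r}")
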