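"""Readers and writers for the cube container and CSV/image exports.

Cube container layout (HDF5): datasets ``data`` (row x col x channel,
float), ``wavenumber`` (cm^-1), root attributes ``pixel_pitch_um`` and
``absorbance`` plus one string attribute per metadata key.  Descending
wavenumber input is reordered to ascending on read and the flip recorded in
the cube metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .core import DomainError, PixelMask, SpectralCube, WavenumberAxis

__all__ = [
    "write_cube",
    "read_cube",
    "write_spectrum_csv",
    "read_spectrum_csv",
    "write_mask",
    "read_mask_csv",
    "write_grid_csv",
]

_RESERVED_ATTRS = {"pixel_pitch_um", "absorbance"}


def write_cube(path, cube: SpectralCube) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=cube.data)
        fh.create_dataset("wavenumber", data=cube.axis.values)
        fh.attrs["pixel_pitch_um"] = float(cube.pixel_pitch)
        fh.attrs["absorbance"] = True
        for key, value in cube.metadata.items():
            if key in _RESERVED_ATTRS:
                raise DomainError(f"metadata key {key!r} is reserved")
            fh.attrs[key] = str(value)


def read_cube(path) -> SpectralCube:
    with h5py.File(path, "r") as fh:
        data = np.asarray(fh["data"], dtype=float)
        wn = np.asarray(fh["wavenumber"], dtype=float)
        pitch = float(fh.attrs.get("pixel_pitch_um", 2.7))
        metadata = {
            key: str(fh.attrs[key])
            for key in fh.attrs
            if key not in _RESERVED_ATTRS
        }
    axis, flipped = WavenumberAxis.from_values(wn)
    if flipped:
        data = data[..., ::-1].copy()
        metadata["axis_flipped"] = "true"
    return SpectralCube(data=data, axis=axis, pixel_pitch=pitch, metadata=metadata)


def write_spectrum_csv(path, axis: WavenumberAxis, mean: np.ndarray, sd: np.ndarray | None = None) -> None:
    """Two-column ``wavenumber_cm-1, absorbance`` CSV, optional ``sd`` column."""
    mean = np.asarray(mean, dtype=float)
    if mean.shape != (len(axis),):
        raise DomainError("spectrum length does not match axis")
    cols = [axis.values, mean]
    header = "wavenumber_cm-1,absorbance"
    if sd is not None:
        sd = np.asarray(sd, dtype=float)
        if sd.shape != mean.shape:
            raise DomainError("sd length does not match spectrum")
        cols.append(sd)
        header += ",sd"
    np.savetxt(path, np.column_stack(cols), delimiter=",", header=header, comments="")


def read_spectrum_csv(path) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    wn, mean = arr[:, 0], arr[:, 1]
    sd = arr[:, 2] if arr.shape[1] > 2 else None
    return wn, mean, sd


def write_mask(path_stem, mask: PixelMask) -> tuple[Path, Path]:
    """Write a mask as a 1-bit PNG plus a CSV of flagged (outlier) coordinates.

    Returns the (png_path, csv_path) pair.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.image as mimg

    stem = Path(path_stem)
    png_path = stem.with_suffix(".png")
    csv_path = stem.with_suffix(".csv")
    mimg.imsave(png_path, mask.grid.astype(np.uint8) * 255, cmap="gray", vmin=0, vmax=255)
    rows, cols = np.nonzero(~mask.grid)
    np.savetxt(
        csv_path,
        np.column_stack([rows, cols]),
        fmt="%d",
        delimiter=",",
        header="row,col",
        comments="",
    )
    # record provenance next to the mask for traceability
    stem.with_suffix(".json").write_text(
        json.dumps({"provenance": mask.provenance, "retention": mask.retention}, indent=2)
    )
    return png_path, csv_path


def read_mask_csv(path, shape: tuple[int, int], provenance: str = "from-csv") -> PixelMask:
    """Rebuild a mask from a CSV of flagged outlier coordinates."""
    grid = np.ones(shape, dtype=bool)
    arr = np.loadtxt(path, delimiter=",", skiprows=1, dtype=int, ndmin=2)
    if arr.size:
        grid[arr[:, 0], arr[:, 1]] = False
    return PixelMask(grid, provenance)


def write_grid_csv(path, grid: np.ndarray) -> None:
    np.savetxt(path, np.asarray(grid, dtype=float), delimiter=",")
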