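"""Image and volume I/O.

Images are 8- or 16-bit grayscale PNG/TIFF, converted internally to float64
on the 0-255 display scale.  Orientation-score volumes and gauge frames are
stored in HDF5 with the grid geometry as attributes, axis order
(row, column, orientation).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np

from .gauge import GaugeFrameField
from .grid import M2Grid, OrientationScore

__all__ = [
    "read_image",
    "write_image",
    "save_score",
    "load_score",
    "save_gauge_frame",
    "load_gauge_frame",
]


def read_image(path) -> np.ndarray:
    """Read a grayscale PNG/TIFF as float64 on the 0-255 scale."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[-1] == 1:
            arr = arr[..., 0]
        else:
            raise ValueError(
                f"{path}: expected a grayscale image, got shape {arr.shape} "
                "(convert RGB inputs to grayscale first)"
            )
    if arr.dtype == np.uint8:
        return arr.astype(np.float64)
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) * (255.0 / 65535.0)
    return arr.astype(np.float64)


def write_image(img: np.ndarray, path, bit_depth: int = 8) -> None:
    """Write an image on the 0-255 scale; clips and rounds per bit depth."""
    img = np.clip(np.asarray(img, dtype=float), 0.0, 255.0)
    path = Path(path)
    if bit_depth == 8:
        out = np.round(img).astype(np.uint8)
    elif bit_depth == 16:
        out = np.round(img * (65535.0 / 255.0)).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    iio.imwrite(path, out)


def save_score(U: OrientationScore, path) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("score", data=U.values)
        ds.attrs["H"] = U.grid.H
        ds.attrs["W"] = U.grid.W
        ds.attrs["N"] = U.grid.N
        ds.attrs["dxy"] = U.grid.dxy


def load_score(path) -> OrientationScore:
    with h5py.File(path, "r") as fh:
        ds = fh["score"]
        grid = M2Grid(int(ds.attrs["H"]), int(ds.attrs["W"]), int(ds.attrs["N"]), float(ds.attrs["dxy"]))
        return OrientationScore(ds[()], grid)


def save_gauge_frame(frame: GaugeFrameField, path) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("gauge_frame", data=frame.coeffs)
        ds.attrs["xi"] = frame.xi
        ds.attrs["H"] = frame.grid.H
        ds.attrs["W"] = frame.grid.W
        ds.attrs["N"] = frame.grid.N
        ds.attrs["dxy"] = frame.grid.dxy
        if frame.degenerate is not None:
            fh.create_dataset("degenerate", data=frame.degenerate)


def load_gauge_frame(path) -> GaugeFrameField:
    with h5py.File(path, "r") as fh:
        ds = fh["gauge_frame"]
        grid = M2Grid(int(ds.attrs["H"]), int(ds.attrs["W"]), int(ds.attrs["N"]), float(ds.attrs["dxy"]))
        degen = fh["degenerate"][()] if "degenerate" in fh else None
        return GaugeFrameField(ds[()], float(ds.attrs["xi"]), grid, degen)
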