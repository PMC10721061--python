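"""Field and mask I/O: plain-text CSV matrices and 8-bit grayscale PNG.

File convention: the first row of a CSV or PNG is the *top* of the domain
(largest y), the standard image orientation; internally row 0 is the bottom.
CSV fields round-trip exactly; PNG quantizes the [-1, 1] range to 8 bits
(max error 1/255 of the range).  Masks are 0/1 CSV integers or PNG with any
nonzero pixel marking an obstacle cell.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .grid import Grid

__all__ = ["read_field", "write_field", "read_mask", "write_mask"]


def _check_shape(arr: np.ndarray, grid: Grid, path) -> None:
    if arr.shape != grid.shape:
        raise ValueError(
            f"{path}: array shape {arr.shape} does not match grid {grid.shape}"
        )


def write_field(path: str | Path, field: np.ndarray, grid: Grid) -> None:
    """Write a phase field; format chosen by suffix (.csv or .png)."""
    path = Path(path)
    field = np.asarray(field, dtype=float)
    _check_shape(field, grid, path)
    flipped = np.flipud(field)  # first file row = top of domain
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        q = np.clip((flipped + 1.0) * 0.5, 0.0, 1.0)
        iio.imwrite(path, np.round(q * 255.0).astype(np.uint8))
    else:
        np.savetxt(path, flipped, delimiter=",", fmt="%.17g")


def read_field(path: str | Path, grid: Grid) -> np.ndarray:
    """Read a phase field written by :func:`write_field`."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        raw = np.asarray(iio.imread(path), dtype=float)
        if raw.ndim == 3:
            raw = raw[..., 0]
        arr = raw / 255.0 * 2.0 - 1.0
    else:
        arr = np.loadtxt(path, delimiter=",", ndmin=2)
    _check_shape(arr, grid, path)
    return np.flipud(arr).copy()


def write_mask(path: str | Path, mask: np.ndarray, grid: Grid) -> None:
    """Write an obstacle mask (.csv of 0/1 or .png with obstacle = 255)."""
    path = Path(path)
    mask = np.asarray(mask).astype(bool)
    _check_shape(mask, grid, path)
    flipped = np.flipud(mask)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, (flipped * 255).astype(np.uint8))
    else:
        np.savetxt(path, flipped.astype(np.int8), delimiter=",", fmt="%d")


def read_mask(path: str | Path, grid: Grid) -> np.ndarray:
    """Read an obstacle mask; any nonzero value marks an obstacle cell."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        raw = np.asarray(iio.imread(path))
        if raw.ndim == 3:
            raw = raw[..., 0]
        arr = raw != 0
    else:
        arr = np.loadtxt(path, delimiter=",", ndmin=2) != 0
    _check_shape(arr, grid, path)
    return np.flipud(arr).copy()
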