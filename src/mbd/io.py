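"""PNG/CSV readers and writers for images, masks, polygons and grids."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .preprocess import RoiPolygon

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_polygon_csv",
    "write_polygon_csv",
    "read_grid_csv",
    "write_grid_csv",
]


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale image; RGB inputs are collapsed by luminance."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = np.round(arr[..., :3].astype(float) @ [0.2126, 0.7152, 0.0722])
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return arr


def write_image(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    """Binary PNG to boolean raster (any value above 127 is True)."""
    return read_image(path) > 127


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_polygon_csv(path: str | Path, label: str = "breast") -> RoiPolygon:
    """Polygon vertices from a CSV with x,y columns (pixel coordinates)."""
    df = pd.read_csv(path)
    return RoiPolygon(
        vertices=tuple(zip(df["x"].astype(float), df["y"].astype(float))),
        label=label,
    )


def write_polygon_csv(path: str | Path, poly: RoiPolygon) -> None:
    pd.DataFrame(poly.vertices, columns=["x", "y"]).to_csv(path, index=False)


def read_grid_csv(path: str | Path) -> np.ndarray:
    """Regional-PD matrix from a headerless CSV (row 0 = image top)."""
    return np.loadtxt(path, delimiter=",", ndmin=2)


def write_grid_csv(path: str | Path, pd_matrix: np.ndarray) -> None:
    np.savetxt(path, np.asarray(pd_matrix, dtype=float), delimiter=",", fmt="%.6f")
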