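"""Region-of-interest definition and optional contrast enhancement.

The breast region of interest is the area inside the breast-contour
polygon minus the pectoral-muscle polygon; everything outside is cropped
(set to zero) so that bright objects off the breast cannot inflate the
density measurement.  Contrast enhancement is a linear percentile stretch
used to make the skin line easier to outline; it is not part of the
default density-quantification path.

Conventions: row-major rasters, origin at the top-left, 0-based indices.
A pixel belongs to a polygon when its center lies inside the polygon or
on its boundary (pixel-center containment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely

__all__ = [
    "RoiPolygon",
    "MaskError",
    "polygon_to_mask",
    "enhance_contrast",
    "apply_mask",
]

DEFAULT_SATURATED_FRACTION = 0.0035


class MaskError(ValueError):
    """Raised for degenerate ROIs or mismatched raster shapes."""


@dataclass(frozen=True)
class RoiPolygon:
    """Ordered polygon in pixel coordinates, vertices as (x, y) = (col, row)."""

    vertices: tuple[tuple[float, float], ...]
    label: str = "breast"

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise MaskError("polygon needs at least 3 vertices")
        if self.label not in ("breast", "pectoral"):
            raise MaskError("polygon label must be 'breast' or 'pectoral'")

    def validate_bounds(self, height: int, width: int) -> None:
        for x, y in self.vertices:
            if not (0 <= x <= width - 1 and 0 <= y <= height - 1):
                raise MaskError(
                    f"vertex ({x}, {y}) outside {height}x{width} image bounds"
                )


def _covers(poly: RoiPolygon, height: int, width: int) -> np.ndarray:
    geom = shapely.Polygon(poly.vertices)
    if not geom.is_valid or geom.area == 0:
        raise MaskError(f"{poly.label} polygon is degenerate")
    cc, rr = np.meshgrid(np.arange(width), np.arange(height))
    pts = shapely.points(np.column_stack([cc.ravel(), rr.ravel()]))
    return shapely.covers(geom, pts).reshape(height, width)


def polygon_to_mask(
    image: np.ndarray,
    breast: RoiPolygon,
    pectoral: RoiPolygon | None = None,
) -> np.ndarray:
    """Rasterize breast-minus-pectoral polygons to a boolean breast mask.

    Pixel-center containment: a pixel (r, c) is inside when the point
    (x=c, y=r) is covered by the polygon (boundary inclusive).  Raises
    :class:`MaskError` if the resulting mask is empty.
    """
    image = np.asarray(image)
    h, w = image.shape
    breast.validate_bounds(h, w)
    mask = _covers(breast, h, w)
    if pectoral is not None:
        pectoral.validate_bounds(h, w)
        mask &= ~_covers(pectoral, h, w)
    if not mask.any():
        raise MaskError("ROI is degenerate: breast minus pectoral region is empty")
    return mask


def enhance_contrast(
    image: np.ndarray,
    mask: np.ndarray,
    saturated_fraction: float = DEFAULT_SATURATED_FRACTION,
) -> np.ndarray:
    """Linear contrast stretch of the in-mask intensities.

    The in-mask quantiles at ``saturated_fraction`` and
    ``1 - saturated_fraction`` are mapped to 0 and 255; values beyond them
    saturate.  Off-mask pixels are untouched.  A constant in-mask image is
    returned unchanged with a warning.
    """
    if not 0 <= saturated_fraction < 0.5:
        raise ValueError("saturated_fraction must be in [0, 0.5)")
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise MaskError("image and mask shapes differ")
    vals = image[mask].astype(float)
    if vals.size == 0:
        raise MaskError("mask is empty")
    lo = np.quantile(vals, saturated_fraction)
    hi = np.quantile(vals, 1 - saturated_fraction)
    if hi == lo:
        warnings.warn("constant in-mask image: contrast enhancement is a no-op")
        return image.copy()
    out = image.astype(float).copy()
    stretched = (vals - lo) / (hi - lo) * 255.0
    out[mask] = np.clip(np.floor(stretched + 0.5), 0, 255)
    return out.astype(image.dtype)


def apply_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero out off-mask pixels; in-mask pixels pass through unchanged."""
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise MaskError("image and mask shapes differ")
    out = image.copy()
    out[~mask] = 0
    return out
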