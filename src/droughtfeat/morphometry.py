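"""Pixel-count geometry on binary masks.

All quantities are integer pixel counts, matching the convention that the
drought shape descriptors are dimensionless ratios of pixel counts:

* projected area — number of true pixels,
* perimeter — number of boundary pixels (true pixels with a false
  4-neighbor; the raster border counts as background),
* bounding-rectangle area — axis-aligned tight box, inclusive endpoints,
* convex-hull area — number of pixels whose centers fall inside or on the
  convex hull of the true-pixel centers (ties broken toward inclusion).

Coordinates are 0-based with x = column, y = row, row 0 at the top.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import shapely
from shapely.geometry import MultiPoint

__all__ = [
    "NoPlantError",
    "BoundingRectangle",
    "MorphometrySummary",
    "projected_area",
    "perimeter_pixels",
    "bounding_rectangle",
    "convex_hull_area",
    "summarize",
]


class NoPlantError(ValueError):
    """Raised when an operation requires a non-empty plant mask."""


@dataclasses.dataclass(frozen=True)
class BoundingRectangle:
    """Tight axis-aligned box around the true pixels, inclusive endpoints."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    @property
    def width(self) -> int:
        return self.x_max - self.x_min + 1

    @property
    def height(self) -> int:
        return self.y_max - self.y_min + 1

    @property
    def area(self) -> int:
        return self.width * self.height


@dataclasses.dataclass(frozen=True)
class MorphometrySummary:
    """The four pixel-count measurements behind the shape descriptors."""

    area: int
    perimeter: int
    bbox_area: int
    hull_area: int


def _as_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    return mask


def projected_area(mask: np.ndarray) -> int:
    """Number of true pixels (total projected plant area)."""
    return int(np.count_nonzero(_as_mask(mask)))


def perimeter_pixels(mask: np.ndarray) -> int:
    """Count of true pixels with at least one false 4-neighbor.

    Pixels outside the raster are treated as false, so plants touching the
    image border contribute edge pixels there.
    """
    mask = _as_mask(mask)
    padded = np.pad(mask, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1]
        & padded[2:, 1:-1]
        & padded[1:-1, :-2]
        & padded[1:-1, 2:]
    )
    return int(np.count_nonzero(mask & ~interior))


def bounding_rectangle(mask: np.ndarray) -> BoundingRectangle:
    """Tight inclusive extents of the true pixels; raises on an empty mask."""
    mask = _as_mask(mask)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise NoPlantError("bounding rectangle of an empty mask is undefined")
    return BoundingRectangle(
        x_min=int(cols.min()),
        y_min=int(rows.min()),
        x_max=int(cols.max()),
        y_max=int(rows.max()),
    )


_ON_BOUNDARY_TOL = 1e-9  # pixel centers on the hull polygon count as inside


def convex_hull_area(mask: np.ndarray) -> int:
    """Pixel count of the filled rasterized convex hull of true-pixel centers.

    A pixel belongs to the filled hull iff its center lies inside or on the
    hull polygon of the true-pixel centers.  Degenerate masks (single pixel,
    collinear pixels) return the pixel count of the rasterized point or
    segment.  Raises on an empty mask.
    """
    mask = _as_mask(mask)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise NoPlantError("convex hull of an empty mask is undefined")
    # shapely collapses collinear/singleton inputs to LineString/Point,
    # so degenerate masks need no special casing here
    hull = MultiPoint(np.column_stack([cols, rows])).convex_hull
    box = bounding_rectangle(mask)
    xs, ys = np.meshgrid(
        np.arange(box.x_min, box.x_max + 1),
        np.arange(box.y_min, box.y_max + 1),
    )
    candidates = shapely.points(np.column_stack([xs.ravel(), ys.ravel()]))
    inside = shapely.dwithin(hull, candidates, _ON_BOUNDARY_TOL)
    return int(np.count_nonzero(inside))


def summarize(mask: np.ndarray) -> MorphometrySummary:
    """All four measurements from one mask; raises on an empty mask."""
    mask = _as_mask(mask)
    area = projected_area(mask)
    if area == 0:
        raise NoPlantError("cannot summarize an empty mask")
    return MorphometrySummary(
        area=area,
        perimeter=perimeter_pixels(mask),
        bbox_area=bounding_rectangle(mask).area,
        hull_area=convex_hull_area(mask),
    )
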