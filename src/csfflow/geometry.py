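"""Planar geometry helpers for compartment regions.

All coordinates are in micrometres unless a name says otherwise.  The image
convention is row-major with the origin at the top-left pixel centre:
``x`` is the column direction, ``y`` the row direction, and ``y`` increases
downward.  The centre of pixel ``(row i, col j)`` sits at
``(x, y) = (j * pixel_size, i * pixel_size)``.
"""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry import Polygon

from .errors import InvalidSpecError

__all__ = [
    "circle_polygon",
    "as_polygon",
    "rasterize",
    "sample_uniform",
    "grid_points",
    "contains",
]


def circle_polygon(center: tuple[float, float], radius: float, n_vertices: int = 96) -> Polygon:
    """Regular-polygon approximation of a disk (µm coordinates)."""
    if radius <= 0:
        raise InvalidSpecError(f"circle radius must be positive, got {radius}")
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    pts = np.column_stack(
        [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)]
    )
    return Polygon(pts)


def as_polygon(region) -> Polygon:
    """Coerce a polygon-like object (Polygon or (n,2) vertex array) to shapely."""
    if isinstance(region, Polygon):
        poly = region
    else:
        pts = np.asarray(region, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise InvalidSpecError("region must be a Polygon or an (n>=3, 2) vertex array")
        poly = Polygon(pts)
    if poly.area <= 0:
        raise InvalidSpecError("region polygon has zero area")
    return poly


def contains(poly: Polygon, x, y) -> np.ndarray:
    """Vectorized point-in-polygon test (boundary counts as outside)."""
    return shapely.contains_xy(poly, np.asarray(x, float), np.asarray(y, float))


def rasterize(poly: Polygon, image_shape: tuple[int, int], pixel_size_um: float) -> np.ndarray:
    """Boolean mask of pixels whose centres fall inside the polygon."""
    rows, cols = image_shape
    jj, ii = np.meshgrid(np.arange(cols), np.arange(rows))
    mask = contains(poly, jj.ravel() * pixel_size_um, ii.ravel() * pixel_size_um)
    return mask.reshape(rows, cols)


def sample_uniform(poly: Polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random points inside the polygon, by rejection sampling."""
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((n, 2), dtype=float)
    filled = 0
    while filled < n:
        m = max(16, int(1.8 * (n - filled) * (maxx - minx) * (maxy - miny) / poly.area))
        cand = rng.uniform([minx, miny], [maxx, maxy], size=(m, 2))
        ok = contains(poly, cand[:, 0], cand[:, 1])
        take = cand[ok][: n - filled]
        out[filled : filled + len(take)] = take
        filled += len(take)
    return out


def grid_points(poly: Polygon, spacing: float) -> np.ndarray:
    """Deterministic regular grid of in-polygon points at the given spacing."""
    minx, miny, maxx, maxy = poly.bounds
    xs = np.arange(minx + spacing / 2, maxx, spacing)
    ys = np.arange(miny + spacing / 2, maxy, spacing)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    return pts[contains(poly, pts[:, 0], pts[:, 1])]
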