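"""Sub-pixel bright-particle detection (stage 1 of the velocimetry chain).

Detection is scale-matched Laplacian-of-Gaussian (LoG) filtering: for a blob
of radius ``r`` the filter scale is ``sigma = r / sqrt(2)``, the scale at
which the normalized LoG response of a Gaussian blob peaks.  Local maxima of
the (sign-flipped, scale-normalized) response above a quality threshold are
kept, refined to sub-pixel accuracy by a quadratic fit in the 3x3
neighbourhood, and non-maximum-suppressed at one blob radius.  The procedure
is fully deterministic; equal-quality ties resolve to the lexicographically
smallest (row, col).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.spatial import cKDTree

from .errors import InvalidParameterError
from .movie import Movie

__all__ = ["detect_particles", "detect_movie", "auto_threshold"]


def _log_response(image: np.ndarray, sigma_px: float) -> np.ndarray:
    """Scale-normalized, sign-flipped LoG response (bright blobs positive).

    The mean is removed first: the truncated discrete kernel does not sum its
    second-derivative weights exactly to zero, so a raw constant offset would
    leak into the response.
    """
    img = np.asarray(image, dtype=np.float64)
    return -(sigma_px**2) * ndi.gaussian_laplace(
        img - img.mean(), sigma_px, mode="nearest"
    )


def auto_threshold(response: np.ndarray, k: float = 5.0) -> float:
    """Robust noise-based threshold: ``k`` times the MAD-estimated sd."""
    med = np.median(response)
    mad = np.median(np.abs(response - med))
    return float(med + k * 1.4826 * mad)


def detect_particles(
    image: np.ndarray,
    pixel_size_um: float,
    blob_radius_um: float,
    quality_threshold: float | str = "auto",
) -> pd.DataFrame:
    """Detect bright blobs in one frame.

    Parameters
    ----------
    image:
        2D intensity frame (any float/integer dtype, finite values).
    pixel_size_um:
        Pixel pitch, µm.
    blob_radius_um:
        Expected particle radius, µm; must be at least one pixel.
    quality_threshold:
        Absolute response threshold, or ``"auto"`` for 5x the robust (MAD)
        noise level of the response image.

    Returns
    -------
    DataFrame with columns ``x_um, y_um, quality``, sorted by descending
    quality then (row, col).
    """
    x, y, q = _detect_arrays(image, pixel_size_um, blob_radius_um, quality_threshold)
    return pd.DataFrame({"x_um": x, "y_um": y, "quality": q})


def _detect_arrays(
    image: np.ndarray,
    pixel_size_um: float,
    blob_radius_um: float,
    quality_threshold: float | str = "auto",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    image = np.asarray(image)
    if image.ndim != 2:
        raise InvalidParameterError("detect_particles expects a single 2D frame")
    if not np.all(np.isfinite(image)):
        raise InvalidParameterError("frame contains non-finite values")
    if blob_radius_um < pixel_size_um:
        raise InvalidParameterError(
            f"blob_radius_um ({blob_radius_um}) must be >= pixel size ({pixel_size_um})"
        )

    radius_px = blob_radius_um / pixel_size_um
    sigma_px = radius_px / np.sqrt(2.0)
    resp = _log_response(image, sigma_px)
    thr = auto_threshold(resp) if quality_threshold == "auto" else float(quality_threshold)

    local_max = (resp == ndi.maximum_filter(resp, size=3, mode="nearest")) & (resp > thr)
    border = int(np.ceil(radius_px))
    local_max[:border, :] = local_max[-border:, :] = False
    local_max[:, :border] = local_max[:, -border:] = False

    rows, cols = np.nonzero(local_max)
    if len(rows) == 0:
        empty = np.empty(0)
        return empty, empty.copy(), empty.copy()
    quality = resp[rows, cols]
    order = np.lexsort((cols, rows, -quality))
    rows, cols, quality = rows[order], cols[order], quality[order]

    # greedy non-maximum suppression at one blob radius, highest quality first;
    # points strictly closer than one radius to an already-kept point drop out
    pts = np.column_stack([rows, cols]).astype(float)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(radius_px, output_type="ndarray")
    if len(pairs):
        d2 = np.sum((pts[pairs[:, 0]] - pts[pairs[:, 1]]) ** 2, axis=1)
        pairs = pairs[d2 < radius_px**2]
    neighbours: dict[int, list[int]] = {}
    for i, j in pairs:  # i < j, i has higher priority
        neighbours.setdefault(int(i), []).append(int(j))
    suppressed = np.zeros(len(pts), dtype=bool)
    for i in range(len(pts)):
        if suppressed[i]:
            continue
        for j in neighbours.get(i, ()):
            suppressed[j] = True
    rows, cols, quality = rows[~suppressed], cols[~suppressed], quality[~suppressed]

    # sub-pixel refinement: 1D quadratic through the 3x3 response neighbourhood
    def parabola_offset(m1, c0, p1):
        denom = m1 - 2 * c0 + p1
        with np.errstate(divide="ignore", invalid="ignore"):
            off = 0.5 * (m1 - p1) / denom
        off = np.where(np.isfinite(off), off, 0.0)
        return np.clip(off, -0.5, 0.5)

    dr = parabola_offset(
        resp[rows - 1, cols], resp[rows, cols], resp[rows + 1, cols]
    )
    dc = parabola_offset(
        resp[rows, cols - 1], resp[rows, cols], resp[rows, cols + 1]
    )
    return (cols + dc) * pixel_size_um, (rows + dr) * pixel_size_um, quality


def detect_movie(
    movie: Movie,
    blob_radius_um: float,
    quality_threshold: float | str = "auto",
) -> pd.DataFrame:
    """Run :func:`detect_particles` on every frame.

    Returns a DataFrame with columns ``frame, x_um, y_um, quality``.
    """
    frames, xs, ys, qs = [], [], [], []
    for t in range(movie.n_frames):
        x, y, q = _detect_arrays(
            movie.data[t], movie.pixel_size_um, blob_radius_um, quality_threshold
        )
        frames.append(np.full(len(x), t, dtype=np.int64))
        xs.append(x)
        ys.append(y)
        qs.append(q)
    return pd.DataFrame(
        {
            "frame": np.concatenate(frames),
            "x_um": np.concatenate(xs),
            "y_um": np.concatenate(ys),
            "quality": np.concatenate(qs),
        }
    )
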