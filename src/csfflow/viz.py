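"""Temporal polarity projections, kymographs and ciliary beat frequency.

``temporal_color_projection`` renders the classic time-coded trail image:
each frame's foreground (frame minus the per-pixel temporal median) is tinted
by its time-indexed colormap colour and max-projected, so particle paths
appear as colour-ordered trails on the grayscale static background.

``compute_kymograph`` samples intensity along a polyline for every frame
(bilinear interpolation, optional transverse averaging), producing the
distance-vs-time image whose periodic stripes reveal ciliary beating;
``beat_frequency`` reads off the dominant temporal frequency of those
stripes, declaring "no beat" when no spectral peak stands clear of the noise
floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
import numpy as np
import scipy.ndimage as ndi

from .errors import InvalidParameterError
from .movie import Movie

__all__ = [
    "Kymograph",
    "temporal_color_projection",
    "compute_kymograph",
    "beat_frequency",
    "save_field_maps",
]


def save_field_maps(field, path_prefix, quiver_stride: int = 4) -> list:
    """Export a dense field as speed / sd colormaps and a quiver overlay.

    Writes ``<prefix>_speed.png``, ``<prefix>_sd.png`` and
    ``<prefix>_quiver.png``; returns the written paths.
    """
    import matplotlib.pyplot as plt

    paths = []
    for name, grid in (
        ("speed", field.speed_grid),
        ("sd", np.hypot(field.sd_vx_grid, field.sd_vy_grid)),
    ):
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(grid, cmap="magma", origin="upper")
        fig.colorbar(im, ax=ax, label=f"{name} (µm/s)")
        ax.set_axis_off()
        out = f"{path_prefix}_{name}.png"
        fig.savefig(out, dpi=150, bbox_inches="tight")
        plt.close(fig)
        paths.append(out)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.imshow(field.speed_grid, cmap="gray", origin="upper")
    rr, cc = np.nonzero(field.roi_mask)
    keep = (rr % quiver_stride == 0) & (cc % quiver_stride == 0)
    ax.quiver(
        cc[keep],
        rr[keep],
        field.vx_grid[rr[keep], cc[keep]],
        -field.vy_grid[rr[keep], cc[keep]],  # image y points down
        color="red",
        width=0.003,
    )
    ax.set_axis_off()
    out = f"{path_prefix}_quiver.png"
    fig.savefig(out, dpi=150, bbox_inches="tight")
    plt.close(fig)
    paths.append(out)
    return paths


def temporal_color_projection(
    movie: Movie,
    frame_range: tuple[int, int] | None = None,
    colormap: str = "viridis",
    fg_threshold: float | str = "auto",
) -> np.ndarray:
    """Time-colour-coded maximum projection of moving foreground.

    Parameters
    ----------
    frame_range:
        Half-open ``(start, stop)`` range; ``None`` means all frames.
    fg_threshold:
        Intensity above the per-pixel temporal median needed to count as
        foreground; ``"auto"`` uses 5x the robust (MAD) sd of the residuals.

    Returns an (H, W, 3) float RGB image in [0, 1].
    """
    if frame_range is None:
        frame_range = (0, movie.n_frames)
    start, stop = frame_range
    if not (0 <= start < stop <= movie.n_frames):
        raise InvalidParameterError(f"invalid frame_range {frame_range}")
    stack = movie.data[start:stop].astype(np.float64)
    n = stack.shape[0]
    # static background from the whole movie so that short (even length-1)
    # ranges still have a meaningful moving foreground
    background = np.median(movie.data.astype(np.float64), axis=0)
    fg = stack - background[None]
    if fg_threshold == "auto":
        med = np.median(fg)
        thr = 5.0 * 1.4826 * np.median(np.abs(fg - med))
    else:
        thr = float(fg_threshold)
    fg = np.clip(fg - thr, 0.0, None)
    fgmax = fg.max()

    bg_lo, bg_hi = background.min(), background.max()
    gray = (background - bg_lo) / (bg_hi - bg_lo) if bg_hi > bg_lo else np.zeros_like(background)
    out = np.repeat(gray[:, :, None], 3, axis=2)

    if fgmax > 0:
        cmap = matplotlib.colormaps[colormap]
        denom = max(n - 1, 1)
        trails = np.zeros_like(out)
        for t in range(n):
            tint = np.asarray(cmap(t / denom)[:3])
            layer = (fg[t] / fgmax)[:, :, None] * tint[None, None, :]
            np.maximum(trails, layer, out=trails)
        np.maximum(out, trails, out=out)
    return out


@dataclass
class Kymograph:
    """Distance-along-line (rows) versus time (columns) intensity image."""

    image: np.ndarray
    line: np.ndarray  # polyline vertices in px, shape (k, 2) as (x, y)
    width: int
    frame_interval_s: float


def _polyline_samples(line: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-px-step sample points along the polyline and their unit normals."""
    line = np.atleast_2d(np.asarray(line, float))
    seg = np.diff(line, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    total = seg_len.sum()
    if total <= 0:
        raise InvalidParameterError("zero-length kymograph line")
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = np.arange(0.0, total + 1e-9, 1.0)
    pts = np.empty((len(s), 2))
    nrm = np.empty((len(s), 2))
    idx = np.clip(np.searchsorted(arc, s, side="right") - 1, 0, len(seg) - 1)
    frac = (s - arc[idx]) / np.where(seg_len[idx] > 0, seg_len[idx], 1.0)
    pts = line[idx] + frac[:, None] * seg[idx]
    tang = seg[idx] / seg_len[idx][:, None]
    nrm = np.column_stack([-tang[:, 1], tang[:, 0]])
    return pts, nrm


def compute_kymograph(movie: Movie, line, width: int = 1) -> Kymograph:
    """Sample intensity along a polyline through time.

    ``line`` is a sequence of (x, y) pixel vertices.  Intensity is bilinearly
    interpolated at unit-pixel arc-length steps and averaged over ``width``
    transverse samples (1 px apart, centred on the line).
    """
    if width < 1:
        raise InvalidParameterError("width must be >= 1")
    pts, nrm = _polyline_samples(line)
    h, w = movie.shape
    if (
        pts[:, 0].min() < 0
        or pts[:, 1].min() < 0
        or pts[:, 0].max() > w - 1
        or pts[:, 1].max() > h - 1
    ):
        raise InvalidParameterError("kymograph line leaves the image bounds")
    offsets = (np.arange(width) - (width - 1) / 2.0)[:, None, None]
    sample_xy = pts[None] + offsets * nrm[None]  # (width, n_pos, 2)
    coords = np.stack([sample_xy[..., 1], sample_xy[..., 0]])  # (2, width, n_pos)
    img = np.empty((pts.shape[0], movie.n_frames))
    for t in range(movie.n_frames):
        vals = ndi.map_coordinates(
            movie.data[t].astype(np.float64), coords, order=1, mode="nearest"
        )
        img[:, t] = vals.mean(axis=0)
    return Kymograph(
        image=img,
        line=np.atleast_2d(np.asarray(line, float)),
        width=width,
        frame_interval_s=movie.frame_interval_s,
    )


def beat_frequency(kymo: Kymograph, peak_factor: float = 3.0) -> float:
    """Dominant temporal frequency of a kymograph, in Hz.

    The position-averaged one-sided power spectrum (rows detrended by their
    mean) is scanned for its largest non-DC peak; if that peak's power is
    below ``peak_factor`` times the spectral median the kymograph is declared
    beat-free and 0 is returned.
    """
    if kymo.frame_interval_s is None or kymo.frame_interval_s <= 0:
        raise InvalidParameterError("kymograph frame interval unknown")
    n = kymo.image.shape[1]
    if n < 32:
        raise InvalidParameterError("beat_frequency needs >= 32 frames")
    x = kymo.image - kymo.image.mean(axis=1, keepdims=True)
    power = np.abs(np.fft.rfft(x, axis=1)) ** 2
    spectrum = power.mean(axis=0)[1:]  # drop DC
    if spectrum.max() <= 0:
        return 0.0
    peak = int(np.argmax(spectrum))
    if spectrum[peak] < peak_factor * np.median(spectrum):
        return 0.0
    return float((peak + 1) / (n * kymo.frame_interval_s))
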