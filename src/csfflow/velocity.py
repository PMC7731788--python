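"""Windowed weighted-least-squares velocimetry (stage 2).

Each trajectory is partitioned into consecutive sub-second windows and each
window is reduced to a single velocity vector by independent weighted linear
regressions of x(t) and y(t).  The window median speed inherits the tracker's
robustness: a handful of mislocalized points perturbs the straight-line fit
far less than a frame-difference estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, InvalidWeightsError

__all__ = ["VelocityVector", "partition_track", "fit_segment_velocity", "collect_vectors", "default_window_frames"]


@dataclass
class VelocityVector:
    """One window's velocity estimate.

    ``x, y`` is the weighted centroid (µm), ``vx, vy`` the fitted velocity
    (µm/s), ``t_mid`` the weighted mean time (s), ``residual_rms`` the rms of
    the 2D fit residuals (µm) and ``weight`` the derived fit confidence
    ``1 / (1 + residual_rms / pixel_size)`` in (0, 1].
    """

    x: float
    y: float
    vx: float
    vy: float
    t_mid: float
    n_points: int
    residual_rms: float
    weight: float


def default_window_frames(frame_interval_s: float, window_seconds: float = 0.5) -> int:
    """Frames per window for a target window duration (default half-second)."""
    return max(3, int(round(window_seconds / frame_interval_s)))


def partition_track(n_points_or_index, window_frames: int) -> list[np.ndarray]:
    """Split a track's point indices into consecutive windows.

    Windows hold ``window_frames`` points each; a trailing remainder of at
    least 3 points becomes a final shorter window, a smaller remainder is
    merged into the previous window.  Tracks shorter than 3 points yield no
    windows.
    """
    if window_frames < 3:
        raise InvalidParameterError("window_frames must be >= 3")
    if np.isscalar(n_points_or_index):
        index = np.arange(int(n_points_or_index))
    else:
        index = np.asarray(n_points_or_index)
    n = len(index)
    if n < 3:
        return []
    if n <= window_frames:
        return [index]
    k, rem = divmod(n, window_frames)
    bounds = [w * window_frames for w in range(k + 1)]
    if rem >= 3:
        bounds.append(n)
    else:
        bounds[-1] = n
    return [index[a:b] for a, b in zip(bounds[:-1], bounds[1:])]


def fit_segment_velocity(
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    pixel_size_um: float = 1.0,
) -> VelocityVector:
    """Weighted least-squares velocity of one window.

    Solves the closed-form normal equations of the two independent linear
    regressions x(t) and y(t); the slope pair is the velocity.  Points with
    zero weight are ignored entirely; all-zero weights raise
    :class:`InvalidWeightsError`.
    """
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.ones_like(t) if weights is None else np.asarray(weights, float)
    if np.any(w < 0):
        raise InvalidWeightsError("weights must be nonnegative")
    sw = w.sum()
    if sw <= 0:
        raise InvalidWeightsError("all weights are zero")
    if len(np.unique(t[w > 0])) < 2:
        raise InvalidParameterError("segment must span >= 2 distinct frames")

    tbar = (w * t).sum() / sw
    dt = t - tbar
    denom = (w * dt**2).sum()
    vx = (w * dt * x).sum() / denom
    vy = (w * dt * y).sum() / denom
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    rx = x - (xbar + vx * dt)
    ry = y - (ybar + vy * dt)
    rms = float(np.sqrt((w * (rx**2 + ry**2)).sum() / sw))
    return VelocityVector(
        x=float(xbar),
        y=float(ybar),
        vx=float(vx),
        vy=float(vy),
        t_mid=float(tbar),
        n_points=int((w > 0).sum()),
        residual_rms=rms,
        weight=float(1.0 / (1.0 + rms / pixel_size_um)),
    )


def collect_vectors(
    tracks: pd.DataFrame,
    frame_interval_s: float,
    pixel_size_um: float,
    window_frames: int | None = None,
    weight_scheme: str = "quality",
    roi_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Windowed WLS velocity vectors for every track.

    Parameters
    ----------
    tracks:
        ``track_id, frame, x_um, y_um[, quality]`` table from the linker.
    window_frames:
        Points per window; defaults to a half-second of frames.
    weight_scheme:
        ``"quality"`` normalizes detection qualities to (0, 1] within each
        window (falling back to uniform when degenerate), ``"uniform"`` uses
        unit weights.
    roi_mask:
        Optional boolean pixel mask; vectors whose centroid falls outside are
        discarded.

    Returns
    -------
    DataFrame ``x_um, y_um, vx_um_s, vy_um_s, t_mid_s, n_points,
    residual_rms_um, weight, track_id``.
    """
    if weight_scheme not in ("quality", "uniform"):
        raise InvalidParameterError(f"unknown weight_scheme {weight_scheme!r}")
    if window_frames is None:
        window_frames = default_window_frames(frame_interval_s)
    rows = []
    if len(tracks):
        for tid, grp in tracks.groupby("track_id", sort=True):
            grp = grp.sort_values("frame", kind="stable")
            t = grp["frame"].to_numpy() * frame_interval_s
            x = grp["x_um"].to_numpy()
            y = grp["y_um"].to_numpy()
            if weight_scheme == "quality" and "quality" in grp.columns:
                q = grp["quality"].to_numpy(dtype=float)
            else:
                q = np.ones(len(grp))
            for seg in partition_track(len(grp), window_frames):
                qs = q[seg]
                qmax = qs.max()
                w = qs / qmax if qmax > 0 and np.any(qs != qs[0]) else np.ones(len(seg))
                vec = fit_segment_velocity(
                    t[seg], x[seg], y[seg], w, pixel_size_um=pixel_size_um
                )
                rows.append(
                    {
                        "x_um": vec.x,
                        "y_um": vec.y,
                        "vx_um_s": vec.vx,
                        "vy_um_s": vec.vy,
                        "t_mid_s": vec.t_mid,
                        "n_points": vec.n_points,
                        "residual_rms_um": vec.residual_rms,
                        "weight": vec.weight,
                        "track_id": tid,
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "x_um",
            "y_um",
            "vx_um_s",
            "vy_um_s",
            "t_mid_s",
            "n_points",
            "residual_rms_um",
            "weight",
            "track_id",
        ],
    )
    if roi_mask is not None and len(df):
        rr = np.round(df["y_um"].to_numpy() / pixel_size_um).astype(int)
        cc = np.round(df["x_um"].to_numpy() / pixel_size_um).astype(int)
        h, w_ = roi_mask.shape
        inside = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w_)
        inside[inside] &= roi_mask[rr[inside], cc[inside]]
        df = df[inside].reset_index(drop=True)
    return df
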