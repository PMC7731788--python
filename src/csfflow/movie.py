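"""Calibrated movie container and multi-page TIFF I/O.

Movies are stored on disk as 16-bit multi-page TIFFs with a JSON sidecar
(``<stem>.json``) holding the spatial and temporal calibration::

    {"pixel_size_um": 2.0, "frame_interval_s": 0.0333}

Calibration passed explicitly (e.g. from a pipeline config) takes precedence
over the sidecar; a conflict is logged as a warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import InvalidParameterError

logger = logging.getLogger(__name__)

__all__ = ["Movie", "write_movie", "read_movie"]


@dataclass
class Movie:
    """T x H x W intensity stack with µm pixel size and frame interval in s."""

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise InvalidParameterError("movie data must be a (T, H, W) array")
        if self.data.shape[0] < 2:
            raise InvalidParameterError("a movie needs at least 2 frames")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise InvalidParameterError("calibration values must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_movie(movie: Movie, path) -> Path:
    """Write a 16-bit multi-page TIFF plus its calibration sidecar."""
    path = Path(path)
    data = np.clip(np.round(movie.data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    with open(_sidecar_path(path), "w") as fh:
        json.dump(
            {
                "pixel_size_um": movie.pixel_size_um,
                "frame_interval_s": movie.frame_interval_s,
            },
            fh,
        )
    return path


def read_movie(path, pixel_size_um=None, frame_interval_s=None) -> Movie:
    """Load a multi-page TIFF, resolving calibration from sidecar or arguments.

    Explicit arguments win over sidecar values; a disagreement beyond 1e-9
    relative is logged.  Missing calibration from both sources is an error, as
    is a single-frame file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"movie file not found: {path}")
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - tifffile message passthrough
        raise InvalidParameterError(f"unreadable TIFF {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise InvalidParameterError(f"expected a 2D time series in {path}")

    sidecar = {}
    sc_path = _sidecar_path(path)
    if sc_path.exists():
        with open(sc_path) as fh:
            sidecar = json.load(fh)

    def resolve(name, explicit):
        from_sidecar = sidecar.get(name)
        if explicit is not None and from_sidecar is not None:
            if abs(explicit - from_sidecar) > 1e-9 * max(abs(explicit), 1e-30):
                logger.warning(
                    "%s: config %s=%g overrides sidecar value %g",
                    path.name,
                    name,
                    explicit,
                    from_sidecar,
                )
            return explicit
        if explicit is not None:
            return explicit
        if from_sidecar is not None:
            return from_sidecar
        raise InvalidParameterError(
            f"missing calibration {name!r} for {path} (no sidecar, no config value)"
        )

    return Movie(
        data=data.astype(np.float32),
        pixel_size_um=float(resolve("pixel_size_um", pixel_size_um)),
        frame_interval_s=float(resolve("frame_interval_s", frame_interval_s)),
    )
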