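"""End-to-end orchestration: detect -> track -> velocity -> field -> stats.

Everything on disk is in µm and µm/s; frame indices and pixel coordinates are
0-based (CLI frame ranges are half-open).  A pipeline run writes every
intermediate table as CSV with fixed float formatting plus a manifest with a
content hash per artifact, so identical configs and inputs reproduce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .detection import detect_movie
from .errors import InvalidParameterError, PipelineStageError
from .gpr import DenseField, fit_gpr_component, predict_field
from .movie import Movie, read_movie
from .stats import ALPHA, median_speed, region_area
from .tracking import LinkParams, build_tracks
from .velocity import collect_vectors, default_window_frames

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionConfig",
    "LinkingConfig",
    "VelocityConfig",
    "GprConfig",
    "StatsConfig",
    "PipelineConfig",
    "PipelineResult",
    "analyze_movie",
    "run_pipeline",
    "validate_movie",
    "load_label_mask",
]

_CSV_FLOAT = "%.6f"


@dataclass
class DetectionConfig:
    blob_radius_um: float = 2.8
    quality_threshold: float | str = "auto"


@dataclass
class LinkingConfig:
    """Linking radii; if ``max_link_distance_um`` is unset it defaults to
    twice the per-frame displacement of the fastest expected flow."""

    max_link_distance_um: float | None = None
    fastest_speed_um_s: float | None = None
    max_gap_frames: int = 2
    max_gap_distance_um: float | None = None
    alt_cost_factor: float = 1.05

    def resolve(self, frame_interval_s: float) -> LinkParams:
        d = self.max_link_distance_um
        if d is None:
            if self.fastest_speed_um_s is None:
                raise InvalidParameterError(
                    "set max_link_distance_um or fastest_speed_um_s"
                )
            d = 2.0 * self.fastest_speed_um_s * frame_interval_s
        gap_d = self.max_gap_distance_um
        if gap_d is None:
            gap_d = 1.5 * d
        return LinkParams(
            max_link_distance_um=d,
            max_gap_frames=self.max_gap_frames,
            max_gap_distance_um=gap_d,
            alt_cost_factor=self.alt_cost_factor,
        )


@dataclass
class VelocityConfig:
    window_seconds: float = 0.5
    window_frames: int | None = None
    weight_scheme: str = "quality"

    def resolve(self, frame_interval_s: float) -> int:
        if self.window_frames is not None:
            return self.window_frames
        return default_window_frames(frame_interval_s, self.window_seconds)


@dataclass
class GprConfig:
    n_restarts: int = 3
    max_train: int = 2000
    opt_subset: int = 400


@dataclass
class StatsConfig:
    vector_source: str = "dense"  # "dense" field pixels or "sparse" stage-2 vectors
    alpha: float = ALPHA


@dataclass
class PipelineConfig:
    movie_path: str = ""
    mask_path: str = ""
    output_dir: str = "csfflow_out"
    pixel_size_um: float | None = None
    frame_interval_s: float | None = None
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    linking: LinkingConfig = field(default_factory=LinkingConfig)
    velocity: VelocityConfig = field(default_factory=VelocityConfig)
    gpr: GprConfig = field(default_factory=GprConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = json.load(fh)
        for key, sub in (
            ("detection", DetectionConfig),
            ("linking", LinkingConfig),
            ("velocity", VelocityConfig),
            ("gpr", GprConfig),
            ("stats", StatsConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)


@dataclass
class PipelineResult:
    detections: pd.DataFrame
    tracks: pd.DataFrame
    vectors: pd.DataFrame
    fields: dict[str, DenseField]
    reports: pd.DataFrame


def validate_movie(path, pixel_size_um=None, frame_interval_s=None) -> Movie:
    """Load and calibrate a movie file (config calibration wins over sidecar)."""
    return read_movie(path, pixel_size_um=pixel_size_um, frame_interval_s=frame_interval_s)


def load_label_mask(path, image_shape=None, pixel_size_um=None):
    """Load a compartment mask as (label image, name -> label dict).

    Accepts a single-page integer label TIFF (names default to the label
    numbers) or a polygon JSON ``{"name": [[x_um, y_um], ...], ...}`` which is
    rasterized onto the movie grid.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        labels = tifffile.imread(path)
        if labels.ndim != 2:
            raise InvalidParameterError("label mask TIFF must be single-page")
        labels = labels.astype(np.int32)
        names = {str(k): int(k) for k in np.unique(labels) if k != 0}
        return labels, names
    if path.suffix.lower() == ".json":
        if image_shape is None or pixel_size_um is None:
            raise InvalidParameterError(
                "polygon masks need the movie grid (image_shape, pixel_size_um)"
            )
        from . import geometry

        with open(path) as fh:
            polys = json.load(fh)
        labels = np.zeros(image_shape, np.int32)
        names = {}
        for k, (name, verts) in enumerate(sorted(polys.items()), start=1):
            poly = geometry.as_polygon(np.asarray(verts, float))
            labels[geometry.rasterize(poly, image_shape, pixel_size_um)] = k
            names[name] = k
        return labels, names
    raise InvalidParameterError(f"unsupported mask format: {path.suffix}")


def _stage(name):
    """Decorator-free stage wrapper: re-raise errors naming the stage."""

    class _Ctx:
        def __init__(self, stage_name):
            self.name = stage_name
            self.t0 = None

        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", self.name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                if isinstance(exc, PipelineStageError):
                    return False
                raise PipelineStageError(self.name, str(exc)) from exc
            logger.info(
                "stage %s: done in %.2fs", self.name, time.perf_counter() - self.t0
            )
            return False

    return _Ctx(name)


def analyze_movie(
    movie: Movie,
    label_img: np.ndarray,
    label_names: dict[str, int],
    detection: DetectionConfig | None = None,
    linking: LinkingConfig | None = None,
    velocity: VelocityConfig | None = None,
    gpr: GprConfig | None = None,
    stats_cfg: StatsConfig | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Run the full in-memory analysis chain on a calibrated movie.

    One GP field is fitted per labelled compartment (mirroring per-ventricle
    manual ROI segmentation); the compartmental report holds the median speed
    (dense-field pixels by default), vector/track counts and the
    cross-sectional area.
    """
    detection = detection or DetectionConfig()
    linking = linking or LinkingConfig()
    velocity = velocity or VelocityConfig()
    gpr = gpr or GprConfig()
    stats_cfg = stats_cfg or StatsConfig()

    with _stage("detect"):
        detections = detect_movie(
            movie, detection.blob_radius_um, detection.quality_threshold
        )
    with _stage("track"):
        params = linking.resolve(movie.frame_interval_s)
        tracks = build_tracks(detections, params)
    with _stage("velocity"):
        window = velocity.resolve(movie.frame_interval_s)
        vectors = collect_vectors(
            tracks,
            movie.frame_interval_s,
            movie.pixel_size_um,
            window_frames=window,
            weight_scheme=velocity.weight_scheme,
            roi_mask=label_img > 0,
        )

    fields: dict[str, DenseField] = {}
    rows = []
    px = movie.pixel_size_um
    for name, lab in label_names.items():
        with _stage(f"field[{name}]"):
            roi = label_img == lab
            rr = np.round(vectors["y_um"].to_numpy() / px).astype(int)
            cc = np.round(vectors["x_um"].to_numpy() / px).astype(int)
            h, w = label_img.shape
            ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            ok[ok] &= roi[rr[ok], cc[ok]]
            vecs = vectors[ok]
            fld = None
            if len(vecs) >= 5:
                pvx = fit_gpr_component(
                    vecs, "vx", n_restarts=gpr.n_restarts, seed=seed,
                    max_train=gpr.max_train, opt_subset=gpr.opt_subset,
                )
                pvy = fit_gpr_component(
                    vecs, "vy", n_restarts=gpr.n_restarts, seed=seed + 1,
                    max_train=gpr.max_train, opt_subset=gpr.opt_subset,
                )
                fld = predict_field(pvx, pvy, roi, px)
                fields[name] = fld
        with _stage(f"stats[{name}]"):
            if stats_cfg.vector_source == "dense" and fld is not None:
                rep = median_speed(fld, label=name)
            elif len(vecs):
                rep = median_speed(vecs, label=name)
            else:
                rep = None
            area = region_area(label_img, lab, px)
            rows.append(
                {
                    "label": name,
                    "n_tracks": int(vecs["track_id"].nunique()) if len(vecs) else 0,
                    "n_vectors": int(len(vecs)),
                    "median_speed_um_s": rep.median_speed_um_s if rep else np.nan,
                    "n_speed_samples": rep.n_vectors if rep else 0,
                    "area_um2": area.area_um2,
                    "pixel_count": area.pixel_count,
                }
            )
    reports = pd.DataFrame(rows)
    return PipelineResult(detections, tracks, vectors, fields, reports)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based pipeline run: load inputs, analyze, write all artifacts."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    with _stage("input-movie"):
        movie = validate_movie(
            config.movie_path,
            pixel_size_um=config.pixel_size_um,
            frame_interval_s=config.frame_interval_s,
        )
    with _stage("stats"):  # the mask is the stats stage's region input
        label_img, label_names = load_label_mask(
            config.mask_path,
            image_shape=movie.shape,
            pixel_size_um=movie.pixel_size_um,
        )

    result = analyze_movie(
        movie,
        label_img,
        label_names,
        detection=config.detection,
        linking=config.linking,
        velocity=config.velocity,
        gpr=config.gpr,
        stats_cfg=config.stats,
        seed=config.seed,
    )

    written = []

    def write_csv(df: pd.DataFrame, name: str):
        path = outdir / name
        df.to_csv(path, index=False, float_format=_CSV_FLOAT)
        written.append(path)

    write_csv(result.detections, "detections.csv")
    write_csv(result.tracks, "tracks.csv")
    tm = result.tracks.rename(
        columns={
            "track_id": "TRACK_ID",
            "frame": "FRAME",
            "x_um": "POSITION_X",
            "y_um": "POSITION_Y",
            "quality": "QUALITY",
        }
    )
    write_csv(tm, "tracks_trackmate.csv")
    write_csv(result.vectors, "vectors.csv")
    write_csv(result.reports, "reports.csv")
    for name, fld in result.fields.items():
        path = outdir / f"field_{name}.npz"
        np.savez_compressed(
            path,
            roi_mask=fld.roi_mask,
            vx_grid=fld.vx_grid,
            vy_grid=fld.vy_grid,
            sd_vx_grid=fld.sd_vx_grid,
            sd_vy_grid=fld.sd_vy_grid,
        )
        meta = outdir / f"field_{name}.json"
        with open(meta, "w") as fh:
            json.dump(
                {"pixel_size_um": fld.pixel_size_um, "hyperparams": fld.hyperparams},
                fh,
                indent=1,
            )
        written += [path, meta]
    with open(outdir / "reports.json", "w") as fh:
        json.dump(result.reports.to_dict(orient="records"), fh, indent=1)
    written.append(outdir / "reports.json")

    cfg_dict = dataclasses.asdict(config)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "parameter_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "outputs": {p.name: _sha256(p) for p in written},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return result
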