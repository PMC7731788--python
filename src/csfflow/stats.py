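"""Compartmental flow summaries and nonparametric group comparisons.

The compartmental summary statistic is the median speed: the median of the
Euclidean norms of all velocity vectors collected in a subregion, either from
the dense GP field (one vector per masked pixel, the default) or from the
sparse stage-2 vectors.  Pre/post comparisons within animals use the Wilcoxon
matched-pairs signed-rank test; control-vs-morphant comparisons use the
Mann-Whitney U test.  Both are two-sided with significance declared at
p < 0.01.

The signed-rank exact path (n <= 25 after dropping zero differences) midranks
ties and evaluates the exact conditional null distribution of W+ by a
subset-sum convolution over the doubled ranks, so tied data still get exact
p-values.  Mann-Whitney uses the exact distribution when both groups have at
most 10 tie-free observations and the tie-corrected normal approximation
otherwise (no continuity correction, so identical samples give p = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import geometry
from .errors import DegenerateInputError, EmptyRegionError, InvalidParameterError
from .gpr import DenseField

__all__ = [
    "SpeedReport",
    "AreaReport",
    "median_speed",
    "region_area",
    "compare_paired",
    "compare_unpaired",
]

ALPHA = 0.01


@dataclass
class SpeedReport:
    region_label: str
    n_vectors: int
    median_speed_um_s: float
    per_animal_um_s: list | None = None


@dataclass
class AreaReport:
    region_label: str
    area_um2: float
    pixel_count: int


def _norms_from_field(field: DenseField, submask):
    sel = field.roi_mask if submask is None else (field.roi_mask & np.asarray(submask, bool))
    speeds = field.speed_grid[sel]
    return speeds[np.isfinite(speeds)]


def _norms_from_vectors(vectors: pd.DataFrame, subregion):
    vx = vectors["vx_um_s"].to_numpy(dtype=float)
    vy = vectors["vy_um_s"].to_numpy(dtype=float)
    if subregion is None:
        keep = np.ones(len(vectors), bool)
    else:
        poly = geometry.as_polygon(subregion)
        keep = geometry.contains(
            poly, vectors["x_um"].to_numpy(), vectors["y_um"].to_numpy()
        )
    return np.hypot(vx[keep], vy[keep])


def median_speed(source, subregion=None, label: str = "") -> SpeedReport:
    """Median vector norm over a subregion.

    ``source`` is either a :class:`~csfflow.gpr.DenseField` (subregion: a
    boolean pixel mask, optional) or a sparse vector DataFrame (subregion: a
    polygon in µm, optional).  Even counts use the midpoint convention of
    :func:`numpy.median`.
    """
    if isinstance(source, DenseField):
        norms = _norms_from_field(source, subregion)
    elif isinstance(source, pd.DataFrame):
        norms = _norms_from_vectors(source, subregion)
    else:
        raise InvalidParameterError("source must be a DenseField or a vector DataFrame")
    if len(norms) == 0:
        raise EmptyRegionError("no velocity vectors in the requested subregion")
    return SpeedReport(
        region_label=label,
        n_vectors=int(len(norms)),
        median_speed_um_s=float(np.median(norms)),
    )


def region_area(label_mask: np.ndarray, label: int, pixel_size_um: float) -> AreaReport:
    """Cross-sectional area of one labelled region: pixel count x pixel area."""
    label_mask = np.asarray(label_mask)
    count = int((label_mask == label).sum())
    if count == 0:
        raise InvalidParameterError(f"label {label!r} not present in mask")
    return AreaReport(
        region_label=str(label),
        area_um2=count * pixel_size_um**2,
        pixel_count=count,
    )


def _exact_signed_rank_p(ranks: np.ndarray, signs: np.ndarray) -> tuple[float, float]:
    """Exact two-sided p for W+ with midranked ties, by subset-sum DP."""
    r2 = np.round(2 * ranks).astype(np.int64)  # midranks doubled -> integers
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(np.round(2 * ranks[signs > 0].sum()))
    lo = counts[: w2 + 1].sum()
    hi = counts[w2:].sum()
    p = min(1.0, 2.0 * min(lo, hi))
    return float(ranks[signs > 0].sum()), p


def compare_paired(before, after, alpha: float = ALPHA) -> dict:
    """Wilcoxon matched-pairs signed-rank test (two-sided).

    Zero differences are dropped; tied absolute differences receive
    midranks.  For n <= 25 remaining pairs the exact conditional distribution
    is used, otherwise the normal approximation.  ``significant`` is
    ``p < alpha`` (default 0.01).
    """
    before = np.asarray(before, float)
    after = np.asarray(after, float)
    if before.shape != after.shape or before.ndim != 1:
        raise InvalidParameterError("before/after must be equal-length 1D arrays")
    if len(before) < 5:
        raise InvalidParameterError("paired comparison needs >= 5 pairs")
    d = after - before
    d = d[d != 0]
    if len(d) == 0:
        raise DegenerateInputError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    if len(d) <= 25:
        stat, p = _exact_signed_rank_p(ranks, np.sign(d))
        method = "exact"
    else:
        res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method="approx")
        stat, p = float(res.statistic), float(res.pvalue)
        method = "normal-approx"
    return {
        "statistic": stat,
        "p": p,
        "significant": bool(p < alpha),
        "n": int(len(d)),
        "method": method,
    }


def compare_unpaired(group_a, group_b, alpha: float = ALPHA) -> dict:
    """Two-sided Mann-Whitney U test between independent groups."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 3 or len(b) < 3:
        raise InvalidParameterError("each group needs >= 3 observations")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(a) <= 10) and (len(b) <= 10) and not has_ties
    res = sps.mannwhitneyu(
        a,
        b,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=False,
    )
    return {
        "U": float(res.statistic),
        "p": float(res.pvalue),
        "significant": bool(res.pvalue < alpha),
        "method": "exact" if exact else "normal-approx-tie-corrected",
    }
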