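"""Global shape observables: compaction, polar distance profiles, plectoneme apices.

A plectoneme apex is the tip of the interwound superhelix — the point of
the axis contour farthest from the molecule's centroid.  Profiles of the
per-bp distance to the centroid ("polar profiles") therefore show apices as
pronounced maxima; anchoring the angular coordinate at a marked site (a
protein binding site) makes ensembles comparable frame to frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .topology import Contour

__all__ = [
    "PolarProfile",
    "ApexCall",
    "radius_of_gyration",
    "polar_profile",
    "detect_apices",
    "apex_occupancy",
    "circular_distance",
]


@dataclass
class PolarProfile:
    """Per-bp distance-to-centroid statistics across an ensemble of contours."""

    distances: np.ndarray        # (n_frames, n_bp) per-frame distances, A
    mean: np.ndarray             # (n_bp,)
    sd: np.ndarray               # (n_bp,)
    angles: np.ndarray           # (n_bp,) radians, site at angle 0
    site: int


@dataclass(frozen=True)
class ApexCall:
    """One detected plectoneme apex."""

    bp_position: int
    prominence: float
    frame_index: int


def circular_distance(i: int, j: int, n: int) -> int:
    """Shortest distance between two positions on a ring of n sites."""
    d = abs(int(i) - int(j)) % n
    return min(d, n - d)


def radius_of_gyration(points: np.ndarray) -> float:
    """Unweighted root-mean-square distance of points from their centroid."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("radius of gyration needs at least 2 points")
    centered = pts - pts.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))


def polar_profile(contours: list[Contour | np.ndarray], site: int = 0) -> PolarProfile:
    """Mean (+/- sd) distance from each axis point to its frame's centroid.

    The angular coordinate places the marked site at angle 0:
    ``angle(bp) = 2 pi (bp - site) / n``.
    """
    if len(contours) == 0:
        raise ValueError("empty trajectory")
    arrs = [c.points if isinstance(c, Contour) else np.asarray(c, float) for c in contours]
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("all contours must have the same length")
    if not (0 <= site < n):
        raise ValueError("site outside contour")
    stack = np.stack(arrs)                             # (F, n, 3)
    centroids = stack.mean(axis=1, keepdims=True)
    dist = np.linalg.norm(stack - centroids, axis=2)   # (F, n)
    angles = 2.0 * np.pi * (np.arange(n) - site) / n
    return PolarProfile(
        distances=dist,
        mean=dist.mean(axis=0),
        sd=dist.std(axis=0),
        angles=angles,
        site=site,
    )


def detect_apices(
    distances: np.ndarray,
    smooth_window: int = 5,
    min_prominence: float | None = None,
    frame_index: int = 0,
) -> list[ApexCall]:
    """Local maxima of a circular per-bp distance series.

    The series is circularly smoothed with a ``smooth_window``-bp moving
    average, then peaks with prominence >= ``min_prominence`` (default
    0.5 * sd of the smoothed series) are reported sorted by prominence
    descending, ties broken by larger distance then lower bp index.
    """
    series = np.asarray(distances, dtype=float)
    n = len(series)
    if smooth_window >= n:
        raise ValueError("smooth_window must be < series length")
    if smooth_window > 1:
        series = uniform_filter1d(series, size=smooth_window, mode="wrap")
    if min_prominence is None:
        min_prominence = 0.5 * float(series.std())
    if series.std() < 1e-12:
        return []
    # unwrap the ring: find peaks on three tiled copies, keep the middle one
    tiled = np.concatenate([series, series, series])
    peaks, props = find_peaks(tiled, prominence=max(min_prominence, 1e-12))
    keep = (peaks >= n) & (peaks < 2 * n)
    pos = peaks[keep] - n
    prom = props["prominences"][keep]
    order = sorted(
        range(len(pos)),
        key=lambda k: (-prom[k], -series[pos[k]], pos[k]),
    )
    return [ApexCall(int(pos[k]), float(prom[k]), frame_index) for k in order]


def apex_occupancy(
    apex_calls: list[list[ApexCall]], site: int, tolerance: int, n_bp: int
) -> float:
    """Fraction of frames whose top-ranked apex falls within +/- tolerance bp
    (circular) of the site.

    Frames with no detected apex count as misses; if no frame has any apex
    the function returns 0.0 with a warning.
    """
    if len(apex_calls) == 0:
        raise ValueError("no frames supplied")
    if all(len(calls) == 0 for calls in apex_calls):
        warnings.warn("no apices detected in any frame", stacklevel=2)
        return 0.0
    hits = sum(
        1
        for calls in apex_calls
        if calls and circular_distance(calls[0].bp_position, site, n_bp) <= tolerance
    )
    return hits / len(apex_calls)
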