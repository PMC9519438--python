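"""Global DNA topology: twist, writhe, linking number and derived quantities.

The central conservation law is White's theorem, Lk = Tw + Wr, relating the
(integer, topologically invariant) linking number of the two backbone
strands of a closed duplex to the twist of the ribbon about its axis and
the writhe of the axis curve.  Writhe is evaluated with the exact
closed-form solid-angle contribution for each pair of straight segments
(the Klenin-Langowski method), which makes the per-frame arc decomposition
used by :mod:`supertwist.domains` exactly additive.

Superhelical density is sigma = (Lk - Lk0) / Lk0, the fractional over- or
underwinding relative to the relaxed linking number Lk0.  Lk0 itself is
calibrated by a linear fit of mean writhe versus Lk over a set of bare
topoisomers: the root of the fitted line is the Lk at which the relaxed
molecule carries no writhe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.ndimage import correlate1d, uniform_filter1d

from .minicircle import RibbonConformation

__all__ = [
    "Contour",
    "TopologyRecord",
    "CalibrationResult",
    "extract_axis",
    "writhe",
    "writhe_cross",
    "twist_global",
    "linking_number",
    "superhelical_density",
    "calibrate_lk0",
    "site_accumulated_twist",
    "analyse_ribbon",
]


# ---------------------------------------------------------------------------
# contour container
# ---------------------------------------------------------------------------

@dataclass
class Contour:
    """Closed polyline through the helical axis; the segment n-1 -> 0 is implied."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.ascontiguousarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must have shape (n, 3)")
        if len(self.points) < 3:
            raise ValueError("a closed contour needs at least 3 points")
        seg = np.roll(self.points, -1, axis=0) - self.points
        if np.any(np.linalg.norm(seg, axis=1) < 1e-12):
            raise ValueError("contour has coincident consecutive points")

    @property
    def n(self) -> int:
        return len(self.points)

    def segments(self) -> tuple[np.ndarray, np.ndarray]:
        """Start and end points of the n closing segments."""
        return self.points, np.roll(self.points, -1, axis=0)


@dataclass
class TopologyRecord:
    """Per-frame topology summary: Lk, Tw, Wr, sigma and binding-site twist."""

    frame_index: int
    lk: float
    tw: float
    wr: float
    sigma: float | None = None
    site_twist: float | None = None


@dataclass
class CalibrationResult:
    """Relaxed linking number from the linear fit wr = slope * (lk - lk0)."""

    lk0: float
    slope: float
    intercept: float
    r_squared: float
    points: list[tuple[float, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# axis extraction
# ---------------------------------------------------------------------------

def extract_axis(bp_centers: np.ndarray, window: int) -> Contour:
    """Helical-axis contour as a circular moving average of bp centres.

    A window of one helical repeat (round(n_bp / lk), about 10-11 bp for
    B-DNA) removes the helical wobble of the backbone exactly for ideal
    helices.  ``window=1`` is the identity.
    """
    pts = np.asarray(bp_centers, dtype=float)
    n = len(pts)
    if window < 1 or window >= n:
        raise ValueError("window must satisfy 1 <= window < n")
    if n < 3 * window:
        raise ValueError("need at least 3*window points")
    if window == 1:
        return Contour(pts.copy())
    if window % 2 == 1:
        smoothed = uniform_filter1d(pts, size=window, axis=0, mode="wrap")
    else:
        # symmetric boxcar for even windows: half-weight endpoints keep the
        # filter centred (a plain even-sized mean is shifted by half a step)
        weights = np.full(window + 1, 1.0 / window)
        weights[0] = weights[-1] = 0.5 / window
        smoothed = correlate1d(pts, weights, axis=0, mode="wrap")
    return Contour(smoothed)


# ---------------------------------------------------------------------------
# writhe: exact per-segment-pair solid angle (Klenin & Langowski method)
# ---------------------------------------------------------------------------

def _cross3(a, b):
    """Row-wise cross product of (m, 3) arrays (faster than np.cross)."""
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


def _dot3(a, b):
    return a[:, 0] * b[:, 0] + a[:, 1] * b[:, 1] + a[:, 2] * b[:, 2]


def _pair_writhe_contrib(p1, p2, q1, q2):
    """Gauss-integral contribution Omega/(4 pi) for segment pairs.

    Inputs are (m, 3) arrays of segment endpoints; returns an (m,) array.
    Uses the exact solid angle of the quadrilateral spanned by the two
    segments.  Degenerate (coplanar or touching) pairs contribute zero.
    """
    r12 = p2 - p1
    r34 = q2 - q1
    r13 = q1 - p1
    r14 = q2 - p1
    r23 = q1 - p2
    r24 = q2 - p2

    n1 = _cross3(r13, r14)
    n2 = _cross3(r14, r24)
    n3 = _cross3(r24, r23)
    n4 = _cross3(r23, r13)

    def _unit(v):
        norm2 = _dot3(v, v)
        ok = norm2 > 1e-24
        inv = np.zeros_like(norm2)
        np.divide(1.0, np.sqrt(norm2, where=ok, out=np.ones_like(norm2)), out=inv, where=ok)
        return v * inv[:, None], ok

    u1, ok1 = _unit(n1)
    u2, ok2 = _unit(n2)
    u3, ok3 = _unit(n3)
    u4, ok4 = _unit(n4)

    def _asin_dot(a, b):
        return np.arcsin(np.clip(_dot3(a, b), -1.0, 1.0))

    omega = _asin_dot(u1, u2) + _asin_dot(u2, u3) + _asin_dot(u3, u4) + _asin_dot(u4, u1)
    sign = np.sign(_dot3(_cross3(r34, r12), r13))
    contrib = omega * sign / (4.0 * np.pi)
    contrib[~(ok1 & ok2 & ok3 & ok4)] = 0.0
    return contrib


def _nonadjacent_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Unordered segment index pairs of a closed n-gon, excluding adjacent."""
    ii, jj = np.triu_indices(n, k=2)
    keep = ~((ii == 0) & (jj == n - 1))  # segments n-1 and 0 are adjacent on the ring
    return ii[keep], jj[keep]


#: pairs per chunk when evaluating large Gauss sums (bounds peak memory)
_PAIR_CHUNK = 1_000_000


def _chunked_pair_sum(a0, a1, ii, jj) -> float:
    total = 0.0
    for lo in range(0, len(ii), _PAIR_CHUNK):
        sl = slice(lo, lo + _PAIR_CHUNK)
        total += float(_pair_writhe_contrib(a0[ii[sl]], a1[ii[sl]], a0[jj[sl]], a1[jj[sl]]).sum())
    return total


def writhe(contour: Contour | np.ndarray) -> float:
    """Writhe of a closed polyline via the exact segment-pair solid angle.

    Adjacent and identical segment pairs contribute zero by convention.
    Right-handed crossings count positive; a planar curve has Wr = 0.
    """
    if not isinstance(contour, Contour):
        contour = Contour(contour)
    a, b = contour.segments()
    ii, jj = _nonadjacent_pairs(contour.n)
    return 2.0 * _chunked_pair_sum(a, b, ii, jj)


def writhe_cross(points: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> float:
    """Cross-writhe between two disjoint sets of segments of one closed curve.

    ``wr_ab = (1/4pi) * sum_{i in a, j in b} Omega_ij`` so that for a
    partition of the ring into arcs a and b,
    ``writhe(full) = wr_aa + wr_bb + 2 * wr_ab`` holds exactly.
    Adjacent segment pairs (sharing an endpoint on the ring) contribute zero.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    a0, a1 = pts, np.roll(pts, -1, axis=0)
    ii, jj = np.meshgrid(np.asarray(idx_a), np.asarray(idx_b), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    adjacent = (ii == jj) | ((ii + 1) % n == jj) | ((jj + 1) % n == ii)
    ii, jj = ii[~adjacent], jj[~adjacent]
    contrib = _pair_writhe_contrib(a0[ii], a1[ii], a0[jj], a1[jj])
    return float(contrib.sum())


def writhe_arc(points: np.ndarray, idx: np.ndarray) -> float:
    """Self-writhe of one arc of a closed curve (pairs within the arc)."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    a0, a1 = pts, np.roll(pts, -1, axis=0)
    idx = np.asarray(idx)
    ii, jj = np.triu_indices(len(idx), k=1)
    si, sj = idx[ii], idx[jj]
    adjacent = ((si + 1) % n == sj) | ((sj + 1) % n == si)
    si, sj = si[~adjacent], sj[~adjacent]
    contrib = _pair_writhe_contrib(a0[si], a1[si], a0[sj], a1[sj])
    return float(2.0 * contrib.sum())


# ---------------------------------------------------------------------------
# twist via parallel transport
# ---------------------------------------------------------------------------

def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    c, s = np.cos(angle), np.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1.0 - c)


def _transport(v: np.ndarray, t_from: np.ndarray, t_to: np.ndarray) -> np.ndarray:
    """Parallel transport v through the minimal rotation taking t_from to t_to."""
    axis = np.cross(t_from, t_to)
    s = np.linalg.norm(axis)
    c = float(np.clip(t_from @ t_to, -1.0, 1.0))
    if s < 1e-14:
        if c > 0:
            return v.copy()
        raise ValueError("antiparallel consecutive tangents; transport undefined")
    return _rotate_about(v, axis / s, np.arctan2(s, c))


def _signed_angle(a: np.ndarray, b: np.ndarray, axis: np.ndarray) -> float:
    """Signed angle from a to b about a unit axis, in (-pi, pi]."""
    return float(np.arctan2(axis @ np.cross(a, b), a @ b))


def twist_global(ribbon: RibbonConformation) -> float:
    """Global twist of a closed ribbon, in turns.

    Sums, over every step of the ring (including the closing step), the
    signed rotation of the reference vector about the local tangent after
    parallel transport of the frame along the axis.
    """
    ribbon.validate_frames(tol=1e-6)
    if not ribbon.closed:
        raise ValueError("global twist requires a closed ribbon")
    t = ribbon.tangents
    r = ribbon.references
    n = ribbon.n_bp
    total = 0.0
    for i in range(n):
        j = (i + 1) % n
        carried = _transport(r[i], t[i], t[j])
        # remove any residual tangent component before measuring the angle
        carried = carried - (carried @ t[j]) * t[j]
        carried /= np.linalg.norm(carried)
        actual = r[j] - (r[j] @ t[j]) * t[j]
        actual /= np.linalg.norm(actual)
        total += _signed_angle(carried, actual, t[j])
    return total / (2.0 * np.pi)


# ---------------------------------------------------------------------------
# linking number
# ---------------------------------------------------------------------------

def linking_number(
    strand1: np.ndarray,
    strand2: np.ndarray,
    warn_tol: float = 0.05,
    raw: bool = False,
) -> int | float:
    """Gauss linking number of two disjoint closed polylines.

    The raw double integral is rounded to the nearest integer; a residual
    beyond ``warn_tol`` triggers a warning (curves too coarse or too close).
    ``raw=True`` returns the unrounded integral, whose distance from an
    integer measures the discretization error.
    """
    c1 = Contour(np.asarray(strand1, dtype=float))
    c2 = Contour(np.asarray(strand2, dtype=float))
    a0, a1 = c1.segments()
    b0, b1 = c2.segments()
    ii, jj = np.meshgrid(np.arange(c1.n), np.arange(c2.n), indexing="ij")
    contrib = _pair_writhe_contrib(
        a0[ii.ravel()], a1[ii.ravel()], b0[jj.ravel()], b1[jj.ravel()]
    )
    integral = float(contrib.sum())
    if raw:
        return integral
    lk = int(np.rint(integral))
    if abs(integral - lk) > warn_tol:
        warnings.warn(
            f"Gauss integral {integral:.4f} is {abs(integral - lk):.4f} from an "
            "integer; curves may be too coarsely sampled or nearly touching",
            stacklevel=2,
        )
    return lk


# ---------------------------------------------------------------------------
# superhelical density and Lk0 calibration
# ---------------------------------------------------------------------------

def superhelical_density(lk: float, lk0: float) -> float:
    """sigma = (Lk - Lk0) / Lk0, the fractional over/underwinding."""
    if lk0 <= 0:
        raise ValueError("lk0 must be positive")
    return (lk - lk0) / lk0


def calibrate_lk0(points: list[tuple[float, float]]) -> CalibrationResult:
    """Relaxed linking number from a linear fit of mean writhe versus Lk.

    Fits wr = slope * lk + intercept by ordinary least squares over bare
    topoisomers and returns the root lk0 = -intercept / slope, the Lk at
    which the relaxed circle carries no writhe.
    """
    pts = [(float(a), float(b)) for a, b in points]
    if len({a for a, _ in pts}) < 3:
        raise ValueError("calibration needs at least 3 distinct lk values")
    lk = np.array([a for a, _ in pts])
    wr = np.array([b for _, b in pts])
    fit = stats.linregress(lk, wr)
    if abs(fit.slope) < 1e-12:
        raise ValueError("degenerate fit: zero slope, no root")
    return CalibrationResult(
        lk0=float(-fit.intercept / fit.slope),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        points=pts,
    )


# ---------------------------------------------------------------------------
# binding-site accumulated twist
# ---------------------------------------------------------------------------

def site_accumulated_twist(
    ribbon: RibbonConformation, bp_range: tuple[int, int]
) -> float:
    """Accumulated dinucleotide twist over a bp range, in degrees.

    Sums the signed rotation of the reference vector about the local
    tangent over the dinucleotide steps ``start -> start+1`` up to
    ``end-1 -> end`` (half-open over step indices, wrapping across the
    origin allowed).  This is a simplified dinucleotide twist: the rotation
    of the bp reference vector about the tangent, not the full mid-frame
    step-parameter algebra.
    """
    start, end = bp_range
    n = ribbon.n_bp
    if not (0 <= start < n and 0 <= end < n + 1):
        raise ValueError("bp_range outside [0, n_bp)")
    n_steps = (end - start) % n if end != start else 0
    if n_steps == 0:
        raise ValueError("empty bp range")
    t = ribbon.tangents
    r = ribbon.references
    total = 0.0
    for k in range(n_steps):
        i = (start + k) % n
        j = (i + 1) % n
        carried = _transport(r[i], t[i], t[j])
        carried = carried - (carried @ t[j]) * t[j]
        carried /= np.linalg.norm(carried)
        actual = r[j] - (r[j] @ t[j]) * t[j]
        actual /= np.linalg.norm(actual)
        total += _signed_angle(carried, actual, t[j])
    return float(np.rad2deg(total))


# ---------------------------------------------------------------------------
# convenience: full per-frame record
# ---------------------------------------------------------------------------

def analyse_ribbon(
    ribbon: RibbonConformation,
    frame_index: int = 0,
    lk0: float | None = None,
    site: tuple[int, int] | None = None,
) -> TopologyRecord:
    """Tw, Wr, Lk = Tw + Wr, sigma and optional site twist for one frame."""
    tw = twist_global(ribbon)
    wr = writhe(Contour(ribbon.origins))
    lk = tw + wr
    sigma = superhelical_density(lk, lk0) if lk0 is not None else None
    site_tw = site_accumulated_twist(ribbon, site) if site is not None else None
    return TopologyRecord(
        frame_index=frame_index, lk=lk, tw=tw, wr=wr, sigma=sigma, site_twist=site_tw
    )
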