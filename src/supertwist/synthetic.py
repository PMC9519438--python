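"""Synthetic conformation generators for the whole pipeline.

Every input the analysis stages consume can be generated here at desk
scale, with fixed seeds and no downloads:

* ``mc_ensemble`` — a closed twistable elastic-chain Metropolis Monte
  Carlo at fixed linking-number offset delta-Lk.  Bending is a harmonic
  penalty on the angle between successive segments; torsion is handled
  implicitly through a harmonic penalty ``(2 pi^2 P_t / L) (dLk - Wr)^2``
  on the writhe, which is the torsional energy of a twistable rod whose
  twist relaxes instantaneously at fixed Lk.  Crankshaft moves (rigid
  rotation of a sub-chain about the chord between two pivots) preserve
  closure by construction, so White's theorem holds for every frame.
* ``ribbon_from_contour`` — dresses any closed axis curve with reference
  vectors carrying a prescribed integer linking number (parallel-transport
  frame plus uniform twist), the bridge from bead models to ribbons.
* ``parametric_curve`` — closed curves of known or oracle-computed writhe.
* ``bridged_trajectory`` — a two-loop (255 bp / 81 bp) bridged minicircle
  whose per-loop writhes evolve independently or in exact compensation.
* ``planted_complex`` — protein-DNA frames realizing prescribed
  hydrogen-bond patterns, the ground truth for binding-mode clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .binding_modes import AtomSelection, detect_hbonds
from .minicircle import RibbonConformation
from .topology import (
    Contour,
    _pair_writhe_contrib,
    _signed_angle,
    _transport,
    _rotate_about,
    writhe,
)

__all__ = [
    "MCParams",
    "MCTrajectory",
    "PlantedComplexSpec",
    "PlantedComplexTrajectory",
    "BridgedTrajectory",
    "mc_ensemble",
    "ribbon_from_contour",
    "parametric_curve",
    "bridged_trajectory",
    "planted_complex",
]


# ---------------------------------------------------------------------------
# ribbon closure: axis curve -> closed ribbon at prescribed Lk
# ---------------------------------------------------------------------------

def ribbon_from_contour(points: np.ndarray, lk: int) -> RibbonConformation:
    """Dress a closed axis polyline with a ribbon of linking number ``lk``.

    A relatively parallel (twist-free) frame is transported around the
    curve; its closure mismatch absorbs the writhe contribution, and a
    uniform per-step twist is added so that the reference vector returns
    to its start after an integer number of turns with total twist
    Tw = lk - Wr.  The resulting ribbon satisfies White's theorem with
    linking number exactly ``lk`` up to discretization error.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    edges = np.roll(pts, -1, axis=0) - pts
    tangents = edges / np.linalg.norm(edges, axis=1, keepdims=True)

    # twist-free transported frame
    u = np.zeros((n, 3))
    seed_vec = np.array([0.0, 0.0, 1.0])
    if abs(seed_vec @ tangents[0]) > 0.9:
        seed_vec = np.array([1.0, 0.0, 0.0])
    u0 = seed_vec - (seed_vec @ tangents[0]) * tangents[0]
    u[0] = u0 / np.linalg.norm(u0)
    for i in range(n - 1):
        v = _transport(u[i], tangents[i], tangents[i + 1])
        v -= (v @ tangents[i + 1]) * tangents[i + 1]
        u[i + 1] = v / np.linalg.norm(v)
    loop_back = _transport(u[n - 1], tangents[n - 1], tangents[0])
    loop_back -= (loop_back @ tangents[0]) * tangents[0]
    loop_back /= np.linalg.norm(loop_back)
    alpha = _signed_angle(u[0], loop_back, tangents[0])

    wr = writhe(Contour(pts))
    k = int(np.rint(lk - wr + alpha / (2.0 * np.pi)))
    delta = (2.0 * np.pi * k - alpha) / n
    if abs(delta) >= np.pi:
        raise ValueError(
            f"cannot carry Lk={lk} on {n} points: per-step twist |{np.degrees(delta):.0f} deg| "
            ">= 180 deg would alias; use more points or a smaller linking number"
        )
    idx = np.arange(n)
    references = np.stack(
        [_rotate_about(u[i], tangents[i], idx[i] * delta) for i in range(n)]
    )
    return RibbonConformation(
        origins=pts, tangents=tangents, references=references, closed=True
    )


# ---------------------------------------------------------------------------
# closed twistable-chain Monte Carlo
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MCParams:
    """Settings of the closed twistable elastic-chain Monte Carlo.

    Persistence lengths default to standard B-DNA values (bend 500 A,
    twist 750 A).  ``delta_lk`` is the linking-number offset from the
    relaxed reference ``lk_reference``; ``excluded_diameter`` = 0 disables
    excluded volume.  Energies are expressed in units of kB T at the given
    temperature.
    """

    n_beads: int = 84
    bead_spacing: float = 13.6           # A; 336 bp * 3.4 A / 84 beads
    bend_persistence: float = 500.0      # A
    twist_persistence: float = 750.0     # A
    delta_lk: float = 0.0
    temperature: float = 300.0
    n_steps: int = 200_000
    move_amplitude: float = 0.8          # radians
    excluded_diameter: float = 0.0       # A
    seed: int = 0
    save_stride: int = 200
    lk_reference: int = 31               # relaxed turns of the emulated circle

    def __post_init__(self) -> None:
        if self.n_beads < 20:
            raise ValueError("n_beads must be >= 20")
        if self.bend_persistence <= 0 or self.twist_persistence <= 0:
            raise ValueError("persistence lengths must be positive")
        if self.save_stride < 1:
            raise ValueError("save_stride must be >= 1")


@dataclass
class MCTrajectory:
    """Frames and bookkeeping emitted by :func:`mc_ensemble`."""

    params: MCParams
    contours: list[np.ndarray]
    ribbons: list[RibbonConformation]
    writhes: np.ndarray
    implied_twist: np.ndarray     # delta-Lk - Wr per saved frame, turns
    energies: np.ndarray
    acceptance_fraction: float

    def __len__(self) -> int:
        return len(self.contours)


def _bend_energy_at(pts: np.ndarray, beads: np.ndarray, coeff: float) -> float:
    """Harmonic bend energy contributions of the angles at given beads."""
    n = len(pts)
    prev_e = pts[beads] - pts[(beads - 1) % n]
    next_e = pts[(beads + 1) % n] - pts[beads]
    prev_u = prev_e / np.linalg.norm(prev_e, axis=1, keepdims=True)
    next_u = next_e / np.linalg.norm(next_e, axis=1, keepdims=True)
    cosang = np.clip(np.einsum("ij,ij->i", prev_u, next_u), -1.0, 1.0)
    theta = np.arccos(cosang)
    return coeff * float(np.sum(theta**2))


def _pair_sum_numpy(pts: np.ndarray, nxt: np.ndarray, ii: np.ndarray, jj: np.ndarray) -> float:
    return float(_pair_writhe_contrib(pts[ii], nxt[ii], pts[jj], nxt[jj]).sum())


try:  # optional numba speedup of the MC inner loop
    from numba import njit as _njit

    @_njit(cache=True, fastmath=True)
    def _pair_sum_jit(pts, nxt, ii, jj):  # pragma: no cover - numeric twin of numpy path
        total = 0.0
        for k in range(ii.size):
            i, j = ii[k], jj[k]
            omega = 0.0
            p1x, p1y, p1z = pts[i, 0], pts[i, 1], pts[i, 2]
            p2x, p2y, p2z = nxt[i, 0], nxt[i, 1], nxt[i, 2]
            q1x, q1y, q1z = pts[j, 0], pts[j, 1], pts[j, 2]
            q2x, q2y, q2z = nxt[j, 0], nxt[j, 1], nxt[j, 2]
            r13 = (q1x - p1x, q1y - p1y, q1z - p1z)
            r14 = (q2x - p1x, q2y - p1y, q2z - p1z)
            r23 = (q1x - p2x, q1y - p2y, q1z - p2z)
            r24 = (q2x - p2x, q2y - p2y, q2z - p2z)

            def cr(a, b):
                return (
                    a[1] * b[2] - a[2] * b[1],
                    a[2] * b[0] - a[0] * b[2],
                    a[0] * b[1] - a[1] * b[0],
                )

            n1 = cr(r13, r14)
            n2 = cr(r14, r24)
            n3 = cr(r24, r23)
            n4 = cr(r23, r13)
            ok = True
            units = []
            for v in (n1, n2, n3, n4):
                nrm2 = v[0] * v[0] + v[1] * v[1] + v[2] * v[2]
                if nrm2 <= 1e-24:
                    ok = False
                    units.append((0.0, 0.0, 0.0))
                else:
                    inv = 1.0 / np.sqrt(nrm2)
                    units.append((v[0] * inv, v[1] * inv, v[2] * inv))
            if not ok:
                continue
            for kk in range(4):
                a = units[kk]
                b = units[(kk + 1) % 4]
                d = a[0] * b[0] + a[1] * b[1] + a[2] * b[2]
                if d > 1.0:
                    d = 1.0
                elif d < -1.0:
                    d = -1.0
                omega += np.arcsin(d)
            r12 = (p2x - p1x, p2y - p1y, p2z - p1z)
            r34 = (q2x - q1x, q2y - q1y, q2z - q1z)
            cx = cr(r34, r12)
            s = cx[0] * r13[0] + cx[1] * r13[1] + cx[2] * r13[2]
            sign = 1.0 if s > 0 else (-1.0 if s < 0 else 0.0)
            total += omega * sign
        return total / (4.0 * np.pi)

    def _pair_sum(pts, nxt, ii, jj):
        return float(_pair_sum_jit(pts, nxt, ii, jj))

except ImportError:  # pragma: no cover
    _pair_sum = _pair_sum_numpy


def _changed_pairs(n: int, a: int, b: int) -> tuple[np.ndarray, np.ndarray]:
    """Unordered non-adjacent segment pairs affected by a crankshaft at (a, b).

    Beads strictly between pivots a and b (ring order) move rigidly, so
    edges a .. b-1 are affected; pairs internal to the rigid block (not
    touching the deforming boundary edges a and b-1) are unchanged.
    """
    block = np.arange(a, a + (b - a) % n) % n          # edges a .. b-1
    in_block = np.zeros(n, dtype=bool)
    in_block[block] = True
    other = np.nonzero(~in_block)[0]
    ii = np.repeat(block, len(other))
    jj = np.tile(other, len(block))
    # boundary edges also move relative to the rigid interior
    interior = block[1:-1]
    if len(interior):
        for edge in (block[0], block[-1]):
            ii = np.concatenate([ii, np.full(len(interior), edge)])
            jj = np.concatenate([jj, interior])
    if len(block) > 1:
        ii = np.concatenate([ii, block[:1]])
        jj = np.concatenate([jj, block[-1:]])
    adjacent = (ii == jj) | ((ii + 1) % n == jj) | ((jj + 1) % n == ii)
    keep = ~adjacent
    return ii[keep], jj[keep]


def mc_ensemble(params: MCParams, progress: bool = False) -> MCTrajectory:
    """Sample closed-chain conformations at fixed delta-Lk by Metropolis MC.

    The chain starts as a planar circle.  Each step proposes a crankshaft
    rotation of a random sub-chain about the chord between two pivot
    beads; closure is preserved by construction and the writhe change is
    evaluated incrementally over the affected segment pairs only.  Frames
    (axis contour + ribbon dressed at Lk = lk_reference + delta_lk) are
    emitted every ``save_stride`` steps.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_beads
    ell = params.bead_spacing
    L = n * ell
    kT_scale = params.temperature / 300.0
    bend_coeff = params.bend_persistence / (2.0 * ell) / kT_scale
    twist_coeff = 2.0 * np.pi**2 * params.twist_persistence / L / kT_scale

    radius = L / (2.0 * np.pi)
    phi = 2.0 * np.pi * np.arange(n) / n
    pts = radius * np.column_stack([np.cos(phi), np.sin(phi), np.zeros(n)])

    wr = writhe(Contour(pts))
    lk_int = int(np.rint(params.lk_reference + params.delta_lk))

    def total_bend(p):
        return _bend_energy_at(p, np.arange(n), bend_coeff)

    e_bend = total_bend(pts)

    def twist_energy(w):
        return twist_coeff * (params.delta_lk - w) ** 2

    contours: list[np.ndarray] = []
    ribbons: list[RibbonConformation] = []
    writhes: list[float] = []
    energies: list[float] = []
    accepted = 0
    max_arc = max(3, n // 2)

    for step in range(1, params.n_steps + 1):
        a = int(rng.integers(0, n))
        m = int(rng.integers(2, max_arc + 1))
        b = (a + m) % n
        angle = float(rng.uniform(-params.move_amplitude, params.move_amplitude))

        axis = pts[b] - pts[a]
        axis_norm = np.linalg.norm(axis)
        if axis_norm < 1e-9:
            continue
        axis = axis / axis_norm
        moved = np.arange(a + 1, a + m) % n

        ii, jj = _changed_pairs(n, a, b)
        old_pairs = _pair_sum(pts, np.roll(pts, -1, axis=0), ii, jj)
        touched = np.unique(np.concatenate([[a], moved, [b]]))
        old_bend = _bend_energy_at(pts, touched, bend_coeff)

        new_pts = pts.copy()
        rel = new_pts[moved] - pts[a]
        c, s = np.cos(angle), np.sin(angle)
        new_pts[moved] = (
            pts[a]
            + rel * c
            + np.cross(axis, rel) * s
            + np.outer(rel @ axis, axis) * (1.0 - c)
        )

        if params.excluded_diameter > 0:
            fixed = np.setdiff1d(np.arange(n), moved, assume_unique=True)
            d = cdist(new_pts[moved], new_pts[fixed])
            ring_sep = np.minimum(
                (moved[:, None] - fixed[None, :]) % n,
                (fixed[None, :] - moved[:, None]) % n,
            )
            d[ring_sep <= 1] = np.inf
            if d.min() < params.excluded_diameter:
                continue

        new_pairs = _pair_sum(new_pts, np.roll(new_pts, -1, axis=0), ii, jj)
        new_wr = wr + 2.0 * (new_pairs - old_pairs)
        new_bend = _bend_energy_at(new_pts, touched, bend_coeff)
        delta_e = (new_bend - old_bend) + (twist_energy(new_wr) - twist_energy(wr))

        if delta_e <= 0 or rng.random() < np.exp(-delta_e):
            pts = new_pts
            wr = new_wr
            e_bend += new_bend - old_bend
            accepted += 1

        if step % 2000 == 0:
            wr = writhe(Contour(pts))   # refresh against incremental drift
            e_bend = total_bend(pts)

        if step % params.save_stride == 0:
            wr = writhe(Contour(pts))
            contours.append(pts.copy())
            ribbons.append(ribbon_from_contour(pts, lk_int))
            writhes.append(wr)
            energies.append(e_bend + twist_energy(wr))

    return MCTrajectory(
        params=params,
        contours=contours,
        ribbons=ribbons,
        writhes=np.array(writhes),
        implied_twist=params.delta_lk - np.array(writhes),
        energies=np.array(energies),
        acceptance_fraction=accepted / params.n_steps,
    )


# ---------------------------------------------------------------------------
# parametric curves of known writhe
# ---------------------------------------------------------------------------

def parametric_curve(family: str, n: int = 400, **params) -> Contour:
    """Closed test curves with known or oracle-computed writhe.

    Families
    --------
    circle : planar circle (radius), Wr = 0 exactly.
    figure_eight : lemniscate with one crossing separated by ``eps``;
        Wr -> handed * 1 as eps -> 0 (handed=+1 gives a right-handed
        crossing).
    trefoil_like : compact trefoil, |Wr| about 3.4 for this parametrization.
    lissajous : circle modulated in x and z; with the default amplitude,
        asymmetry and phase its writhe is about -0.4246 (dense-quadrature
        value; see the test suite).
    """
    if n < 32:
        raise ValueError("need n >= 32 sample points")
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    if family == "circle":
        r = params.get("radius", 1.0)
        pts = np.column_stack([r * np.cos(t), r * np.sin(t), np.zeros(n)])
    elif family == "figure_eight":
        eps = params.get("eps", 0.005)
        handed = params.get("handed", 1)
        pts = np.column_stack(
            [np.sin(t), np.sin(t) * np.cos(t), handed * eps * np.cos(t)]
        )
    elif family == "trefoil_like":
        pts = np.column_stack(
            [
                np.sin(t) + 2.0 * np.sin(2.0 * t),
                np.cos(t) - 2.0 * np.cos(2.0 * t),
                -np.sin(3.0 * t),
            ]
        )
    elif family == "lissajous":
        amp = params.get("amplitude", 0.3)
        q = params.get("lobes", 3)
        phase = params.get("phase", 0.7)
        asym = params.get("asymmetry", 0.4)
        pts = np.column_stack(
            [
                np.cos(t) + asym * np.cos(2.0 * t),
                np.sin(t),
                amp * np.sin(q * t + phase),
            ]
        )
    else:
        raise ValueError(f"unknown curve family: {family!r}")
    return Contour(pts)


# ---------------------------------------------------------------------------
# bridged two-loop trajectories
# ---------------------------------------------------------------------------

def _solenoid_loop(
    n_pts: int,
    radius: float,
    wobble: float,
    lobes: int,
    lam: float,
) -> np.ndarray:
    """Closed loop through the origin whose writhe grows with chirality lam.

    A circle of the given radius decorated with ``lobes`` solenoidal
    wobbles; ``lam`` lifts the wobble out of plane with a definite
    handedness, producing writhe that increases smoothly with lam.
    """
    u = 2.0 * np.pi * np.arange(n_pts) / n_pts
    rho = radius + wobble * np.cos(lobes * u)
    x = rho * np.cos(u) - (radius + wobble)
    y = rho * np.sin(u)
    z = lam * wobble * np.sin(lobes * u)
    return np.column_stack([x, y, z])


@dataclass
class BridgedTrajectory:
    """Two-loop bridged minicircle frames plus generation ground truth."""

    contours: list[np.ndarray]
    bridge: tuple[int, int]
    loop_bp: tuple[int, int]
    mode: str
    truth_lambda1: np.ndarray
    truth_lambda2: np.ndarray
    planted_wr1: np.ndarray
    planted_wr2: np.ndarray


def _loop_writhe_map(loop_fn, lam_grid: np.ndarray) -> np.ndarray:
    return np.array([writhe(Contour(loop_fn(lam))) for lam in lam_grid])


def bridged_trajectory(
    n_bp: int = 336,
    bridge: tuple[int, int] = (0, 255),
    mode: str = "independent",
    n_frames: int = 200,
    seed: int = 0,
    rise: float = 3.4,
    lam_mean: tuple[float, float] = (0.8, 0.5),
    lam_sd: tuple[float, float] | None = None,
) -> BridgedTrajectory:
    """Trajectory of a minicircle pinched into two loops at a bridge.

    The default bridge at (0, 255) on a 336-bp circle yields loops of 255
    and 81 bp.  Each loop is a solenoidally decorated circle whose
    out-of-plane chirality parameter lambda sets its writhe.  In
    ``independent`` mode the two lambdas follow independent AR(1)
    processes; in ``compensating`` mode the small-loop writhe is chosen
    each frame so the planted total writhe stays fixed, emulating free
    exchange of writhe across the bridge.
    """
    if mode not in ("independent", "compensating"):
        raise ValueError("mode must be 'independent' or 'compensating'")
    i, j = int(bridge[0]) % n_bp, int(bridge[1]) % n_bp
    if i == j:
        raise ValueError("bridge contacts must be distinct")
    n1 = (j - i) % n_bp
    n2 = n_bp - n1
    rng = np.random.default_rng(seed)

    r1 = n1 * rise / (2.0 * np.pi)
    r2 = n2 * rise / (2.0 * np.pi)
    gap = 8.0  # A between the two bridge contact points

    def loop1(lam):
        return _solenoid_loop(n1, r1, 0.35 * r1, 3, lam)

    def loop2(lam):
        pts = _solenoid_loop(n2, r2, 0.35 * r2, 3, lam)
        pts = pts * np.array([-1.0, -1.0, 1.0])    # extend +x instead of -x
        return pts + np.array([0.0, 0.0, gap])

    lam_grid = np.linspace(-1.6, 1.6, 33)
    wmap1 = _loop_writhe_map(loop1, lam_grid)
    wmap2 = _loop_writhe_map(loop2, lam_grid)

    def lam_for_wr(wmap, target):
        # wmap is monotone decreasing in lam; flip for interpolation
        return float(np.interp(target, wmap[::-1], lam_grid[::-1]))

    # AR(1) around a writhed mean state
    rho, n_burn = 0.6, 20
    def ar1(mean, sd, size):
        x = np.empty(size + n_burn)
        x[0] = mean
        noise = rng.normal(0.0, sd * np.sqrt(1 - rho**2), size + n_burn)
        for k in range(1, size + n_burn):
            x[k] = mean + rho * (x[k - 1] - mean) + noise[k]
        return x[n_burn:]

    if lam_sd is None:
        lam_sd = (0.3, 0.3) if mode == "independent" else (0.15, 0.15)
    lam1 = np.clip(ar1(lam_mean[0], lam_sd[0], n_frames), lam_grid[0], lam_grid[-1])
    w1 = np.interp(lam1, lam_grid, wmap1)
    if mode == "independent":
        lam2 = np.clip(ar1(lam_mean[1], lam_sd[1], n_frames), lam_grid[0], lam_grid[-1])
        w2 = np.interp(lam2, lam_grid, wmap2)
    else:
        total = float(
            np.interp(lam_mean[0], lam_grid, wmap1)
            + np.interp(lam_mean[1], lam_grid, wmap2)
        )
        w2 = np.clip(total - w1, wmap2.min(), wmap2.max())
        lam2 = np.array([lam_for_wr(wmap2, w) for w in w2])

    contours = []
    for k in range(n_frames):
        p1 = loop1(float(lam1[k]))
        p2 = loop2(float(lam2[k]))
        ring = np.empty((n_bp, 3))
        ring[np.arange(i, i + n1) % n_bp] = p1
        ring[np.arange(j, j + n2) % n_bp] = p2
        contours.append(ring)
    return BridgedTrajectory(
        contours=contours,
        bridge=(i, j),
        loop_bp=(n1, n2),
        mode=mode,
        truth_lambda1=lam1,
        truth_lambda2=lam2,
        planted_wr1=w1,
        planted_wr2=w2,
    )


# ---------------------------------------------------------------------------
# planted protein-DNA hydrogen-bond states
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedComplexSpec:
    """Ground-truth binding-mode fixture: per-state binary contact patterns.

    ``fingerprints`` is an (n_states, n_residues) binary array; ``None``
    draws random patterns with pairwise Hamming distance >= 3.
    """

    n_states: int = 5
    n_residues: int = 12
    fingerprints: np.ndarray | None = None
    frames_per_state: int = 20
    geometric_jitter: float = 0.1    # A
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometric_jitter < 0:
            raise ValueError("jitter must be >= 0")
        if self.fingerprints is not None:
            fp = np.asarray(self.fingerprints)
            if len(np.unique(fp, axis=0)) != len(fp):
                raise ValueError("state fingerprints must be pairwise distinct")


@dataclass
class PlantedComplexTrajectory:
    """Frames, resolved selection and truth labels for clustering tests."""

    coords: np.ndarray               # (n_frames, n_atoms, 3)
    selection: AtomSelection
    truth_labels: np.ndarray
    truth_fingerprints: np.ndarray   # (n_states, n_residues) binary
    topoisomers: np.ndarray | None = None
    replicas: np.ndarray | None = None


def _random_patterns(rng, n_states: int, n_res: int) -> np.ndarray:
    """Distinct binary patterns with pairwise Hamming distance >= 3."""
    for _ in range(2000):
        fp = rng.integers(0, 2, size=(n_states, n_res))
        dist = cdist(fp, fp, metric="hamming") * n_res
        iu = np.triu_indices(n_states, 1)
        if np.all(dist[iu] >= 3) and np.all(fp.sum(axis=1) >= 1):
            return fp.astype(float)
    raise RuntimeError("could not draw distinct state patterns; too few residues?")


# geometry of a planted contact: bound donors sit a hydrogen bond away
# from their acceptor, unbound ones well outside the distance cutoff
_BOUND_OFFSET = 2.9    # A, donor heavy -> acceptor when bonded
_UNBOUND_OFFSET = 8.0  # A when not bonded
_RES_SPACING = 6.0     # A between successive acceptor sites


def planted_complex(spec: PlantedComplexSpec) -> PlantedComplexTrajectory:
    """Generate frames whose detected H-bond patterns equal the planted ones.

    Each protein residue contributes one donor (heavy atom + hydrogen);
    the DNA contributes one acceptor per residue site.  In a frame of
    state s, residue r's donor is placed a hydrogen bond away from its
    acceptor when pattern[s, r] = 1 and far outside the cutoff otherwise,
    then Gaussian jitter and a random rigid motion are applied.  Frames
    whose detected pattern deviates from the planted one are redrawn; a
    jitter too large to preserve the patterns raises after 20 retries.
    """
    rng = np.random.default_rng(spec.seed)
    fp = (
        np.asarray(spec.fingerprints, dtype=float)
        if spec.fingerprints is not None
        else _random_patterns(rng, spec.n_states, spec.n_residues)
    )
    n_states, n_res = fp.shape

    donor_atoms = np.arange(n_res)
    hydrogen_atoms = np.arange(n_res, 2 * n_res)
    acceptor_atoms = np.arange(2 * n_res, 3 * n_res)
    width = len(str(n_res))  # zero-pad so lexicographic residue order is numeric
    selection = AtomSelection(
        donor_atoms=donor_atoms,
        donor_hydrogens=hydrogen_atoms,
        donor_residues=np.array([f"R{r+1:0{width}d}" for r in range(n_res)]),
        donor_is_protein=np.ones(n_res, dtype=bool),
        acceptor_atoms=acceptor_atoms,
        acceptor_residues=np.array([f"DNA{r+1:0{width}d}" for r in range(n_res)]),
        acceptor_is_protein=np.zeros(n_res, dtype=bool),
        backbone_atoms=np.concatenate([donor_atoms, acceptor_atoms]),
    )

    def make_frame(state: int) -> np.ndarray:
        x = _RES_SPACING * np.arange(n_res)
        acc = np.column_stack([x, np.zeros(n_res), np.zeros(n_res)])
        z = np.where(fp[state] > 0, _BOUND_OFFSET, _UNBOUND_OFFSET)
        don = np.column_stack([x, np.zeros(n_res), z])
        hyd = np.column_stack([x, np.zeros(n_res), z - 1.0])
        frame = np.concatenate([don, hyd, acc])
        frame = frame + rng.normal(0.0, spec.geometric_jitter, frame.shape)
        # random rigid motion: clustering must superpose before comparing
        from scipy.spatial.transform import Rotation

        R = Rotation.random(random_state=rng).as_matrix()
        return frame @ R.T + rng.normal(0.0, 5.0, 3)

    def detected_pattern(frame: np.ndarray) -> np.ndarray:
        pat = np.zeros(n_res)
        for bond in detect_hbonds(frame, selection):
            r = int(str(bond.protein_residue)[1:]) - 1
            pat[r] = 1.0
        return pat

    frames, labels = [], []
    for s in range(n_states):
        for _ in range(spec.frames_per_state):
            for attempt in range(20):
                frame = make_frame(s)
                if np.array_equal(detected_pattern(frame), fp[s]):
                    break
            else:
                raise RuntimeError(
                    "jitter too large: planted H-bond pattern not realized"
                )
            frames.append(frame)
            labels.append(s)
    return PlantedComplexTrajectory(
        coords=np.stack(frames),
        selection=selection,
        truth_labels=np.array(labels),
        truth_fingerprints=fp,
    )
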