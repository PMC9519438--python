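"""Construction of planar closed-circular DNA topoisomers.

A DNA minicircle is modelled as a *ribbon*: a closed sequence of base-pair
frames, each carrying an axis origin, a unit tangent along the helical axis
and a unit reference vector (perpendicular to the tangent, pointing from the
axis toward the strand-I backbone).  A planar topoisomer with ``lk`` helical
turns places the axis origins on a circle and rotates the reference vector
uniformly so that it completes exactly ``lk`` full turns around the axis on
one traversal of the circle.  Planarity forces the writhe of the axis to
zero, so the imposed twist equals the linking number of the two backbone
strands: Lk = Tw + Wr = lk + 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BasePairFrame",
    "RibbonConformation",
    "MinicircleSpec",
    "build_planar_minicircle",
    "strand_curves",
]

#: default helical rise per base pair, Angstrom
DEFAULT_RISE = 3.4

#: tolerance for unit-vector / orthogonality invariants
_FRAME_TOL = 1e-9


@dataclass(frozen=True)
class BasePairFrame:
    """Geometry of one base pair: axis origin plus an orthonormal pair.

    ``tangent`` points along the helical axis, ``reference`` from the axis
    toward the strand-I backbone.
    """

    index: int
    origin: np.ndarray
    tangent: np.ndarray
    reference: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.tangent, dtype=float)
        r = np.asarray(self.reference, dtype=float)
        if abs(np.linalg.norm(t) - 1.0) > 1e-6:
            raise ValueError("tangent must be a unit vector")
        if abs(np.linalg.norm(r) - 1.0) > 1e-6:
            raise ValueError("reference must be a unit vector")
        if abs(float(t @ r)) > 1e-6:
            raise ValueError("reference must be perpendicular to tangent")


@dataclass
class RibbonConformation:
    """Closed DNA duplex as arrays of per-bp frames.

    Attributes
    ----------
    origins, tangents, references : (n_bp, 3) float arrays
        Axis origins (A), unit tangents and unit reference vectors.
    closed : bool
        Whether the successor of base pair ``n_bp - 1`` is base pair 0.
    sequence : str or None
        Optional nucleotide sequence; metadata only, never used by the
        geometry.
    """

    origins: np.ndarray
    tangents: np.ndarray
    references: np.ndarray
    closed: bool = True
    sequence: str | None = None

    def __post_init__(self) -> None:
        self.origins = np.ascontiguousarray(self.origins, dtype=float)
        self.tangents = np.ascontiguousarray(self.tangents, dtype=float)
        self.references = np.ascontiguousarray(self.references, dtype=float)
        n = len(self.origins)
        if self.tangents.shape != (n, 3) or self.references.shape != (n, 3):
            raise ValueError("origins, tangents and references must share shape (n_bp, 3)")
        if self.sequence is not None and len(self.sequence) != n:
            raise ValueError("sequence length must equal n_bp")

    @property
    def n_bp(self) -> int:
        return len(self.origins)

    @property
    def frames(self) -> list[BasePairFrame]:
        return [
            BasePairFrame(i, self.origins[i], self.tangents[i], self.references[i])
            for i in range(self.n_bp)
        ]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "RibbonConformation":
        """Rigidly transformed copy (topological quantities are invariant)."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return RibbonConformation(
            origins=self.origins @ R.T + t,
            tangents=self.tangents @ R.T,
            references=self.references @ R.T,
            closed=self.closed,
            sequence=self.sequence,
        )

    def validate_frames(self, tol: float = 1e-6) -> None:
        """Raise if any tangent/reference breaks unit-norm or orthogonality."""
        tn = np.linalg.norm(self.tangents, axis=1)
        rn = np.linalg.norm(self.references, axis=1)
        dot = np.einsum("ij,ij->i", self.tangents, self.references)
        if np.any(np.abs(tn - 1.0) > tol) or np.any(np.abs(rn - 1.0) > tol):
            raise ValueError("non-unit frame vectors")
        if np.any(np.abs(dot) > tol):
            raise ValueError("reference vectors not perpendicular to tangents")


@dataclass(frozen=True)
class MinicircleSpec:
    """Parameters of a planar topoisomer: size, imposed turns, rise."""

    n_bp: int
    lk: int
    rise: float = DEFAULT_RISE
    sequence: str | None = None

    def __post_init__(self) -> None:
        if not float(self.lk).is_integer():
            raise ValueError("lk must be an integer number of turns; open strands would not close")
        if self.n_bp < 30:
            raise ValueError("n_bp too small for the discretization (need >= 30)")
        if self.lk < 1:
            raise ValueError("lk must be >= 1")
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if self.sequence is not None and len(self.sequence) != self.n_bp:
            raise ValueError("sequence length must equal n_bp")


def build_planar_minicircle(spec: MinicircleSpec) -> RibbonConformation:
    """Build a perfectly planar closed minicircle with ``spec.lk`` turns.

    Axis origins lie on a circle of radius ``n_bp * rise / (2 pi)`` in the
    z = 0 plane.  The reference vector starts along the in-plane radial
    direction at bp 0 and accumulates a uniform per-step twist of
    ``lk * 360 / n_bp`` degrees, so global twist equals ``lk`` exactly and
    writhe is exactly zero.
    """
    n, lk = spec.n_bp, int(spec.lk)
    radius = n * spec.rise / (2.0 * np.pi)
    phi = 2.0 * np.pi * np.arange(n) / n
    radial = np.column_stack([np.cos(phi), np.sin(phi), np.zeros(n)])
    origins = radius * radial
    tangents = np.column_stack([-np.sin(phi), np.cos(phi), np.zeros(n)])
    # The in-plane radial frame {radial, z} is twist-free (relatively
    # parallel) along a planar circle, so rotating within it by theta_i
    # yields a ribbon of total twist exactly lk turns.
    theta = 2.0 * np.pi * lk * np.arange(n) / n
    z = np.array([0.0, 0.0, 1.0])
    # minus sign on z: a rotation from radial toward -z is a positive
    # (right-handed) rotation about the tangent for a counter-clockwise
    # circle, giving Tw = +lk and strand linking number +lk
    references = np.cos(theta)[:, None] * radial - np.sin(theta)[:, None] * z
    return RibbonConformation(
        origins=origins,
        tangents=tangents,
        references=references,
        closed=True,
        sequence=spec.sequence,
    )


def strand_curves(
    ribbon: RibbonConformation,
    strand_radius: float = 9.0,
    separation_angle: float = 180.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Backbone curves of the two strands as closed polylines.

    Strand I sits at ``origin + strand_radius * reference``; strand II is
    rotated about the local tangent by ``separation_angle`` degrees
    (default 180, a symmetric ribbon).  The Gauss linking integral of the
    pair equals the ribbon's linking number.
    """
    if not ribbon.closed:
        raise ValueError("strand curves require a closed ribbon")
    if strand_radius <= 0:
        raise ValueError("strand_radius must be positive (zero collapses both strands onto the axis)")
    ang = np.deg2rad(separation_angle)
    ref = ribbon.references
    tan = ribbon.tangents
    # rotate reference about tangent by the separation angle (Rodrigues)
    ref2 = (
        ref * np.cos(ang)
        + np.cross(tan, ref) * np.sin(ang)
        + tan * np.einsum("ij,ij->i", tan, ref)[:, None] * (1.0 - np.cos(ang))
    )
    strand1 = ribbon.origins + strand_radius * ref
    strand2 = ribbon.origins + strand_radius * ref2
    return strand1, strand2
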