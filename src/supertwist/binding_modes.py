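"""Protein-DNA binding-mode classification from hydrogen-bond fingerprints.

A hydrogen bond is called when the donor-heavy-atom to acceptor distance is
within 3.5 Angstrom and the donor-hydrogen-acceptor angle is at least 120
degrees.  Bonds are capped at one per protein residue per frame, so the
time average over a trajectory is the fraction of frames in which that
residue contacts DNA at all — the per-residue *occupancy fingerprint*.

Frames are clustered by pairwise backbone RMSD (after optimal rigid
superposition) with average-linkage (UPGMA) agglomeration; the per-cluster
mean fingerprints then characterize each binding mode, and state
populations are tabulated per topoisomer and replica.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist, squareform
from scipy.spatial.transform import Rotation

__all__ = [
    "AtomSelection",
    "HBond",
    "ContactFingerprint",
    "ClusterResult",
    "StateTable",
    "detect_hbonds",
    "contact_matrix",
    "fingerprint",
    "frame_rmsd_matrix",
    "cluster_frames",
    "state_populations",
    "DEFAULT_DISTANCE_CUTOFF",
    "DEFAULT_ANGLE_CUTOFF",
]

DEFAULT_DISTANCE_CUTOFF = 3.5   # donor heavy atom -> acceptor, Angstrom
DEFAULT_ANGLE_CUTOFF = 120.0    # donor-hydrogen-acceptor, degrees


@dataclass
class AtomSelection:
    """Resolved donor/hydrogen/acceptor roles for H-bond detection.

    ``donor_atoms[k]`` is the heavy-atom index of donor k and
    ``donor_hydrogens[k]`` its attached hydrogen (-1 when hydrogens are
    absent from the model).  ``donor_is_protein`` / ``acceptor_is_protein``
    mark which molecule each atom belongs to; only protein<->DNA bonds are
    reported.  ``donor_residues`` / ``acceptor_residues`` are residue labels
    used for the per-residue occupancy cap.
    """

    donor_atoms: np.ndarray
    donor_hydrogens: np.ndarray
    donor_residues: np.ndarray
    donor_is_protein: np.ndarray
    acceptor_atoms: np.ndarray
    acceptor_residues: np.ndarray
    acceptor_is_protein: np.ndarray
    backbone_atoms: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.donor_atoms = np.asarray(self.donor_atoms, dtype=int)
        self.donor_hydrogens = np.asarray(self.donor_hydrogens, dtype=int)
        self.acceptor_atoms = np.asarray(self.acceptor_atoms, dtype=int)
        self.donor_is_protein = np.asarray(self.donor_is_protein, dtype=bool)
        self.acceptor_is_protein = np.asarray(self.acceptor_is_protein, dtype=bool)
        if len(self.donor_hydrogens) != len(self.donor_atoms):
            raise ValueError("donor_hydrogens must align with donor_atoms")

    @property
    def protein_residues(self) -> np.ndarray:
        """Sorted unique protein residue labels appearing in the selection."""
        res = np.concatenate(
            [
                np.asarray(self.donor_residues)[self.donor_is_protein],
                np.asarray(self.acceptor_residues)[self.acceptor_is_protein],
            ]
        )
        return np.unique(res)

    @property
    def has_hydrogens(self) -> bool:
        return bool(np.all(self.donor_hydrogens >= 0))


@dataclass(frozen=True)
class HBond:
    """One detected protein-DNA hydrogen bond."""

    donor_atom: int
    acceptor_atom: int
    protein_residue: object
    distance: float
    angle: float | None   # None when detection fell back to distance-only


@dataclass
class ContactFingerprint:
    """Per-protein-residue H-bond occupancy over a trajectory, in [0, 1]."""

    occupancy: np.ndarray
    residues: np.ndarray
    n_frames: int

    def as_series(self) -> pd.Series:
        return pd.Series(self.occupancy, index=list(self.residues), name="occupancy")


@dataclass
class ClusterResult:
    """Average-linkage clustering of trajectory frames."""

    labels: np.ndarray
    linkage: np.ndarray
    n_clusters: int
    mean_fingerprints: np.ndarray | None = None   # (n_clusters, n_residues)


@dataclass
class StateTable:
    """State populations per topoisomer, mirroring a per-state percentage table."""

    pooled: pd.DataFrame            # index topoisomer, columns state, % of frames
    per_replica_majority: pd.DataFrame
    replica_weighted: pd.DataFrame  # each replica contributes equally


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def detect_hbonds(
    coords: np.ndarray,
    selection: AtomSelection,
    d_cut: float = DEFAULT_DISTANCE_CUTOFF,
    angle_cut: float = DEFAULT_ANGLE_CUTOFF,
) -> list[HBond]:
    """Protein-DNA hydrogen bonds in one frame.

    A bond requires donor-heavy to acceptor distance <= ``d_cut`` and, when
    hydrogens are present, a donor-hydrogen-acceptor angle >= ``angle_cut``.
    Without hydrogens the angle criterion is skipped and each bond carries
    ``angle=None`` (a single warning is emitted).
    """
    xyz = np.asarray(coords, dtype=float)
    don = xyz[selection.donor_atoms]
    acc = xyz[selection.acceptor_atoms]
    dists = cdist(don, acc)
    # protein<->DNA only
    cross = selection.donor_is_protein[:, None] != selection.acceptor_is_protein[None, :]
    candidate = (dists <= d_cut) & cross
    use_angles = selection.has_hydrogens
    if not use_angles:
        warnings.warn(
            "selection has no hydrogens: falling back to distance-only detection",
            stacklevel=2,
        )
    bonds: list[HBond] = []
    for di, ai in zip(*np.nonzero(candidate)):
        angle = None
        if use_angles:
            h = xyz[selection.donor_hydrogens[di]]
            v1 = xyz[selection.donor_atoms[di]] - h
            v2 = xyz[selection.acceptor_atoms[ai]] - h
            cosang = float(v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle < angle_cut:
                continue
        res = (
            selection.donor_residues[di]
            if selection.donor_is_protein[di]
            else selection.acceptor_residues[ai]
        )
        bonds.append(
            HBond(
                donor_atom=int(selection.donor_atoms[di]),
                acceptor_atom=int(selection.acceptor_atoms[ai]),
                protein_residue=res,
                distance=float(dists[di, ai]),
                angle=angle,
            )
        )
    return bonds


def contact_matrix(
    trajectory: np.ndarray,
    selection: AtomSelection,
    d_cut: float = DEFAULT_DISTANCE_CUTOFF,
    angle_cut: float = DEFAULT_ANGLE_CUTOFF,
) -> tuple[np.ndarray, np.ndarray]:
    """(n_frames, n_protein_residues) binary contact indicators.

    Entry (f, r) is 1 when protein residue r makes at least one H-bond to
    DNA in frame f — the per-residue cap at one bond per frame.
    """
    residues = selection.protein_residues
    res_index = {r: k for k, r in enumerate(residues)}
    frames = np.asarray(trajectory, dtype=float)
    if frames.ndim != 3:
        raise ValueError("trajectory must have shape (n_frames, n_atoms, 3)")
    out = np.zeros((len(frames), len(residues)), dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("once")
        for f, xyz in enumerate(frames):
            for bond in detect_hbonds(xyz, selection, d_cut, angle_cut):
                out[f, res_index[bond.protein_residue]] = 1.0
    return out, residues


def fingerprint(
    trajectory: np.ndarray,
    selection: AtomSelection,
    d_cut: float = DEFAULT_DISTANCE_CUTOFF,
    angle_cut: float = DEFAULT_ANGLE_CUTOFF,
) -> ContactFingerprint:
    """Trajectory-averaged occupancy fingerprint (capped at one bond/residue/frame)."""
    if len(selection.protein_residues) == 0:
        raise ValueError("selection contains no protein residues")
    contacts, residues = contact_matrix(trajectory, selection, d_cut, angle_cut)
    if len(contacts) == 0:
        raise ValueError("empty trajectory")
    return ContactFingerprint(
        occupancy=contacts.mean(axis=0), residues=residues, n_frames=len(contacts)
    )


# ---------------------------------------------------------------------------
# RMSD and clustering
# ---------------------------------------------------------------------------

def _superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between two coordinate sets after optimal superposition."""
    ca = a - a.mean(axis=0)
    cb = b - b.mean(axis=0)
    _, rssd = Rotation.align_vectors(ca, cb)
    return float(rssd / np.sqrt(len(a)))


def frame_rmsd_matrix(
    trajectory: np.ndarray, atom_indices: np.ndarray | None = None
) -> np.ndarray:
    """Pairwise minimum backbone RMSD between frames, Angstrom.

    Each pair is optimally superposed (Kabsch) on the selected atoms before
    the RMSD is taken; the matrix is symmetric with zero diagonal.
    """
    frames = np.asarray(trajectory, dtype=float)
    if frames.ndim != 3:
        raise ValueError("trajectory must have shape (n_frames, n_atoms, 3)")
    if atom_indices is not None:
        frames = frames[:, np.asarray(atom_indices, dtype=int), :]
    nf = len(frames)
    centered = frames - frames.mean(axis=1, keepdims=True)
    mat = np.zeros((nf, nf))
    for i in range(nf):
        for j in range(i + 1, nf):
            _, rssd = Rotation.align_vectors(centered[i], centered[j])
            mat[i, j] = mat[j, i] = rssd / np.sqrt(frames.shape[1])
    return mat


def cluster_frames(
    distance_matrix: np.ndarray,
    n_clusters: int | str = "auto",
    frame_contacts: np.ndarray | None = None,
    k_max: int = 10,
    distinctness: float = 0.5,
) -> ClusterResult:
    """Average-linkage (UPGMA) clustering of frames on an RMSD matrix.

    With ``n_clusters='auto'`` the number of states is chosen so that each
    has a distinct interaction pattern: the largest k <= ``k_max`` whose
    per-cluster mean contact fingerprints are pairwise L1-separated by at
    least ``distinctness`` (requires ``frame_contacts``).
    """
    D = np.asarray(distance_matrix, dtype=float)
    nf = len(D)
    if D.shape != (nf, nf):
        raise ValueError("distance matrix must be square")
    if nf == 1:
        return ClusterResult(
            labels=np.zeros(1, dtype=int),
            linkage=np.empty((0, 4)),
            n_clusters=1,
            mean_fingerprints=(
                frame_contacts.copy() if frame_contacts is not None else None
            ),
        )
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")

    def _cut(k: int) -> np.ndarray:
        return hierarchy.fcluster(Z, t=k, criterion="maxclust") - 1

    def _means(labels: np.ndarray, k: int) -> np.ndarray | None:
        if frame_contacts is None:
            return None
        return np.stack(
            [frame_contacts[labels == c].mean(axis=0) for c in range(k)]
        )

    if n_clusters == "auto":
        if frame_contacts is None:
            raise ValueError("auto cluster count needs per-frame contact indicators")
        chosen, chosen_labels = 1, _cut(1)
        for k in range(min(k_max, nf), 0, -1):
            labels = _cut(k)
            if len(np.unique(labels)) != k:
                continue
            means = _means(labels, k)
            dists = cdist(means, means, metric="cityblock")
            iu = np.triu_indices(k, 1)
            if k == 1 or np.all(dists[iu] >= distinctness):
                chosen, chosen_labels = k, labels
                break
        labels, k = chosen_labels, chosen
    else:
        k = int(n_clusters)
        if k > nf:
            raise ValueError("n_clusters exceeds number of frames")
        labels = _cut(k)
        k = len(np.unique(labels))
    return ClusterResult(
        labels=labels, linkage=Z, n_clusters=k, mean_fingerprints=_means(labels, k)
    )


# ---------------------------------------------------------------------------
# state populations
# ---------------------------------------------------------------------------

def state_populations(
    labels: np.ndarray,
    topoisomers: np.ndarray,
    replicas: np.ndarray,
) -> StateTable:
    """Percentage of frames in each state per topoisomer.

    ``pooled`` weights every frame equally within a topoisomer;
    ``replica_weighted`` gives each replica equal weight regardless of its
    length (both tabulations are reported because printed tables are often
    ambiguous about the convention).  Percentages are rounded to integers.
    """
    df = pd.DataFrame(
        {"state": np.asarray(labels), "topo": np.asarray(topoisomers), "rep": np.asarray(replicas)}
    )
    if df.empty:
        raise ValueError("no frames")
    states = np.unique(df["state"])

    pooled = (
        df.groupby("topo")["state"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=states, fill_value=0.0)
        * 100.0
    ).round(0)

    per_rep = (
        df.groupby(["topo", "rep"])["state"]
        .agg(lambda s: s.value_counts().idxmax())
        .unstack()
    )

    rep_frac = (
        df.groupby(["topo", "rep"])["state"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .groupby("topo")
        .mean()
        .reindex(columns=states, fill_value=0.0)
        * 100.0
    ).round(0)

    return StateTable(pooled=pooled, per_replica_majority=per_rep, replica_weighted=rep_frac)
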