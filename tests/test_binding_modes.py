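"""Hydrogen bonds, occupancy fingerprints, RMSD clustering, state tables."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from supertwist.binding_modes import (
    AtomSelection,
    cluster_frames,
    contact_matrix,
    detect_hbonds,
    fingerprint,
    frame_rmsd_matrix,
    state_populations,
)


def _single_donor_selection() -> AtomSelection:
    """One protein donor (atoms 0=heavy, 1=H) and one DNA acceptor (atom 2)."""
    return AtomSelection(
        donor_atoms=[0],
        donor_hydrogens=[1],
        donor_residues=np.array(["ARG1"]),
        donor_is_protein=[True],
        acceptor_atoms=[2],
        acceptor_residues=np.array(["DA5"]),
        acceptor_is_protein=[False],
    )


def _geometry(distance: float, angle_deg: float) -> np.ndarray:
    """Donor at origin, H at 1 A toward acceptor direction, acceptor placed
    so that D-A = distance and the D-H-A angle equals angle_deg."""
    donor = np.zeros(3)
    h = np.array([1.0, 0.0, 0.0])
    # place acceptor in the xy-plane at the requested angle about the hydrogen
    theta = np.radians(180.0 - angle_deg)   # D-H-A angle
    d_ha_dir = np.array([np.cos(theta), np.sin(theta), 0.0])
    # solve for |HA| so that |DA| = distance
    from scipy.optimize import brentq

    def f(r):
        acc = h + r * d_ha_dir
        return np.linalg.norm(acc - donor) - distance

    r = brentq(f, 1e-6, distance + 2.0)
    return np.stack([donor, h, h + r * d_ha_dir])


class TestDetectHbonds:
    @pytest.mark.parametrize(
        "distance,angle,expected",
        [
            (2.9, 170.0, True),    # well inside both cutoffs
            (3.6, 170.0, False),   # distance fails at 3.5 A
            (3.2, 110.0, False),   # angle fails at 120 deg
            (3.49, 121.0, True),   # just inside both
        ],
    )
    def test_distance_and_angle_cutoffs(self, distance, angle, expected):
        sel = _single_donor_selection()
        coords = _geometry(distance, angle)
        bonds = detect_hbonds(coords, sel)
        assert (len(bonds) == 1) is expected
        if expected:
            assert bonds[0].distance == pytest.approx(distance, abs=1e-9)
            assert bonds[0].angle == pytest.approx(angle, abs=1e-6)

    def test_protein_protein_pairs_ignored(self):
        sel = AtomSelection(
            donor_atoms=[0],
            donor_hydrogens=[1],
            donor_residues=np.array(["ARG1"]),
            donor_is_protein=[True],
            acceptor_atoms=[2],
            acceptor_residues=np.array(["GLU2"]),
            acceptor_is_protein=[True],     # same molecule: not protein-DNA
        )
        assert detect_hbonds(_geometry(2.9, 170.0), sel) == []

    def test_missing_hydrogens_fall_back_to_distance_only(self):
        sel = AtomSelection(
            donor_atoms=[0],
            donor_hydrogens=[-1],
            donor_residues=np.array(["ARG1"]),
            donor_is_protein=[True],
            acceptor_atoms=[2],
            acceptor_residues=np.array(["DA5"]),
            acceptor_is_protein=[False],
        )
        coords = _geometry(3.2, 110.0)      # would fail the angle criterion
        with pytest.warns(UserWarning, match="distance-only"):
            bonds = detect_hbonds(coords, sel)
        assert len(bonds) == 1 and bonds[0].angle is None


class TestFingerprint:
    def test_multiple_bonds_capped_at_one_per_residue(self):
        # one donor within range of three acceptors in every frame
        sel = AtomSelection(
            donor_atoms=[0],
            donor_hydrogens=[1],
            donor_residues=np.array(["LYS20"]),
            donor_is_protein=[True],
            acceptor_atoms=[2, 3, 4],
            acceptor_residues=np.array(["DA1", "DA2", "DA3"]),
            acceptor_is_protein=[False, False, False],
        )
        frame = np.array(
            [
                [0.0, 0.0, 0.0],
                [1.0, 0.0, 0.0],
                [2.9, 0.0, 0.0],
                [2.8, 0.5, 0.0],
                [2.8, -0.5, 0.0],
            ]
        )
        fp = fingerprint(np.stack([frame] * 4), sel)
        assert fp.occupancy.tolist() == [1.0]

    def test_partial_occupancy_is_frame_fraction(self):
        sel = _single_donor_selection()
        bound = _geometry(2.9, 170.0)
        unbound = bound.copy()
        unbound[2] += np.array([10.0, 0.0, 0.0])
        traj = np.stack([bound] * 5 + [unbound] * 5)
        fp = fingerprint(traj, sel)
        assert fp.occupancy.tolist() == [0.5]
        assert fp.n_frames == 10

    def test_never_bonded_residue_scores_zero(self):
        sel = _single_donor_selection()
        unbound = _geometry(2.9, 170.0)
        unbound[2] += 20.0
        assert fingerprint(np.stack([unbound] * 3), sel).occupancy.tolist() == [0.0]

    def test_adding_bond_free_frames_only_decreases_occupancy(self):
        sel = _single_donor_selection()
        bound = _geometry(2.9, 170.0)
        unbound = bound.copy()
        unbound[2] += 10.0
        occ5 = fingerprint(np.stack([bound] * 5), sel).occupancy[0]
        occ8 = fingerprint(np.stack([bound] * 5 + [unbound] * 3), sel).occupancy[0]
        assert occ8 <= occ5

    def test_empty_selection_rejected(self):
        sel = AtomSelection(
            donor_atoms=[],
            donor_hydrogens=[],
            donor_residues=np.array([]),
            donor_is_protein=[],
            acceptor_atoms=[],
            acceptor_residues=np.array([]),
            acceptor_is_protein=[],
        )
        with pytest.raises(ValueError, match="no protein residues"):
            fingerprint(np.zeros((2, 1, 3)), sel)


class TestRmsdMatrix:
    def test_identical_frames_give_zero(self):
        rng = np.random.default_rng(0)
        frame = rng.normal(size=(30, 3))
        D = frame_rmsd_matrix(np.stack([frame, frame]))
        assert D[0, 1] == pytest.approx(0.0, abs=1e-6)

    def test_rigid_transform_gives_zero_after_superposition(self):
        rng = np.random.default_rng(1)
        frame = rng.normal(size=(30, 3))
        R = Rotation.from_euler("xyz", [0.4, -0.9, 1.3]).as_matrix()
        moved = frame @ R.T + np.array([5.0, 1.0, -2.0])
        D = frame_rmsd_matrix(np.stack([frame, moved]))
        assert D[0, 1] == pytest.approx(0.0, abs=1e-6)

    def test_single_displaced_atom_matches_hand_formula(self):
        # superposition cannot fully remove a single-atom displacement, so
        # compare against the unsuperposed bound d/sqrt(k) and check the
        # superposed value is no larger
        rng = np.random.default_rng(2)
        k, d = 40, 2.0
        frame = rng.normal(size=(k, 3)) * 20.0
        moved = frame.copy()
        moved[7] += np.array([0.0, 0.0, d])
        D = frame_rmsd_matrix(np.stack([frame, moved]))
        assert D[0, 1] <= d / np.sqrt(k) + 1e-9
        assert D[0, 1] == pytest.approx(d / np.sqrt(k), rel=0.05)

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(3)
        traj = rng.normal(size=(6, 20, 3))
        D = frame_rmsd_matrix(traj)
        np.testing.assert_allclose(D, D.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(D), 0.0, atol=1e-12)

    def test_atom_subset_selection(self):
        rng = np.random.default_rng(4)
        traj = rng.normal(size=(3, 50, 3))
        D_sub = frame_rmsd_matrix(traj, atom_indices=np.arange(10))
        assert D_sub.shape == (3, 3)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            frame_rmsd_matrix(np.zeros((4, 3)))


class TestClustering:
    def test_two_tight_groups_recovered_exactly(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(10, 20, 3)) * 0.1
        b = rng.normal(size=(10, 20, 3)) * 0.1 + np.array([10.0, 0.0, 0.0]) * np.array(
            [1.0] * 1
        )
        # displace half the atoms so superposition cannot absorb the shift
        b[:, :10, :] += 8.0
        traj = np.concatenate([a, b])
        D = frame_rmsd_matrix(traj)
        res = cluster_frames(D, n_clusters=2)
        labels = res.labels
        assert len(np.unique(labels[:10])) == 1
        assert len(np.unique(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_merge_heights_are_monotone(self):
        rng = np.random.default_rng(6)
        traj = rng.normal(size=(15, 12, 3))
        res = cluster_frames(frame_rmsd_matrix(traj), n_clusters=3)
        heights = res.linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_single_frame_is_one_cluster(self):
        res = cluster_frames(np.zeros((1, 1)), n_clusters=1)
        assert res.n_clusters == 1 and res.labels.tolist() == [0]
        assert res.linkage.shape[0] == 0

    def test_too_many_clusters_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            cluster_frames(np.zeros((3, 3)), n_clusters=5)

    def test_auto_mode_requires_contacts(self):
        with pytest.raises(ValueError, match="contact"):
            cluster_frames(np.zeros((4, 4)), n_clusters="auto")

    def test_auto_mode_recovers_planted_state_count(self, planted_five_state):
        pc = planted_five_state
        contacts, _ = contact_matrix(pc.coords, pc.selection)
        D = frame_rmsd_matrix(pc.coords, pc.selection.backbone_atoms)
        res = cluster_frames(D, n_clusters="auto", frame_contacts=contacts)
        assert res.n_clusters == 5
        assert res.mean_fingerprints.shape == (5, 12)


class TestStatePopulations:
    def test_three_equal_replicas_in_distinct_states(self):
        labels = np.repeat([0, 1, 2], 50)
        topo = np.full(150, -2)
        reps = np.repeat([1, 2, 3], 50)
        table = state_populations(labels, topo, reps)
        assert table.pooled.loc[-2].tolist() == [33.0, 33.0, 33.0]
        assert table.per_replica_majority.loc[-2].tolist() == [0, 1, 2]

    def test_all_replicas_one_state(self):
        labels = np.zeros(150, dtype=int)
        table = state_populations(labels, np.full(150, 1), np.repeat([1, 2, 3], 50))
        assert table.pooled.loc[1, 0] == 100.0

    def test_single_replica_split(self):
        labels = np.array([0] * 70 + [1] * 30)
        table = state_populations(labels, np.zeros(100), np.ones(100))
        assert table.pooled.loc[0].tolist() == [70.0, 30.0]

    def test_replica_weighted_differs_from_pooled_for_unequal_lengths(self):
        # replica 1: 90 frames state 0; replica 2: 10 frames state 1
        labels = np.array([0] * 90 + [1] * 10)
        reps = np.array([1] * 90 + [2] * 10)
        table = state_populations(labels, np.zeros(100), reps)
        assert table.pooled.loc[0].tolist() == [90.0, 10.0]
        assert table.replica_weighted.loc[0].tolist() == [50.0, 50.0]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            state_populations(np.array([]), np.array([]), np.array([]))
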