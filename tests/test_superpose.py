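"""Kabsch superposition and RMSD primitives, checked against an independent
quaternion (Horn) superposition oracle."""

import numpy as np
import pytest

from glycotraj.superpose import (
    RigidTransform,
    fit_frames,
    kabsch_fit,
    make_whole,
    reimage_group,
    rmsd,
)
from glycotraj.system_model import Trajectory, protein_heavy_selection
from tests.conftest import static_trajectory


def horn_quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Independent oracle: optimal superposition RMSD via Horn's quaternion
    method (largest eigenvalue of the 4x4 key matrix)."""
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)
    S = x.T @ y
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    N = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(N)[-1]
    sq = (x**2).sum() + (y**2).sum() - 2.0 * lam
    return float(np.sqrt(max(sq, 0.0) / len(mobile)))


def rotation_z(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    return np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])


class TestKabschFit:
    def test_identity_case(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 3))
        t = kabsch_fit(pts, pts)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t.translation, 0.0, atol=1e-12)
        assert rmsd(t.apply(pts), pts) < 1e-12

    def test_exact_rigid_motion_recovered(self):
        rng = np.random.default_rng(1)
        reference = rng.normal(size=(12, 3))
        mobile = (reference - [1, 2, 3]) @ rotation_z(90).T
        t = kabsch_fit(mobile, reference)
        np.testing.assert_allclose(t.apply(mobile), reference, atol=1e-10)

    def test_matches_quaternion_oracle_on_noisy_points(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            reference = rng.normal(size=(20, 3))
            mobile = reference @ rotation_z(rng.uniform(0, 360)).T + rng.normal(
                0, 0.05, size=(20, 3)
            )
            t = kabsch_fit(mobile, reference)
            ours = rmsd(t.apply(mobile), reference)
            oracle = horn_quaternion_rmsd(mobile, reference)
            assert abs(ours - oracle) < 1e-10

    def test_reflection_branch_gives_proper_rotation(self):
        rng = np.random.default_rng(3)
        reference = rng.normal(size=(8, 3))
        mirrored = reference * [1, 1, -1]
        t = kabsch_fit(mirrored, reference)
        assert np.isclose(np.linalg.det(t.rotation), 1.0, atol=1e-10)

    def test_degenerate_inputs_rejected(self):
        line = np.stack([[i, 0.0, 0.0] for i in range(5)])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_fit(line + 1.0, line)
        with pytest.raises(ValueError, match="3 points"):
            kabsch_fit(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_transform_inverse_round_trip(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(6, 3))
        t = RigidTransform(rotation_z(37.0), np.array([0.3, -0.2, 1.1]))
        np.testing.assert_allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-10)


class TestRMSD:
    def test_identical_sets_zero(self):
        pts = np.random.default_rng(5).normal(size=(7, 3))
        assert rmsd(pts, pts) == 0.0

    def test_single_displacement_definition(self):
        a = np.zeros((1, 3))
        b = np.array([[0.7, 0.0, 0.0]])
        assert np.isclose(rmsd(a, b), 0.7)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(7, 3))
        b = rng.normal(size=(7, 3))
        brute = np.sqrt(sum(np.sum((ai - bi) ** 2) for ai, bi in zip(a, b)) / 7.0)
        assert abs(rmsd(a, b) - brute) < 1e-12

    def test_rigid_invariance_and_symmetry(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(9, 3))
        b = rng.normal(size=(9, 3))
        t = RigidTransform(rotation_z(63.0), np.array([1.0, -2.0, 0.5]))
        assert abs(rmsd(t.apply(a), t.apply(b)) - rmsd(a, b)) < 1e-10
        assert rmsd(a, b) == rmsd(b, a)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


class TestFitFrames:
    def test_rigidly_rotated_protein_refit_exactly(self, toy_system):
        traj = static_trajectory(toy_system, toy_system.bound_ligand, n_frames=4)
        rng = np.random.default_rng(8)
        coords = traj.coords.copy()
        for f in range(traj.n_frames):
            R = rotation_z(rng.uniform(0, 360))
            coords[f] = coords[f] @ R.T + rng.uniform(-1, 1, size=3)
        moved = Trajectory(coords, traj.times, traj.box, traj.atom_ids)
        sel = protein_heavy_selection(moved.atom_ids)
        fitted = fit_frames(moved, sel, toy_system.reference)
        for f in range(fitted.n_frames):
            assert (
                rmsd(fitted.coords[f, sel.indices], toy_system.reference.protein_coords)
                < 1e-9
            )
            # ligand co-moving rigidly with the protein stays constant
            np.testing.assert_allclose(
                fitted.coords[f, toy_system.ligand_atom_indices],
                toy_system.bound_ligand,
                atol=1e-9,
            )

    def test_equals_frame_by_frame_kabsch_oracle(self, short_trajectory, toy_system):
        trajectory, _ = short_trajectory
        sel = protein_heavy_selection(trajectory.atom_ids)
        fitted = fit_frames(trajectory, sel, toy_system.reference)
        for f in (0, 10, 99):
            t = kabsch_fit(
                trajectory.coords[f, sel.indices], toy_system.reference.protein_coords
            )
            np.testing.assert_allclose(
                fitted.coords[f], t.apply(trajectory.coords[f]), atol=1e-12
            )

    def test_reimaging_undoes_integer_box_shifts(self, toy_system):
        traj = static_trajectory(toy_system, toy_system.bound_ligand, n_frames=1)
        lig = toy_system.ligand_atom_indices
        shifted = traj.coords.copy()
        shifted[0, lig] += np.array([1, -2, 1]) * toy_system.box_edge
        moved = Trajectory(shifted, traj.times, traj.box, traj.atom_ids)
        sel = protein_heavy_selection(moved.atom_ids)
        fitted = fit_frames(moved, sel, toy_system.reference, reimage_indices=lig)
        np.testing.assert_allclose(fitted.coords[0, lig], toy_system.bound_ligand, atol=1e-9)


class TestPeriodicHelpers:
    def test_make_whole_rejoins_split_molecule(self):
        box = np.array([4.0, 4.0, 4.0])
        coords = np.array([[3.9, 1.0, 1.0], [0.1, 1.0, 1.0]])  # split across x
        whole = make_whole(coords, box)
        assert abs(whole[1, 0] - whole[0, 0] - 0.2) < 1e-12

    def test_reimage_group_moves_to_nearest_image(self):
        box = np.array([4.0, 4.0, 4.0])
        frame = np.array([[2.0, 2.0, 2.0], [9.5, 2.0, 2.0]])
        out = reimage_group(frame, box, np.array([1]), anchor=frame[0])
        np.testing.assert_allclose(out[1], [1.5, 2.0, 2.0], atol=1e-12)
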