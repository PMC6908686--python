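"""Rigid-body least-squares superposition (Kabsch) and RMSD primitives.

The fit is unweighted and SVD-based with an explicit determinant correction so
the returned rotation is always proper (no reflections), matching the standard
protocol of fitting trajectory frames onto the non-hydrogen atoms of a
reference protein structure before measuring ligand RMSD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .system_model import AtomSelection, ReferenceComplex, Trajectory

_SINGULAR_TOL = 1e-12


@dataclass(frozen=True)
class RigidTransform:
    """x -> rotation @ x + translation (nm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3, translation 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping mobile onto reference.

    Minimises sum_i |R x_i + t - y_i|^2 over proper rotations R.  Degenerate
    (fewer than 3 points, or collinear reference) inputs are rejected because
    the rotation is then underdetermined.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (N, 3)")
    if mobile.shape[0] < 3:
        raise ValueError("at least 3 points required for a rigid fit")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    ref_centered = reference - cr
    sv_ref = np.linalg.svd(ref_centered, compute_uv=False)
    if sv_ref[1] <= _SINGULAR_TOL * max(sv_ref[0], 1.0):
        raise ValueError("reference points are collinear; rotation underdetermined")
    H = (mobile - cm).T @ ref_centered
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if d != 0 else 1.0])
    R = Vt.T @ D @ U.T
    return RigidTransform(rotation=R, translation=cr - R @ cm)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between two point sets in a common frame.

    No fitting happens here; superpose first if a fit is wanted.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.shape[0] < 1:
        raise ValueError("need at least one atom")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_frames(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Vectorised per-frame RMSD of (F, N, 3) coords against one (N, 3) set."""
    diff = np.asarray(coords) - np.asarray(reference)[None]
    return np.sqrt(np.mean(np.sum(diff**2, axis=2), axis=1))


def make_whole(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Unwrap a molecule across periodic boundaries.

    Each atom is shifted to the periodic image nearest the first atom, so a
    molecule written wrapped into the primary box becomes contiguous.
    Orthorhombic boxes only.
    """
    coords = np.array(coords, dtype=float)
    delta = coords - coords[0]
    coords -= np.round(delta / box) * box
    return coords


def reimage_group(coords_frame: np.ndarray, box: np.ndarray, group: np.ndarray,
                  anchor: np.ndarray) -> np.ndarray:
    """Shift a whole atom group to the periodic image nearest an anchor point.

    The group is first made whole, then rigidly translated by integer box
    multiples so its centroid lands in the image closest to the anchor
    (typically the protein centroid).  Returns a modified copy of the frame.
    """
    out = np.array(coords_frame, dtype=float)
    whole = make_whole(out[group], box)
    centroid = whole.mean(axis=0)
    shift = -np.round((centroid - anchor) / box) * box
    out[group] = whole + shift
    return out


def fit_frames(
    trajectory: Trajectory,
    fit_selection: AtomSelection,
    reference: ReferenceComplex,
    reimage_indices: np.ndarray | None = None,
) -> Trajectory:
    """Superpose every frame onto the reference protein coordinates.

    Each frame's ``fit_selection`` atoms (which must map one-to-one, in order,
    onto ``reference.protein_coords``) define a Kabsch fit; the resulting
    transform is applied to all atoms of the frame, carrying the ligand along.

    When ``reimage_indices`` is given (normally the ligand atoms), that group
    is first re-imaged to the periodic image nearest the protein centroid,
    frame by frame, so box crossings do not fabricate huge RMSD values.
    """
    if len(fit_selection) != len(reference.protein_coords):
        raise ValueError(
            f"fit selection has {len(fit_selection)} atoms but reference "
            f"has {len(reference.protein_coords)}; one-to-one mapping required"
        )
    fitted = np.empty_like(trajectory.coords)
    idx = fit_selection.indices
    for f in range(trajectory.n_frames):
        frame = trajectory.coords[f]
        if reimage_indices is not None and len(reimage_indices):
            anchor = frame[idx].mean(axis=0)
            frame = reimage_group(frame, trajectory.box[f], reimage_indices, anchor)
        transform = kabsch_fit(frame[idx], reference.protein_coords)
        fitted[f] = transform.apply(frame)
    return Trajectory(
        coords=fitted,
        times=trajectory.times.copy(),
        box=trajectory.box.copy(),
        atom_ids=list(trajectory.atom_ids),
    )
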