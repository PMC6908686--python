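"""Interaction detectors versus brute-force oracles, stacking faces and the
specific/nonspecific signature."""

import warnings

import numpy as np
import pytest

from glycotraj import interactions
from glycotraj.interactions import (
    AromaticRing,
    ch_pi_contacts,
    find_aromatic_rings,
    hydrogen_bonds,
    specificity_signature,
    stacking_face,
)
from glycotraj.system_model import AMINO_ACIDS, AtomID


def brute_force_hbonds(coords, atom_ids, donors, acceptors, max_da=0.35, min_angle=120.0):
    """Independent all-pairs scan with the textbook distance/angle formulas."""
    found = set()
    for d, h in donors:
        for a in acceptors:
            if a in (d, h):
                continue
            d_prot = atom_ids[d].resname.upper() in AMINO_ACIDS
            a_prot = atom_ids[a].resname.upper() in AMINO_ACIDS
            if d_prot == a_prot:
                continue
            if np.linalg.norm(coords[a] - coords[d]) > max_da:
                continue
            v1 = coords[d] - coords[h]
            v2 = coords[a] - coords[h]
            cos = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            if np.degrees(np.arccos(np.clip(cos, -1, 1))) >= min_angle:
                found.add((d, h, a))
    return found


def brute_force_chpi(coords, ch_groups, rings, max_dist=0.45, max_offset=0.20, max_angle=40.0):
    found = set()
    for ring in rings:
        pts = coords[ring.atom_indices]
        centroid = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - centroid)
        normal = vt[2]
        if np.abs((pts - centroid) @ normal).max() > 0.03:
            continue
        for c, h in ch_groups:
            rel = coords[c] - centroid
            if np.linalg.norm(rel) > max_dist:
                continue
            height = rel @ normal
            if np.linalg.norm(rel - height * normal) > max_offset:
                continue
            toward_ring = -(normal if height >= 0 else -normal)
            ch = coords[h] - coords[c]
            cos = np.dot(ch, toward_ring) / (np.linalg.norm(ch) * np.linalg.norm(toward_ring))
            if np.degrees(np.arccos(np.clip(cos, -1, 1))) <= max_angle:
                found.add((c, h, ring.label))
    return found


def flat_ring(center, normal_axis="z", label="TRP23/6ring", resid=23):
    angles = np.deg2rad(60.0 * np.arange(6))
    pts = np.stack([0.139 * np.cos(angles), 0.139 * np.sin(angles), np.zeros(6)], axis=1)
    if normal_axis == "x":
        pts = pts[:, [2, 0, 1]]
    return np.asarray(center) + pts


class TestHydrogenBonds:
    def setup_method(self):
        # protein backbone donor N-H plus carbonyl, and one ligand acceptor
        self.atom_ids = [
            AtomID("GLY", 1, "N"),
            AtomID("GLY", 1, "H"),
            AtomID("GLY", 1, "O"),
            AtomID("PYR", 101, "O5"),
        ]
        self.donors = [(0, 1)]
        self.acceptors = [3]

    def coords(self, da, angle_deg=180.0):
        n = np.zeros(3)
        h = np.array([0.10, 0.0, 0.0])
        # place acceptor so D-A distance = da and D-H...A angle = angle_deg
        a_dir = np.array(
            [np.cos(np.deg2rad(180 - angle_deg)), np.sin(np.deg2rad(180 - angle_deg)), 0.0]
        )
        a = h + a_dir * (da - 0.10 if angle_deg == 180 else da * 0.8)
        return np.stack([n, h, np.array([0.5, 0.5, 0.5]), a])

    def test_inside_criteria_detected(self):
        records = hydrogen_bonds(self.coords(0.29), self.atom_ids, self.donors, self.acceptors)
        assert len(records) == 1
        rec = records[0]
        assert rec.partner_class == "backbone"
        assert rec.ligand_atom.name == "O5"
        assert rec.distance == pytest.approx(0.29, abs=1e-9)

    def test_long_distance_not_detected(self):
        records = hydrogen_bonds(self.coords(0.40), self.atom_ids, self.donors, self.acceptors)
        assert records == []

    def test_bent_geometry_not_detected(self):
        records = hydrogen_bonds(self.coords(0.29, angle_deg=90.0), self.atom_ids, self.donors, self.acceptors)
        assert records == []

    def test_matches_brute_force_on_random_frames(self, toy_system):
        atom_ids = toy_system.atom_ids
        donors = interactions.backbone_donors(atom_ids)
        acceptors = interactions.ligand_acceptors(atom_ids)
        rng = np.random.default_rng(31)
        for _ in range(25):
            coords = rng.uniform(0, 2.0, size=(len(atom_ids), 3))
            ours = hydrogen_bonds(coords, atom_ids, donors, acceptors)
            oracle = brute_force_hbonds(coords, atom_ids, donors, acceptors)
            our_sig = sorted(
                (r.protein_partner, r.ligand_atom, round(r.distance, 9)) for r in ours
            )
            oracle_sig = sorted(
                (
                    f"{atom_ids[d].resname}{atom_ids[d].resid}:{atom_ids[d].name}",
                    atom_ids[a],
                    round(float(np.linalg.norm(coords[a] - coords[d])), 9),
                )
                for d, h, a in oracle
            )
            assert our_sig == oracle_sig


class TestChPiContacts:
    def make_system(self, c_pos, h_pos):
        ring = AromaticRing(23, "TRP23/6ring", np.arange(6))
        coords = np.vstack([flat_ring([0, 0, 0]), [c_pos], [h_pos]])
        atom_ids = [AtomID("TRP", 23, n) for n in ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")]
        atom_ids += [AtomID("PYR", 101, "C2"), AtomID("PYR", 101, "H2")]
        return coords, atom_ids, [(6, 7)], [ring]

    def test_stacked_ch_detected(self):
        coords, ids, chs, rings = self.make_system([0, 0, 0.40], [0, 0, 0.30])
        records = ch_pi_contacts(coords, ids, chs, rings)
        assert len(records) == 1
        assert records[0].offset == pytest.approx(0.0, abs=1e-12)
        assert records[0].angle == pytest.approx(0.0, abs=1e-9)

    def test_parallel_ch_not_detected(self):
        coords, ids, chs, rings = self.make_system([0, 0, 0.40], [0.109, 0, 0.40])
        assert ch_pi_contacts(coords, ids, chs, rings) == []

    def test_offset_beyond_limit_not_detected(self):
        coords, ids, chs, rings = self.make_system([0.3, 0, 0.25], [0.3, 0, 0.15])
        assert ch_pi_contacts(coords, ids, chs, rings) == []

    def test_nonplanar_ring_flagged_and_skipped(self):
        coords, ids, chs, rings = self.make_system([0, 0, 0.40], [0, 0, 0.30])
        coords[0, 2] += 0.12  # bend one ring atom out of plane
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            assert ch_pi_contacts(coords, ids, chs, rings) == []
        assert any("non-planar" in str(w.message) for w in caught)

    def test_matches_brute_force_on_random_frames(self, toy_system):
        atom_ids = toy_system.atom_ids
        rings = find_aromatic_rings(atom_ids)
        pairs, _, _ = interactions.ligand_ch_groups(atom_ids, 101)
        rng = np.random.default_rng(32)
        for _ in range(25):
            coords = rng.uniform(0, 1.2, size=(len(atom_ids), 3))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ours = ch_pi_contacts(coords, atom_ids, pairs, rings)
                oracle = brute_force_chpi(coords, pairs, rings)
            our_keys = {
                (r.ligand_atom.name, r.protein_partner) for r in ours
            }
            oracle_keys = {(atom_ids[c].name, label) for c, h, label in oracle}
            assert our_keys == oracle_keys and len(ours) == len(oracle)

    def test_rigid_transform_invariance(self, toy_system):
        atom_ids = toy_system.atom_ids
        rings = find_aromatic_rings(atom_ids)
        pairs, _, _ = interactions.ligand_ch_groups(atom_ids, 101)
        coords = np.vstack([toy_system.protein_coords, toy_system.bound_ligand])
        base = ch_pi_contacts(coords, atom_ids, pairs, rings)
        a = np.deg2rad(77.0)
        R = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
        moved = coords @ R.T + np.array([1.0, -2.0, 0.3])
        transformed = ch_pi_contacts(moved, atom_ids, pairs, rings)
        assert {(r.ligand_atom, r.protein_partner) for r in base} == {
            (r.ligand_atom, r.protein_partner) for r in transformed
        }
        for rb, rt in zip(base, transformed):
            assert rb.distance == pytest.approx(rt.distance, abs=1e-9)
            assert rb.angle == pytest.approx(rt.angle, abs=1e-6)


class TestStackingFace:
    def place_moiety(self, toy_system, flip=False, offset=(0.0, 0.0, 0.37)):
        """Moiety ring centroid above a free-standing ring, optionally flipped
        180 degrees about the in-plane x axis."""
        from glycotraj.synthetic_data import pyranose_template

        names, template = pyranose_template()
        coords = template.copy()
        if flip:
            flip_mat = np.diag([1.0, -1.0, -1.0])
            coords = coords @ flip_mat.T
        coords = coords - coords[[names.index(n) for n in ("C1", "C2", "C3", "C4", "C5", "O5")]].mean(axis=0)
        coords = coords + np.asarray(offset)
        ring_pts = flat_ring([0, 0, 0])
        atom_ids = [AtomID("TRP", 23, n) for n in ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")]
        atom_ids += [AtomID("PYR", 101, n) for n in names]
        all_coords = np.vstack([ring_pts, coords])
        ring = AromaticRing(23, "TRP23/6ring", np.arange(6))
        return all_coords, atom_ids, ring

    def test_even_face_down_in_template_orientation(self, toy_system):
        # the template's H2/H4/H6 hydrogens point to -z, toward the ring below
        coords, ids, ring = self.place_moiety(toy_system)
        assert stacking_face(coords, ids, 101, ring) == "even"

    def test_flipped_moiety_presents_odd_face(self, toy_system):
        coords, ids, ring = self.place_moiety(toy_system, flip=True)
        assert stacking_face(coords, ids, 101, ring) == "odd"

    def test_distant_moiety_is_none(self, toy_system):
        coords, ids, ring = self.place_moiety(toy_system, offset=(0.0, 0.0, 2.0))
        assert stacking_face(coords, ids, 101, ring) == "none"


class TestSpecificitySignature:
    def hbond(self, partner_class):
        return interactions.InteractionRecord(
            kind="hbond", frame=0, ligand_atom=AtomID("PYR", 101, "O5"),
            protein_partner="GLY26:N", partner_class=partner_class,
            distance=0.29, angle=170.0,
        )

    def chpi(self):
        return interactions.InteractionRecord(
            kind="chpi", frame=0, ligand_atom=AtomID("PYR", 101, "C2"),
            protein_partner="TRP23/6ring", partner_class="sidechain",
            distance=0.4, angle=10.0, offset=0.05,
        )

    def test_backbone_only_hbonds_is_nonspecific_like(self):
        records = [self.hbond("backbone") for _ in range(10)]
        sig = specificity_signature(records, n_frames=10)
        assert sig.verdict == "nonspecific-like"
        assert sig.backbone_hbond_fraction == 1.0

    def test_sustained_chpi_is_specific_like(self):
        records = [self.chpi() for _ in range(10)]
        sig = specificity_signature(records, n_frames=10)
        assert sig.verdict == "specific-like"
        assert sig.mean_chpi_count_per_frame == 1.0

    def test_no_records_is_indeterminate_with_warning(self):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            sig = specificity_signature([], n_frames=5)
        assert sig.verdict == "indeterminate"
        assert any("indeterminate" in str(w.message) for w in caught)

    def test_generator_poses_fall_on_opposite_sides(self, toy_system):
        """The synthetic specific pose reads specific-like, the nonspecific
        pose nonspecific-like — the discriminating signature end to end."""
        from glycotraj.pipeline import frame_interactions
        from tests.conftest import static_trajectory

        for ligand, expected in (
            (toy_system.bound_ligand, "specific-like"),
            (toy_system.nonspecific_ligand, "nonspecific-like"),
        ):
            traj = static_trajectory(toy_system, ligand, n_frames=1)
            records = frame_interactions(traj.coords[0], traj, 0)
            sig = specificity_signature(records, n_frames=1)
            assert sig.verdict == expected
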