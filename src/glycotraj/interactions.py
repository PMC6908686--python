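"""Geometric interaction fingerprints.

Hydrogen bonds and carbohydrate-aromatic CH/pi contacts are detected with
conventional geometric criteria (H-bond: donor-acceptor distance <= 0.35 nm
and D-H...A angle >= 120 deg; CH/pi: ring-carbon to ring-centroid distance
<= 0.45 nm, in-plane offset <= 0.20 nm, C-H versus ring-normal angle
<= 40 deg).  Two observables separate specific from nonspecific binding
modes: nonspecific adhesion shows hydrogen bonds almost exclusively to
protein backbone N-H / C=O groups and essentially no CH/pi contacts, while
the specific pose stacks pyranose CH bonds on the Trp/Tyr ring faces.

The stacking face of a pyranose on an aromatic ring is reported as ``odd``
(CH bonds of C1/C3/C5 touch the ring) or ``even`` (C2/C4/C6) — the two faces
discriminate the correct binding orientation from a flipped pose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .system_model import AMINO_ACIDS, AtomID, BACKBONE_ATOMS, is_hydrogen

HBOND_MAX_DA = 0.35  # nm
HBOND_MIN_ANGLE = 120.0  # degrees
CHPI_MAX_DIST = 0.45  # nm, ring carbon to ring centroid
CHPI_MAX_OFFSET = 0.20  # nm, projection onto ring plane
CHPI_MAX_ANGLE = 40.0  # degrees, C-H vs ring normal
RING_PLANARITY_TOL = 0.03  # nm
CH_BOND_LENGTH = 0.109  # nm, for reconstructed hydrogens
_TETRAHEDRAL_HALF = np.deg2rad(109.47 / 2.0)

TRP_RING5 = ("CG", "CD1", "NE1", "CE2", "CD2")
TRP_RING6 = ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")
TYR_RING = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")


@dataclass(frozen=True)
class InteractionRecord:
    kind: str  # "hbond" | "chpi"
    frame: int
    ligand_atom: AtomID
    protein_partner: str  # atom id string or ring label
    partner_class: str  # "backbone" | "sidechain"
    distance: float  # nm (D-A or C-centroid)
    angle: float  # degrees
    offset: float | None = None  # nm, CH/pi in-plane offset
    reconstructed_h: bool = False

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("distance must be positive")
        if not 0 <= self.angle <= 180:
            raise ValueError("angle must be within [0, 180]")


@dataclass
class AromaticRing:
    """One aromatic ring (Trp indole 5/6-ring or Tyr phenol ring)."""

    residue_id: int
    label: str
    atom_indices: np.ndarray

    def __post_init__(self) -> None:
        self.atom_indices = np.asarray(self.atom_indices, dtype=int)
        if len(self.atom_indices) < 5:
            raise ValueError("an aromatic ring needs at least 5 atoms")

    def geometry(self, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        """(centroid, unit normal, max deviation from the LS plane) in nm."""
        pts = coords[self.atom_indices]
        centroid = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - centroid)
        normal = vt[2]
        deviation = float(np.abs((pts - centroid) @ normal).max())
        return centroid, normal, deviation


def find_aromatic_rings(atom_ids: Sequence[AtomID]) -> list[AromaticRing]:
    """Locate Trp (two rings) and Tyr (one ring) ring systems by atom name."""
    by_residue: dict[tuple[str, int], dict[str, int]] = {}
    for i, aid in enumerate(atom_ids):
        by_residue.setdefault((aid.resname.upper(), aid.resid), {})[aid.name] = i
    rings = []
    for (resname, resid), atoms in by_residue.items():
        specs = []
        if resname == "TRP":
            specs = [("5ring", TRP_RING5), ("6ring", TRP_RING6)]
        elif resname == "TYR":
            specs = [("ring", TYR_RING)]
        for tag, names in specs:
            if all(n in atoms for n in names):
                rings.append(
                    AromaticRing(
                        residue_id=resid,
                        label=f"{resname}{resid}/{tag}",
                        atom_indices=np.array([atoms[n] for n in names]),
                    )
                )
    return sorted(rings, key=lambda r: (r.residue_id, r.label))


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _partner_split(atom_ids: Sequence[AtomID], i: int, j: int) -> tuple[int, int] | None:
    """Return (ligand index, protein index) or None if not a ligand-protein pair."""
    i_prot = atom_ids[i].resname.upper() in AMINO_ACIDS
    j_prot = atom_ids[j].resname.upper() in AMINO_ACIDS
    if i_prot == j_prot:
        return None
    return (j, i) if i_prot else (i, j)


def _partner_class(aid: AtomID) -> str:
    return "backbone" if aid.name in BACKBONE_ATOMS else "sidechain"


def hydrogen_bonds(
    coords: np.ndarray,
    atom_ids: Sequence[AtomID],
    donors: Sequence[tuple[int, int]],
    acceptors: Sequence[int],
    max_da: float = HBOND_MAX_DA,
    min_angle: float = HBOND_MIN_ANGLE,
    frame: int = 0,
) -> list[InteractionRecord]:
    """Detect ligand-protein hydrogen bonds in one frame.

    ``donors`` are (donor heavy atom, donor hydrogen) index pairs; ``acceptors``
    are acceptor heavy-atom indices.  A record is emitted for every (D, H, A)
    with D-A distance <= max_da and D-H...A angle >= min_angle where exactly
    one of D and A belongs to the protein; the partner_class reflects whether
    the protein-side atom is main chain (N, H, C, O) or side chain.
    """
    coords = np.asarray(coords)
    records: list[InteractionRecord] = []
    for d_idx, h_idx in donors:
        for a_idx in acceptors:
            if a_idx in (d_idx, h_idx):
                continue
            split = _partner_split(atom_ids, d_idx, a_idx)
            if split is None:
                continue
            dist = float(np.linalg.norm(coords[a_idx] - coords[d_idx]))
            if dist > max_da:
                continue
            angle = _angle_deg(coords[d_idx] - coords[h_idx], coords[a_idx] - coords[h_idx])
            if angle < min_angle:
                continue
            lig_idx, prot_idx = split
            prot = atom_ids[prot_idx]
            records.append(
                InteractionRecord(
                    kind="hbond",
                    frame=frame,
                    ligand_atom=atom_ids[lig_idx],
                    protein_partner=f"{prot.resname}{prot.resid}:{prot.name}",
                    partner_class=_partner_class(prot),
                    distance=dist,
                    angle=angle,
                )
            )
    return records


def ch_pi_contacts(
    coords: np.ndarray,
    atom_ids: Sequence[AtomID],
    ch_groups: Sequence[tuple[int, int]],
    rings: Sequence[AromaticRing],
    max_dist: float = CHPI_MAX_DIST,
    max_offset: float = CHPI_MAX_OFFSET,
    max_angle: float = CHPI_MAX_ANGLE,
    frame: int = 0,
    reconstructed: bool = False,
) -> list[InteractionRecord]:
    """Detect CH/pi contacts between ligand C-H groups and aromatic rings.

    A contact requires carbon-to-ring-centroid distance <= max_dist, in-plane
    offset of the projected carbon <= max_offset, and an angle between the
    C->H vector and the ring normal <= max_angle (evaluated against whichever
    normal direction points from ring to carbon).  Non-planar rings
    (deviation > 0.03 nm from the least-squares plane) are flagged and
    skipped.
    """
    coords = np.asarray(coords)
    records: list[InteractionRecord] = []
    for ring in rings:
        centroid, normal, deviation = ring.geometry(coords)
        if deviation > RING_PLANARITY_TOL:
            warnings.warn(f"ring {ring.label} non-planar ({deviation:.3f} nm); skipped", stacklevel=2)
            continue
        for c_idx, h_idx in ch_groups:
            rel = coords[c_idx] - centroid
            dist = float(np.linalg.norm(rel))
            if dist > max_dist:
                continue
            height = float(rel @ normal)
            offset = float(np.linalg.norm(rel - height * normal))
            if offset > max_offset:
                continue
            outward = normal if height >= 0 else -normal
            ch_vec = coords[h_idx] - coords[c_idx]
            angle = _angle_deg(ch_vec, -outward)  # H pointing at the ring face
            if angle > max_angle:
                continue
            records.append(
                InteractionRecord(
                    kind="chpi",
                    frame=frame,
                    ligand_atom=atom_ids[c_idx],
                    protein_partner=ring.label,
                    partner_class="sidechain",
                    distance=dist,
                    angle=angle,
                    offset=offset,
                    reconstructed_h=reconstructed,
                )
            )
    return records


def ligand_ch_groups(
    atom_ids: Sequence[AtomID],
    residue_number: int,
    coords: np.ndarray | None = None,
) -> tuple[list[tuple[int, int]], np.ndarray | None, bool]:
    """(C, H) index pairs for a pyranose's ring carbons C1..C6.

    Hydrogens are matched by name (H1..H5 for C1..C5; H61/H62 for C6).  When a
    carbon has no hydrogen and ``coords`` is given, candidate hydrogens are
    reconstructed from ideal tetrahedral geometry at the two open positions of
    the ring carbon and appended as extra coordinates; the returned flag says
    reconstruction happened.  Returns (pairs, extended coords or None, flag).
    """
    atoms = {aid.name: i for i, aid in enumerate(atom_ids) if aid.resid == residue_number}
    h_names = {f"C{k}": [f"H{k}"] for k in range(1, 6)}
    h_names["C6"] = ["H61", "H62"]
    pairs: list[tuple[int, int]] = []
    extra: list[np.ndarray] = []
    reconstructed = False
    neighbors = {
        "C1": ("C2", "O5"), "C2": ("C1", "C3"), "C3": ("C2", "C4"),
        "C4": ("C3", "C5"), "C5": ("C4", "O5"), "C6": ("C5", "C5"),
    }
    n_atoms = len(atom_ids)
    for carbon, hydrogens in h_names.items():
        if carbon not in atoms:
            continue
        c_idx = atoms[carbon]
        found = [atoms[h] for h in hydrogens if h in atoms]
        if found:
            pairs.extend((c_idx, h) for h in found)
            continue
        if coords is None:
            raise ValueError(
                f"residue {residue_number}: no hydrogen for {carbon} "
                f"(expected one of {hydrogens}) and no coordinates to reconstruct from"
            )
        a_name, b_name = neighbors[carbon]
        if a_name not in atoms or b_name not in atoms:
            raise ValueError(f"residue {residue_number}: cannot reconstruct H on {carbon}")
        reconstructed = True
        c = coords[c_idx]
        u = coords[atoms[a_name]] - c
        v = coords[atoms[b_name]] - c
        u /= np.linalg.norm(u)
        v /= np.linalg.norm(v)
        if a_name == b_name:  # exocyclic C6: only one neighbour known
            axis = u
            perp = np.array([1.0, 0.0, 0.0])
            if abs(axis @ perp) > 0.9:
                perp = np.array([0.0, 1.0, 0.0])
            perp = perp - (perp @ axis) * axis
            perp /= np.linalg.norm(perp)
            directions = [-axis * np.cos(_TETRAHEDRAL_HALF * 2) + perp * np.sin(_TETRAHEDRAL_HALF * 2)]
        else:
            bisector = u + v
            bisector /= np.linalg.norm(bisector)
            perp = np.cross(u, v)
            perp /= np.linalg.norm(perp)
            directions = [
                -bisector * np.cos(_TETRAHEDRAL_HALF) + s * perp * np.sin(_TETRAHEDRAL_HALF)
                for s in (+1.0, -1.0)
            ]
        for d in directions:
            extra.append(c + CH_BOND_LENGTH * d)
            pairs.append((c_idx, n_atoms + len(extra) - 1))
    if extra:
        coords_ext = np.vstack([np.asarray(coords), np.stack(extra)])
        return pairs, coords_ext, reconstructed
    return pairs, (None if coords is None else np.asarray(coords)), reconstructed


def stacking_face(
    coords: np.ndarray,
    atom_ids: Sequence[AtomID],
    residue_number: int,
    ring: AromaticRing,
    max_dist: float = CHPI_MAX_DIST,
    max_offset: float = CHPI_MAX_OFFSET,
    max_angle: float = CHPI_MAX_ANGLE,
) -> str:
    """Which pyranose face stacks on the ring: ``odd`` (C1/C3/C5), ``even``
    (C2/C4/C6) or ``none``.

    Qualifying CH/pi contacts are counted per carbon set; the set with
    strictly more contacting carbons wins, a tie (including 0-0, e.g. when
    the moiety is out of range) returns ``none``.
    """
    pairs, coords_ext, reconstructed = ligand_ch_groups(atom_ids, residue_number, coords)
    work = coords_ext if coords_ext is not None else np.asarray(coords)
    records = ch_pi_contacts(
        work, list(atom_ids), pairs, [ring],
        max_dist=max_dist, max_offset=max_offset, max_angle=max_angle,
        reconstructed=reconstructed,
    ) if len(pairs) else []
    odd = {"C1", "C3", "C5"}
    even = {"C2", "C4", "C6"}
    odd_carbons = {r.ligand_atom.name for r in records if r.ligand_atom.name in odd}
    even_carbons = {r.ligand_atom.name for r in records if r.ligand_atom.name in even}
    if len(odd_carbons) > len(even_carbons):
        return "odd"
    if len(even_carbons) > len(odd_carbons):
        return "even"
    return "none"


@dataclass(frozen=True)
class SpecificitySignature:
    backbone_hbond_fraction: float
    mean_chpi_count_per_frame: float
    verdict: str
    n_hbonds: int = 0
    n_chpi: int = 0


def specificity_signature(
    records: Sequence[InteractionRecord],
    n_frames: int,
    backbone_fraction_hi: float = 0.8,
    chpi_min: float = 0.5,
) -> SpecificitySignature:
    """Classify a bound interval as specific-like or nonspecific-like.

    The nonspecific regime shows backbone-dominated hydrogen bonding
    (backbone fraction >= backbone_fraction_hi) with essentially no CH/pi
    contacts (< chpi_min per frame); sustained CH/pi contacts
    (>= chpi_min per frame) mark the specific-like regime; anything else,
    including an interval without any interaction, is indeterminate.
    """
    if n_frames <= 0:
        raise ValueError("interval must contain at least one frame")
    hbonds = [r for r in records if r.kind == "hbond"]
    chpis = [r for r in records if r.kind == "chpi"]
    if not records:
        warnings.warn("no interaction records in interval; verdict indeterminate", stacklevel=2)
        return SpecificitySignature(0.0, 0.0, "indeterminate")
    backbone_fraction = (
        sum(1 for r in hbonds if r.partner_class == "backbone") / len(hbonds)
        if hbonds
        else 0.0
    )
    mean_chpi = len(chpis) / n_frames
    if mean_chpi >= chpi_min:
        verdict = "specific-like"
    elif hbonds and backbone_fraction >= backbone_fraction_hi:
        verdict = "nonspecific-like"
    else:
        verdict = "indeterminate"
    return SpecificitySignature(
        backbone_hbond_fraction=float(backbone_fraction),
        mean_chpi_count_per_frame=float(mean_chpi),
        verdict=verdict,
        n_hbonds=len(hbonds),
        n_chpi=len(chpis),
    )


def backbone_donors(atom_ids: Sequence[AtomID]) -> list[tuple[int, int]]:
    """Protein (N, H) amide donor pairs plus hydroxyl donors (OG-HG, OH-HH)."""
    by_residue: dict[int, dict[str, int]] = {}
    for i, aid in enumerate(atom_ids):
        if aid.resname.upper() in AMINO_ACIDS:
            by_residue.setdefault(aid.resid, {})[aid.name] = i
    donors = []
    for atoms in by_residue.values():
        for heavy, hydrogen in (("N", "H"), ("N", "HN"), ("OG", "HG"), ("OH", "HH")):
            if heavy in atoms and hydrogen in atoms:
                donors.append((atoms[heavy], atoms[hydrogen]))
    return donors


def protein_acceptors(atom_ids: Sequence[AtomID]) -> list[int]:
    """Protein oxygen acceptors (carbonyl O, hydroxyl OG/OH, carboxylate)."""
    return [
        i
        for i, aid in enumerate(atom_ids)
        if aid.resname.upper() in AMINO_ACIDS
        and not is_hydrogen(aid.name)
        and aid.name.startswith("O")
    ]


def ligand_acceptors(atom_ids: Sequence[AtomID]) -> list[int]:
    """Ligand oxygen and nitrogen acceptors."""
    return [
        i
        for i, aid in enumerate(atom_ids)
        if aid.resname.upper() not in AMINO_ACIDS
        and (aid.name.startswith("O") or aid.name.startswith("N"))
        and not is_hydrogen(aid.name)
    ]
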