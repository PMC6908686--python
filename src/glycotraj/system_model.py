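"""Domain types and structure/trajectory ingestion.

Everything downstream works in a single unit system: nanometres for lengths,
nanoseconds for times.  PDB files (Angstrom) are converted on ingest, as are
MDAnalysis-read trajectories (Angstrom / picosecond).

The canonical pyranose ring atom order ``(C1, C2, C3, C4, C5, C6, O5)`` is the
contract between atom selections and subsite reference coordinates: every
7-atom moiety selection and every subsite reference stores its positions in
exactly this order, so RMSD never needs name matching at compute time.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

ANGSTROM_PER_NM = 10.0
PS_PER_NS = 1000.0

#: Fixed atom order for one monosaccharide moiety.
CANONICAL_MOIETY_ATOMS: tuple[str, ...] = ("C1", "C2", "C3", "C4", "C5", "C6", "O5")

#: Default key binding residues (Ser19, Trp21, Trp23, Tyr30).
DEFAULT_BINDING_RESIDUES: frozenset[int] = frozenset({19, 21, 23, 30})

#: Residue names treated as protein when splitting protein from ligand.
AMINO_ACIDS: frozenset[str] = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Protein main-chain heavy atoms plus the amide hydrogen.
BACKBONE_ATOMS: frozenset[str] = frozenset({"N", "H", "HN", "C", "O"})


class AtomID(NamedTuple):
    """(residue name, residue number, atom name) identity of one atom."""

    resname: str
    resid: int
    name: str


def is_hydrogen(atom_name: str) -> bool:
    """Heuristic element test from the atom name (PDB v3 style names)."""
    stripped = atom_name.lstrip("0123456789")
    return stripped[:1].upper() == "H"


@dataclass(frozen=True)
class AtomSelection:
    """Ordered atom indices into a Trajectory."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1:
            raise ValueError("indices must be one-dimensional")
        if len(np.unique(idx)) != len(idx):
            raise ValueError("selection indices must be unique")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class MoietySpec:
    """One monosaccharide moiety of the ligand.

    role is the position in the oligosaccharide chain: ``reducing`` carries the
    anomeric hydroxyl, ``nonreducing`` is the opposite terminus, ``internal``
    sits in between (only for trisaccharides).
    """

    residue_number: int
    role: str

    _ROLES = ("reducing", "internal", "nonreducing")

    def __post_init__(self) -> None:
        if self.role not in self._ROLES:
            raise ValueError(f"role must be one of {self._ROLES}, got {self.role!r}")


@dataclass
class ReferenceComplex:
    """Reference protein coordinates plus per-subsite 7-atom saccharide poses.

    subsite_refs maps a subsite label (conventionally red/green/blue) to the
    positions of one monosaccharide's C1..C6,O5 atoms in canonical order, all
    in nm.
    """

    protein_coords: np.ndarray
    protein_atom_ids: list[AtomID]
    subsite_refs: dict[str, np.ndarray]
    binding_residue_ids: frozenset[int] = DEFAULT_BINDING_RESIDUES
    source_label: str = ""

    def __post_init__(self) -> None:
        self.protein_coords = np.asarray(self.protein_coords, dtype=float)
        if self.protein_coords.ndim != 2 or self.protein_coords.shape[1] != 3:
            raise ValueError("protein_coords must be (N, 3)")
        if len(self.protein_coords) == 0:
            raise ValueError("protein_coords must be non-empty")
        if len(self.protein_atom_ids) != len(self.protein_coords):
            raise ValueError("protein_atom_ids length mismatch")
        if len(set(self.subsite_refs)) != len(self.subsite_refs):
            raise ValueError("subsite labels must be unique")
        refs = {}
        for label, pos in self.subsite_refs.items():
            pos = np.asarray(pos, dtype=float)
            if pos.shape != (7, 3):
                raise ValueError(
                    f"subsite {label!r}: expected 7 positions in order "
                    f"{CANONICAL_MOIETY_ATOMS}, got shape {pos.shape}"
                )
            refs[label] = pos
        self.subsite_refs = refs

    @property
    def subsite_labels(self) -> tuple[str, ...]:
        return tuple(self.subsite_refs)


@dataclass
class Trajectory:
    """Coordinates (frames x atoms x 3, nm), times (ns) and orthorhombic box
    edge lengths (frames x 3, nm) with per-atom identities."""

    coords: np.ndarray
    times: np.ndarray
    box: np.ndarray
    atom_ids: list[AtomID]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (frames, atoms, 3)")
        n_frames = self.coords.shape[0]
        if self.times.shape != (n_frames,):
            raise ValueError("times length must equal frame count")
        if self.box.shape != (n_frames, 3):
            raise ValueError("box must be (frames, 3) edge lengths")
        if n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if len(self.atom_ids) != self.coords.shape[1]:
            raise ValueError("atom_ids length must equal atom count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


# ---------------------------------------------------------------------------
# Structure ingestion


def read_reference_complex(
    structure_file: str | Path,
    model_index: int,
    subsite_map: Mapping[str, int],
    binding_residues: Iterable[int] = DEFAULT_BINDING_RESIDUES,
    source_label: str | None = None,
) -> ReferenceComplex:
    """Read a reference complex from a PDB file.

    Parameters
    ----------
    structure_file
        PDB path.  Coordinates are converted from Angstrom to nm.
    model_index
        1-based MODEL number as written in the PDB file (NMR ensembles number
        their models from 1).
    subsite_map
        subsite label -> ligand residue number carrying that subsite's
        monosaccharide.  Each mapped residue must provide atoms C1..C6 and O5.
    binding_residues
        Residue numbers of the key binding residues.

    Protein atoms are the heavy (non-hydrogen) atoms of standard amino-acid
    residues; everything else (HETATM saccharides etc.) is considered ligand.
    """
    import gemmi

    structure = gemmi.read_structure(str(structure_file))
    available = [m.num for m in structure]
    model = None
    for m in structure:
        if m.num == int(model_index):
            model = m
            break
    if model is None:
        raise ValueError(
            f"model {model_index} not found in {structure_file}; "
            f"available models: {available}"
        )

    protein_coords: list[list[float]] = []
    protein_ids: list[AtomID] = []
    ligand_atoms: dict[int, dict[str, np.ndarray]] = {}
    for chain in model:
        for residue in chain:
            resid = residue.seqid.num
            is_protein = residue.name.upper() in AMINO_ACIDS
            for atom in residue:
                if atom.is_hydrogen():
                    continue
                pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z]) / ANGSTROM_PER_NM
                if is_protein:
                    protein_coords.append(pos.tolist())
                    protein_ids.append(AtomID(residue.name, resid, atom.name))
                else:
                    ligand_atoms.setdefault(resid, {})[atom.name] = pos

    subsite_refs: dict[str, np.ndarray] = {}
    for label, resid in subsite_map.items():
        atoms = ligand_atoms.get(resid)
        if atoms is None:
            raise ValueError(
                f"subsite {label!r}: ligand residue {resid} not found "
                f"(ligand residues present: {sorted(ligand_atoms)})"
            )
        missing = [name for name in CANONICAL_MOIETY_ATOMS if name not in atoms]
        if missing:
            raise ValueError(
                f"subsite {label!r}: residue {resid} lacks atoms {missing}"
            )
        subsite_refs[label] = np.stack([atoms[n] for n in CANONICAL_MOIETY_ATOMS])

    return ReferenceComplex(
        protein_coords=np.asarray(protein_coords),
        protein_atom_ids=protein_ids,
        subsite_refs=subsite_refs,
        binding_residue_ids=frozenset(binding_residues),
        source_label=source_label or f"{Path(structure_file).name}#model{model_index}",
    )


# ---------------------------------------------------------------------------
# Trajectory ingestion

XYZT_SUFFIX = ".xyzt"


def write_xyzt(trajectory: Trajectory, path: str | Path) -> None:
    """Write the plain-text XYZ-with-time fixture dialect.

    Per frame::

        <n_atoms>
        t=<time_ns> box=<bx> <by> <bz>
        <resname> <resid> <atom name> <x> <y> <z>     (nm, one line per atom)
    """
    with open(path, "w") as handle:
        for f in range(trajectory.n_frames):
            handle.write(f"{trajectory.n_atoms}\n")
            bx, by, bz = trajectory.box[f]
            handle.write(f"t={trajectory.times[f]:.6f} box={bx:.6f} {by:.6f} {bz:.6f}\n")
            for aid, pos in zip(trajectory.atom_ids, trajectory.coords[f]):
                handle.write(
                    f"{aid.resname} {aid.resid} {aid.name} "
                    f"{pos[0]:.6f} {pos[1]:.6f} {pos[2]:.6f}\n"
                )


def _read_xyzt(path: Path) -> Trajectory:
    frames: list[np.ndarray] = []
    times: list[float] = []
    boxes: list[np.ndarray] = []
    atom_ids: list[AtomID] | None = None
    with open(path) as handle:
        while True:
            header = handle.readline()
            if not header:
                break
            if not header.strip():
                continue
            try:
                n_atoms = int(header)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed frame header {header!r}") from exc
            meta = handle.readline().split()
            if len(meta) != 4 or not meta[0].startswith("t=") or not meta[1].startswith("box="):
                raise ValueError(f"{path}: malformed frame metadata line {meta!r}")
            times.append(float(meta[0][2:]))
            boxes.append(np.array([float(meta[1][4:]), float(meta[2]), float(meta[3])]))
            ids: list[AtomID] = []
            coords = np.empty((n_atoms, 3))
            for i in range(n_atoms):
                line = handle.readline()
                parts = line.split()
                if len(parts) != 6:
                    raise ValueError(
                        f"{path}: truncated frame at t={times[-1]} ns (atom {i + 1}/{n_atoms})"
                    )
                ids.append(AtomID(parts[0], int(parts[1]), parts[2]))
                coords[i] = [float(parts[3]), float(parts[4]), float(parts[5])]
            if atom_ids is None:
                atom_ids = ids
            elif ids != atom_ids:
                raise ValueError(f"{path}: atom identities change between frames")
            frames.append(coords)
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return Trajectory(
        coords=np.stack(frames), times=np.array(times), box=np.stack(boxes),
        atom_ids=list(atom_ids),
    )


def _read_mdanalysis(traj_file: Path, topology_file: Path) -> Trajectory:
    import warnings

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        universe = mda.Universe(str(topology_file), str(traj_file))
    atom_ids = [
        AtomID(str(a.resname), int(a.resid), str(a.name)) for a in universe.atoms
    ]
    frames, times, boxes = [], [], []
    for ts in universe.trajectory:
        dims = ts.dimensions
        if dims is None or not np.allclose(dims[3:], 90.0, atol=1e-3):
            raise ValueError(
                "only orthorhombic boxes are supported "
                f"(frame at {ts.time} ps has angles {None if dims is None else dims[3:]})"
            )
        frames.append(ts.positions / ANGSTROM_PER_NM)
        times.append(ts.time / PS_PER_NS)
        boxes.append(np.asarray(dims[:3], dtype=float) / ANGSTROM_PER_NM)
    return Trajectory(
        coords=np.stack(frames), times=np.array(times), box=np.stack(boxes),
        atom_ids=atom_ids,
    )


def read_trajectory(traj_file: str | Path, topology_file: str | Path | None = None) -> Trajectory:
    """Read a trajectory into nm/ns units.

    The plain-text ``.xyzt`` fixture dialect is self-describing; any other
    format (XTC, TRR, DCD, multi-model PDB ...) is read through MDAnalysis and
    needs ``topology_file``.  Frames are 0-indexed everywhere downstream.
    """
    traj_file = Path(traj_file)
    if traj_file.suffix == XYZT_SUFFIX:
        return _read_xyzt(traj_file)
    if topology_file is None:
        raise ValueError(f"topology_file required for {traj_file.suffix} trajectories")
    return _read_mdanalysis(traj_file, Path(topology_file))


# ---------------------------------------------------------------------------
# Atom selection


def select_atoms(
    atom_ids: Sequence[AtomID],
    residue_number: int,
    atom_names: Sequence[str],
    label: str = "",
) -> AtomSelection:
    """Select atoms of one residue, ordered by the given atom-name sequence.

    The returned indices follow ``atom_names`` order (not file order), so a
    C1..C6,O5 query aligns positionally with subsite reference coordinates.
    """
    if len(atom_names) == 0:
        raise ValueError("atom_names must be non-empty")
    lookup = {
        (aid.resid, aid.name): i
        for i, aid in enumerate(atom_ids)
        if aid.resid == residue_number
    }
    indices = []
    for name in atom_names:
        key = (residue_number, name)
        if key not in lookup:
            present = sorted({aid.name for aid in atom_ids if aid.resid == residue_number})
            raise ValueError(
                f"atom {name!r} not found in residue {residue_number}; "
                f"present: {present}"
            )
        indices.append(lookup[key])
    return AtomSelection(np.array(indices), label=label or f"res{residue_number}")


def select_moiety(atom_ids: Sequence[AtomID], moiety: MoietySpec) -> AtomSelection:
    """The 7 ring atoms of one moiety in canonical order."""
    return select_atoms(
        atom_ids, moiety.residue_number, CANONICAL_MOIETY_ATOMS,
        label=f"{moiety.role}:{moiety.residue_number}",
    )


def protein_heavy_selection(atom_ids: Sequence[AtomID], label: str = "protein-heavy") -> AtomSelection:
    """All heavy atoms of standard amino-acid residues, in file order."""
    indices = [
        i
        for i, aid in enumerate(atom_ids)
        if aid.resname.upper() in AMINO_ACIDS and not is_hydrogen(aid.name)
    ]
    if not indices:
        raise ValueError("no protein heavy atoms found")
    return AtomSelection(np.array(indices), label=label)


def residues_heavy_selection(
    atom_ids: Sequence[AtomID], residue_numbers: Iterable[int], label: str = ""
) -> AtomSelection:
    """Pooled heavy atoms of the listed protein residues, in file order."""
    wanted = set(residue_numbers)
    if not wanted:
        raise ValueError("residue list must be non-empty")
    indices = [
        i
        for i, aid in enumerate(atom_ids)
        if aid.resid in wanted
        and aid.resname.upper() in AMINO_ACIDS
        and not is_hydrogen(aid.name)
    ]
    if not indices:
        raise ValueError(f"no heavy atoms found for residues {sorted(wanted)}")
    return AtomSelection(np.array(indices), label=label or f"residues{sorted(wanted)}")


def ligand_indices(atom_ids: Sequence[AtomID]) -> np.ndarray:
    """Indices of all non-protein atoms (the saccharide ligand, H included)."""
    return np.array(
        [i for i, aid in enumerate(atom_ids) if aid.resname.upper() not in AMINO_ACIDS],
        dtype=int,
    )
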