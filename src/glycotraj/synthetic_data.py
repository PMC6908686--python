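"""Synthetic reference complexes and ground-truth binding trajectories.

The generator emulates the statistical structure the analysis assumes, not
the physics that produces it: a rigid pseudo-protein scaffold carries three
carbohydrate subsites in a groove above two tryptophan-like rings and a
tyrosine-like ring; the ligand is one to three idealised 4C1 pyranose
moieties with ring hydrogens; and the ligand's binding state follows a
continuous-time Markov chain (Gillespie-sampled) whose emission rules place
the ligand at the subsite pose (specific), at a fixed off-site backbone patch
(nonspecific) or uniformly in the box away from the protein (unbound), each
with isotropic Gaussian positional noise.  Because the state path is exact,
occupancies, switch times and the implied dissociation constant are known
analytically, which is what the recovery tests lean on.

Defaults mirror the study conditions this pipeline targets: a single protein
and single ligand copy in a ~4.1 nm box (about 24 mmol/l), 2000 ns of frames
at 1 ns spacing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .system_model import (
    ANGSTROM_PER_NM,
    AtomID,
    CANONICAL_MOIETY_ATOMS,
    MoietySpec,
    ReferenceComplex,
    Trajectory,
    is_hydrogen,
)

LIGAND_RESNAME = "PYR"
LIGAND_FIRST_RESID = 101
SUBSITE_LABELS = ("red", "green", "blue")
SUBSITE_SPACING = 0.52  # nm, approx glycosidic repeat
STACK_HEIGHT = 0.37  # nm, pyranose centroid above ring plane
_MIN_HEAVY_DISTANCE = 0.05  # nm, overlap guard


# ---------------------------------------------------------------------------
# Idealised 4C1 pyranose template


def pyranose_template() -> tuple[list[str], np.ndarray]:
    """Atom names and local coordinates (nm) of one idealised 4C1 pyranose.

    Ring atoms C1..C5,O5 form a chair (alternating +-0.025 nm puckering);
    axial hydrogens H1/H3/H5 point to the +z face (the odd face) and H2/H4 to
    -z; the exocyclic C6 with H61/H62 extends the even (-z) face, so the two
    stacking faces are geometrically distinct, as in beta-GlcNAc.
    An O3 hydroxyl oxygen provides a hydrogen-bond acceptor.
    """
    radius, pucker, ch = 0.145, 0.025, 0.109
    ring_order = ("C1", "C2", "C3", "C4", "C5", "O5")
    names: list[str] = []
    coords: list[np.ndarray] = []
    ring_pos: dict[str, np.ndarray] = {}
    for k, name in enumerate(ring_order):
        angle = np.deg2rad(60.0 * k)
        z = pucker if k % 2 == 0 else -pucker
        pos = np.array([radius * np.cos(angle), radius * np.sin(angle), z])
        ring_pos[name] = pos
        names.append(name)
        coords.append(pos)
    # axial hydrogens: up on the up-puckered carbons, down on the others
    for carbon, sign in (("C1", +1), ("C2", -1), ("C3", +1), ("C4", -1), ("C5", +1)):
        names.append("H" + carbon[1])
        coords.append(ring_pos[carbon] + np.array([0.0, 0.0, sign * ch]))
    # exocyclic C6 on C5, equatorial (tilted to the -z face)
    radial = ring_pos["C5"] / np.linalg.norm(ring_pos["C5"][:2] * [1, 1])
    radial = np.array([ring_pos["C5"][0], ring_pos["C5"][1], 0.0])
    radial /= np.linalg.norm(radial)
    c6 = ring_pos["C5"] + 0.151 * (radial * np.cos(np.deg2rad(30)) - np.array([0, 0, 1]) * np.sin(np.deg2rad(30)))
    names.append("C6")
    coords.append(c6)
    names.append("H61")
    coords.append(c6 + np.array([0.0, 0.0, -ch]))
    names.append("H62")
    coords.append(c6 + ch * np.array([radial[0] * 0.6, radial[1] * 0.6, -0.8]) / np.linalg.norm([radial[0] * 0.6, radial[1] * 0.6, -0.8]))
    # O3 hydroxyl oxygen, equatorial on C3
    radial3 = np.array([ring_pos["C3"][0], ring_pos["C3"][1], 0.0])
    radial3 /= np.linalg.norm(radial3)
    names.append("O3")
    coords.append(ring_pos["C3"] + 0.143 * (radial3 * np.cos(np.deg2rad(30)) - np.array([0, 0, 1]) * np.sin(np.deg2rad(30))))
    return names, np.stack(coords)


def _rot_x(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    return np.array([[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]])


def _hexagon(center: np.ndarray, radius: float = 0.139, phase_deg: float = 0.0) -> np.ndarray:
    angles = np.deg2rad(phase_deg + 60.0 * np.arange(6))
    return center + radius * np.stack([np.cos(angles), np.sin(angles), np.zeros(6)], axis=1)


# ---------------------------------------------------------------------------
# Toy system


@dataclass
class ToySystem:
    """A toy reference complex with full topology and emission poses."""

    reference: ReferenceComplex
    atom_ids: list[AtomID]  # protein (H included) then ligand atoms
    protein_coords: np.ndarray  # reference protein coords incl. hydrogens
    bound_ligand: np.ndarray  # ligand coords in the specific pose
    nonspecific_ligand: np.ndarray  # ligand coords in the off-site pose
    ligand_template: np.ndarray  # ligand coords centred for unbound placement
    moieties: list[MoietySpec]
    binding_sidechain_indices: np.ndarray  # atoms displaced by the open toggle
    box_edge: float

    @property
    def n_protein_atoms(self) -> int:
        return len(self.protein_coords)

    @property
    def ligand_atom_indices(self) -> np.ndarray:
        return np.arange(self.n_protein_atoms, len(self.atom_ids))


def _moiety_roles(n_moieties: int) -> list[str]:
    return {
        1: ["reducing"],
        2: ["nonreducing", "reducing"],
        3: ["reducing", "internal", "nonreducing"],
    }[n_moieties]


def build_toy_system(
    n_subsites: int = 3, n_moieties: int = 1, box_edge: float = 4.1
) -> ToySystem:
    """Build the toy scaffold, subsite references and ligand poses.

    The scaffold holds 16 pseudo-residues (numbers 17-32) with backbone
    N/H/CA/C/O, tryptophan-like indole rings on residues 21 and 23, a
    tyrosine-like ring on residue 30 and a serine-like hydroxyl on residue
    19.  Subsite reference poses sit ``STACK_HEIGHT`` above the ring plane at
    ``SUBSITE_SPACING`` intervals; the nonspecific pose hangs below the
    backbone on the opposite face, where only main-chain N-H / C=O partners
    are in reach.  Everything is finally translated so the scaffold centroid
    sits at the box centre.
    """
    if not 1 <= n_moieties <= 3:
        raise ValueError("n_moieties must be 1, 2 or 3")
    if n_subsites != 3:
        raise ValueError("the toy scaffold provides exactly 3 subsites")
    if box_edge < 4.0:
        raise ValueError("box_edge must be >= 4 nm to hold scaffold and ligand")

    protein_ids: list[AtomID] = []
    protein_coords: list[np.ndarray] = []
    sidechain_idx: list[int] = []

    def add(resname: str, resid: int, name: str, pos: np.ndarray, sidechain: bool = False) -> None:
        if sidechain and resid in (19, 21, 23, 30) and not is_hydrogen(name):
            sidechain_idx.append(len(protein_ids))
        protein_ids.append(AtomID(resname, resid, name))
        protein_coords.append(np.asarray(pos, dtype=float))

    resnames = {19: "SER", 21: "TRP", 23: "TRP", 30: "TYR"}
    for resid in range(17, 33):
        resname = resnames.get(resid, "GLY")
        x = -1.4 + 0.22 * (resid - 17)
        y = 0.25 if resid % 2 == 0 else -0.25
        n_pos = np.array([x, y, -0.5])
        add(resname, resid, "N", n_pos)
        add(resname, resid, "H", n_pos + [0.0, 0.0, -0.101])
        add(resname, resid, "CA", n_pos + [0.11, 0.05, 0.04])
        add(resname, resid, "C", n_pos + [0.22, -0.02, 0.0])
        add(resname, resid, "O", n_pos + [0.24, -0.02, -0.122])

    # Trp rings: 6-ring hexagon in the z=0 plane, fused 5-ring sharing the
    # CD2-CE2 edge; centred under the red (res 23) and green (res 21) subsites.
    for resid, center_x in ((23, 0.0), (21, SUBSITE_SPACING)):
        center = np.array([center_x, 0.0, 0.0])
        hexagon = _hexagon(center)
        for name, pos in zip(("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"), hexagon):
            add("TRP", resid, name, pos, sidechain=True)
        edge_mid = 0.5 * (hexagon[0] + hexagon[1])
        out = edge_mid - center
        out /= np.linalg.norm(out)
        perp = np.cross([0.0, 0.0, 1.0], out)
        add("TRP", resid, "CG", edge_mid + 0.19 * out + 0.11 * perp, sidechain=True)
        add("TRP", resid, "CD1", edge_mid + 0.30 * out, sidechain=True)
        add("TRP", resid, "NE1", edge_mid + 0.19 * out - 0.11 * perp, sidechain=True)

    # Tyr ring off to the side of the red subsite, plus its hydroxyl
    tyr_center = np.array([-0.55, 0.42, 0.05])
    for name, pos in zip(("CG", "CD1", "CE1", "CZ", "CE2", "CD2"), _hexagon(tyr_center)):
        add("TYR", 30, name, pos, sidechain=True)
    oh = tyr_center + np.array([0.0, 0.0, 0.136 + 0.139])
    add("TYR", 30, "OH", tyr_center + np.array([0.25, 0.0, 0.10]), sidechain=True)
    add("TYR", 30, "HH", tyr_center + np.array([0.30, 0.0, 0.18]))

    # ligand template: n moieties chained along x, alternate moieties flipped
    # about x (the beta(1->4) alternation), moiety 0 with its even face down
    names1, template1 = pyranose_template()
    lig_names: list[str] = []
    lig_resids: list[int] = []
    template_parts = []
    for j in range(n_moieties):
        part = template1 @ _rot_x(180.0 * (j % 2)).T
        part = part + np.array([SUBSITE_SPACING * j, 0.0, 0.0])
        template_parts.append(part)
        lig_names.extend(names1)
        lig_resids.extend([LIGAND_FIRST_RESID + j] * len(names1))
    ligand_template = np.vstack(template_parts)
    ligand_ids = [AtomID(LIGAND_RESNAME, r, n) for r, n in zip(lig_resids, lig_names)]

    # subsite reference poses: a full 3-moiety chain stacked above the rings
    _, t1 = pyranose_template()
    subsite_refs: dict[str, np.ndarray] = {}
    name_index = {n: i for i, n in enumerate(names1)}
    ring_sel = [name_index[n] for n in CANONICAL_MOIETY_ATOMS]
    for j, label in enumerate(SUBSITE_LABELS):
        pose = t1 @ _rot_x(180.0 * (j % 2)).T + np.array(
            [SUBSITE_SPACING * j, 0.0, STACK_HEIGHT]
        )
        subsite_refs[label] = pose[ring_sel]

    bound_ligand = ligand_template + np.array([0.0, 0.0, STACK_HEIGHT])

    # Ser19 hydroxyl donor aimed at the red moiety's O3 acceptor
    red_o3 = (t1 + np.array([0.0, 0.0, STACK_HEIGHT]))[name_index["O3"]]
    d = np.array([0.45, 0.75, 0.45])
    d /= np.linalg.norm(d)
    og = red_o3 + 0.29 * d
    add("SER", 19, "CB", og + 0.15 * d, sidechain=True)
    add("SER", 19, "OG", og, sidechain=True)
    add("SER", 19, "HG", og - 0.10 * d)

    # nonspecific pose: below the backbone, ring plane vertical, an oxygen
    # placed straight under a backbone amide for a linear N-H...O bond
    nonspec = ligand_template @ _rot_x(90.0).T
    donor_n = np.array([-1.4 + 0.22 * 9, 0.25, -0.5])  # residue 26 amide N
    o5_now = nonspec[name_index["O5"]]
    nonspec = nonspec + (donor_n + np.array([0.0, 0.0, -0.29]) - o5_now)

    # group atoms by residue (stable), matching PDB reader conventions
    order = np.argsort([a.resid for a in protein_ids], kind="stable")
    inverse = np.empty(len(order), dtype=int)
    inverse[order] = np.arange(len(order))
    protein_ids = [protein_ids[i] for i in order]
    protein_coords = [protein_coords[i] for i in order]
    sidechain_idx = sorted(int(inverse[i]) for i in sidechain_idx)

    protein_arr = np.stack(protein_coords)
    heavy_mask = np.array([not is_hydrogen(a.name) for a in protein_ids])
    centroid = protein_arr[heavy_mask].mean(axis=0)
    shift = np.full(3, box_edge / 2.0) - centroid
    protein_arr += shift
    bound_ligand += shift
    nonspec += shift
    for label in subsite_refs:
        subsite_refs[label] = subsite_refs[label] + shift

    # overlap guard on all reference heavy atoms
    ref_heavy = np.vstack([protein_arr[heavy_mask], bound_ligand])
    deltas = ref_heavy[:, None] - ref_heavy[None, :]
    dist = np.sqrt((deltas**2).sum(-1)) + np.eye(len(ref_heavy)) * 10
    if dist.min() < _MIN_HEAVY_DISTANCE:
        raise ValueError(f"geometric overlap in toy system (min distance {dist.min():.3f} nm)")

    reference = ReferenceComplex(
        protein_coords=protein_arr[heavy_mask],
        protein_atom_ids=[a for a, h in zip(protein_ids, heavy_mask) if h],
        subsite_refs=subsite_refs,
        source_label="toy scaffold",
    )
    moieties = [
        MoietySpec(residue_number=LIGAND_FIRST_RESID + j, role=role)
        for j, role in enumerate(_moiety_roles(n_moieties))
    ]
    return ToySystem(
        reference=reference,
        atom_ids=protein_ids + ligand_ids,
        protein_coords=protein_arr,
        bound_ligand=bound_ligand,
        nonspecific_ligand=nonspec,
        ligand_template=ligand_template - ligand_template.mean(axis=0),
        moieties=moieties,
        binding_sidechain_indices=np.array(sorted(sidechain_idx), dtype=int),
        box_edge=box_edge,
    )


# ---------------------------------------------------------------------------
# Kinetic scheme


@dataclass
class KineticScheme:
    """CTMC over binding states with state-conditioned emission rules.

    states must contain ``unbound`` and ``specific``; any number of
    ``nonspecific*`` states in between.  ``rates[(a, b)]`` is the transition
    rate a->b in 1/ns.  sigma_b is the positional noise (nm) applied to the
    specific/nonspecific poses.
    """

    states: tuple[str, ...]
    rates: dict[tuple[str, str], float]
    sigma_b: float = 0.05

    def __post_init__(self) -> None:
        if "specific" not in self.states or "unbound" not in self.states:
            raise ValueError("scheme needs 'unbound' and 'specific' states")
        for (a, b), rate in self.rates.items():
            if a not in self.states or b not in self.states or a == b:
                raise ValueError(f"bad transition {(a, b)}")
            if rate < 0:
                raise ValueError("rates must be non-negative")

    def generator(self) -> np.ndarray:
        """Generator matrix Q (rows sum to zero)."""
        n = len(self.states)
        index = {s: i for i, s in enumerate(self.states)}
        Q = np.zeros((n, n))
        for (a, b), rate in self.rates.items():
            Q[index[a], index[b]] = rate
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q


def two_state_scheme(k_on: float = 0.045, k_off: float = 0.03, sigma_b: float = 0.05) -> KineticScheme:
    """unbound <-> specific.  Defaults give stationary specific occupancy
    k_on/(k_on+k_off) = 0.6 with dwell times (22, 33 ns) long against the
    1 ns frame interval yet short enough for ~50 binding events per 2000 ns."""
    return KineticScheme(
        states=("unbound", "specific"),
        rates={("unbound", "specific"): k_on, ("specific", "unbound"): k_off},
        sigma_b=sigma_b,
    )


def three_state_scheme(
    k_adsorb: float = 0.01,
    k_desorb: float = 0.004,
    k_dock: float = 0.003,
    k_undock: float = 0.0005,
    sigma_b: float = 0.05,
) -> KineticScheme:
    """unbound <-> nonspecific <-> specific, at the slow event scale of a
    microsecond simulation (dwells of hundreds of ns)."""
    return KineticScheme(
        states=("unbound", "nonspecific", "specific"),
        rates={
            ("unbound", "nonspecific"): k_adsorb,
            ("nonspecific", "unbound"): k_desorb,
            ("nonspecific", "specific"): k_dock,
            ("specific", "nonspecific"): k_undock,
        },
        sigma_b=sigma_b,
    )


def stationary_distribution(Q: np.ndarray, strict: bool = True) -> np.ndarray:
    """Stationary distribution of a generator matrix.

    With ``strict`` (default) the chain must be irreducible (strongly
    connected transition graph); otherwise any generator with a unique
    invariant distribution is accepted (e.g. a chain with one absorbing
    state, whose invariant law is the point mass there).
    """
    from scipy.sparse.csgraph import connected_components

    adjacency = (Q > 0).astype(int)
    n_comp, _ = connected_components(adjacency, directed=True, connection="strong")
    if strict and n_comp != 1:
        raise ValueError("rate matrix is reducible; no unique stationary distribution")
    null = _null_space(Q.T)
    if null.shape[1] != 1:
        raise ValueError("generator has no unique invariant distribution")
    pi = np.abs(null[:, 0])
    return pi / pi.sum()


def _null_space(A: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    _, s, vt = np.linalg.svd(A)
    rank = int(np.sum(s > tol * max(s[0], 1.0))) if len(s) else 0
    return vt[rank:].T


def stationary_occupancy(scheme: KineticScheme) -> float:
    """Stationary probability of the specific state."""
    pi = stationary_distribution(scheme.generator())
    return float(pi[scheme.states.index("specific")])


# ---------------------------------------------------------------------------
# Trajectory simulation


@dataclass
class ConformationToggle:
    """Two-state (closed/open) toggle of the binding-residue sidechains.

    In the open state the sidechain heavy atoms of the key binding residues
    are rigidly displaced by ``displacement`` nm; when ``gates_binding`` the
    ligand can only enter the specific state while the toggle is closed —
    the conformational-selection scenario.
    """

    k_open: float = 0.02
    k_close: float = 0.02
    displacement: tuple[float, float, float] = (0.30, 0.25, 0.28)
    gates_binding: bool = False


@dataclass
class GroundTruth:
    frame_states: np.ndarray  # per-frame true ligand state label
    switch_times: np.ndarray  # exact CTMC ligand-state switch times (ns)
    switch_to: np.ndarray  # state entered at each switch
    occupancy_specific: float  # analytic stationary specific occupancy
    conf_frame_states: np.ndarray | None = None  # closed/open per frame

    def to_json(self) -> str:
        payload = {
            "frame_states": self.frame_states.tolist(),
            "switch_times": self.switch_times.tolist(),
            "switch_to": self.switch_to.tolist(),
            "occupancy_specific": self.occupancy_specific,
        }
        if self.conf_frame_states is not None:
            payload["conf_frame_states"] = self.conf_frame_states.tolist()
        return json.dumps(payload)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det +1)."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def _joint_chain(
    scheme: KineticScheme, toggle: ConformationToggle | None
) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Joint (ligand state, conf state) chain and its generator matrix."""
    conf_states = ("closed", "open") if toggle is not None else ("closed",)
    states = [(s, c) for s in scheme.states for c in conf_states]
    index = {s: i for i, s in enumerate(states)}
    Q = np.zeros((len(states), len(states)))
    for (a, b), rate in scheme.rates.items():
        for c in conf_states:
            if (
                toggle is not None
                and toggle.gates_binding
                and b == "specific"
                and c == "open"
            ):
                continue
            Q[index[(a, c)], index[(b, c)]] = rate
    if toggle is not None:
        for s in scheme.states:
            Q[index[(s, "closed")], index[(s, "open")]] = toggle.k_open
            Q[index[(s, "open")], index[(s, "closed")]] = toggle.k_close
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return states, Q


def _gillespie(
    states: list, Q: np.ndarray, start: int, duration: float, rng: np.random.Generator
) -> tuple[list[float], list[int]]:
    """Exact CTMC path: (switch times, state indices after each switch)."""
    t = 0.0
    current = start
    times: list[float] = []
    path: list[int] = []
    while True:
        exit_rate = -Q[current, current]
        if exit_rate <= 0:
            break  # absorbing state: allowed, path simply ends
        t += rng.exponential(1.0 / exit_rate)
        if t >= duration:
            break
        probs = np.clip(Q[current].copy(), 0, None)
        probs[current] = 0.0
        probs /= probs.sum()
        current = int(rng.choice(len(states), p=probs))
        times.append(t)
        path.append(current)
    return times, path


def simulate_binding_trajectory(
    system: ToySystem,
    scheme: KineticScheme,
    duration: float = 2000.0,
    frame_interval: float = 1.0,
    seed: int | None = None,
    start_state: str = "unbound",
    toggle: ConformationToggle | None = None,
    protein_noise: float = 0.01,
    exclusion_radius: float = 2.2,
    scramble_ligand_images: bool = True,
) -> tuple[Trajectory, GroundTruth]:
    """Simulate a labelled binding trajectory.

    The ligand state follows the scheme's CTMC (jointly with the optional
    conformational toggle); per frame the ligand is emitted at the pose of
    its current state with Gaussian noise sigma_b, the protein gets per-atom
    noise, and the whole frame receives a random rigid rotation/translation
    (what a raw MD frame looks like before fitting).  When
    ``scramble_ligand_images`` is on, the ligand is additionally shifted by a
    random integer multiple of the box vectors, which downstream re-imaging
    must undo.  Deterministic given the seed.
    """
    if duration < frame_interval:
        raise ValueError("duration must cover at least one frame interval")
    rng = np.random.default_rng(seed)
    joint_states, Q = _joint_chain(scheme, toggle)
    start = joint_states.index((start_state, "closed"))
    switch_times, path = _gillespie(joint_states, Q, start, duration, rng)

    n_frames = int(np.floor(duration / frame_interval))
    times = np.arange(n_frames) * frame_interval
    # state at each frame time (right-continuous path)
    frame_joint = np.empty(n_frames, dtype=object)
    seq = [start] + path
    edges = np.array(switch_times)
    which = np.searchsorted(edges, times, side="right")
    for f in range(n_frames):
        frame_joint[f] = joint_states[seq[which[f]]]

    try:
        pi = stationary_distribution(Q, strict=False)
        occupancy = float(sum(p for s, p in zip(joint_states, pi) if s[0] == "specific"))
    except ValueError:
        warnings.warn("scheme has no unique invariant law; occupancy reported as nan", stacklevel=2)
        occupancy = float("nan")

    lig_idx = system.ligand_atom_indices
    n_lig = len(lig_idx)
    box_center = np.full(3, system.box_edge / 2.0)
    coords = np.empty((n_frames, len(system.atom_ids), 3))
    box = np.full((n_frames, 3), system.box_edge)

    ligand_switch_times: list[float] = []
    ligand_switch_to: list[str] = []
    prev = joint_states[start][0]
    for t, s in zip(switch_times, path):
        lig_state = joint_states[s][0]
        if lig_state != prev:
            ligand_switch_times.append(t)
            ligand_switch_to.append(lig_state)
            prev = lig_state

    for f in range(n_frames):
        lig_state, conf_state = frame_joint[f]
        protein = system.protein_coords + rng.normal(0.0, protein_noise, size=system.protein_coords.shape)
        if conf_state == "open":
            protein[system.binding_sidechain_indices] += np.asarray(
                toggle.displacement if toggle else (0, 0, 0)
            )
        if lig_state == "specific":
            ligand = system.bound_ligand + rng.normal(0.0, scheme.sigma_b, size=(n_lig, 3))
        elif lig_state.startswith("nonspecific"):
            ligand = system.nonspecific_ligand + rng.normal(0.0, scheme.sigma_b, size=(n_lig, 3))
        else:  # unbound: uniform placement outside the protein exclusion zone
            while True:
                center = rng.uniform(0.0, system.box_edge, size=3)
                if np.linalg.norm(center - box_center) >= exclusion_radius:
                    break
            ligand = system.ligand_template @ _random_rotation(rng).T + center
        frame = np.vstack([protein, ligand])
        # raw-MD appearance: a random global rigid motion about the box centre
        R = _random_rotation(rng)
        frame = (frame - box_center) @ R.T + box_center + rng.uniform(-0.3, 0.3, size=3)
        if scramble_ligand_images:
            frame[lig_idx] += rng.integers(-1, 2, size=3) * system.box_edge
        coords[f] = frame

    trajectory = Trajectory(coords=coords, times=times, box=box, atom_ids=list(system.atom_ids))
    truth = GroundTruth(
        frame_states=np.array([frame_joint[f][0] for f in range(n_frames)], dtype=object).astype(str),
        switch_times=np.array(ligand_switch_times),
        switch_to=np.array(ligand_switch_to, dtype=object).astype(str),
        occupancy_specific=occupancy,
        conf_frame_states=(
            np.array([frame_joint[f][1] for f in range(n_frames)], dtype=object).astype(str)
            if toggle is not None
            else None
        ),
    )
    return trajectory, truth


# ---------------------------------------------------------------------------
# Fixture writers


def write_toy_pdb(system: ToySystem, path: str | Path) -> None:
    """Write the reference scaffold plus bound ligand as a one-model PDB (A)."""
    lig_idx = system.ligand_atom_indices
    with open(path, "w") as handle:
        handle.write("MODEL        1\n")
        serial = 1
        for i, aid in enumerate(system.atom_ids):
            if i < system.n_protein_atoms:
                pos = system.protein_coords[i] * ANGSTROM_PER_NM
                record, chain = "ATOM  ", "A"
            else:
                pos = system.bound_ligand[i - system.n_protein_atoms] * ANGSTROM_PER_NM
                record, chain = "HETATM", "B"
            element = "H" if is_hydrogen(aid.name) else aid.name[0]
            handle.write(
                f"{record}{serial:>5} {aid.name:<4}{aid.resname:>4} {chain}"
                f"{aid.resid:>4}    {pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
                f"  1.00  0.00          {element:>2}\n"
            )
            serial += 1
        handle.write("ENDMDL\nEND\n")


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(truth.to_json())


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        frame_states=np.array(payload["frame_states"], dtype=object).astype(str),
        switch_times=np.array(payload["switch_times"], dtype=float),
        switch_to=np.array(payload["switch_to"], dtype=object).astype(str),
        occupancy_specific=float(payload["occupancy_specific"]),
        conf_frame_states=(
            np.array(payload["conf_frame_states"], dtype=object).astype(str)
            if "conf_frame_states" in payload
            else None
        ),
    )
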