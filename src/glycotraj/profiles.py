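"""RMSD observables of a binding trajectory.

Two profile families:

* per-moiety, per-subsite ligand RMSD — the trajectory is globally fitted on
  protein heavy atoms once; each monosaccharide moiety's seven ring atoms
  (C1..C6, O5) are then compared against each subsite's reference pose with no
  re-fitting, so large values are real distances from the subsite;
* binding-residue RMSD versus the initial structure — per frame the whole
  protein is fitted, then RMSD is taken over the pooled heavy atoms of the key
  binding residues (default Ser19/Trp21/Trp23/Tyr30).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import superpose
from .system_model import (
    AtomID,
    MoietySpec,
    ReferenceComplex,
    Trajectory,
    protein_heavy_selection,
    residues_heavy_selection,
    select_moiety,
)


@dataclass
class RMSDProfile:
    """Per-frame RMSD time series (nm) keyed by what was measured."""

    times: np.ndarray
    values: np.ndarray
    key: tuple[str, str]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(self.values < 0):
            raise ValueError("RMSD values must be non-negative")


def moiety_subsite_rmsd(
    fitted: Trajectory, moiety: MoietySpec, reference: ReferenceComplex
) -> dict[str, RMSDProfile]:
    """RMSD of one moiety's 7 ring atoms against every subsite reference.

    ``fitted`` must already be superposed on the reference protein
    (superpose.fit_frames); this function does no fitting of its own.
    """
    sel = select_moiety(fitted.atom_ids, moiety)
    moiety_coords = fitted.coords[:, sel.indices, :]
    out: dict[str, RMSDProfile] = {}
    for label, ref in reference.subsite_refs.items():
        values = superpose.rmsd_frames(moiety_coords, ref)
        out[label] = RMSDProfile(times=fitted.times, values=values, key=(moiety.role, label))
    return out


def binding_residue_rmsd(
    trajectory: Trajectory,
    binding_residue_ids=None,
    reference_frame: np.ndarray | None = None,
) -> RMSDProfile:
    """Binding-residue RMSD relative to the initial structure.

    Per frame the protein heavy atoms are fitted onto ``reference_frame``
    (default: the first frame's protein heavy atoms), then RMSD is computed
    over the pooled heavy atoms of ``binding_residue_ids``.
    """
    protein = protein_heavy_selection(trajectory.atom_ids)
    if binding_residue_ids is None:
        from .system_model import DEFAULT_BINDING_RESIDUES

        binding_residue_ids = DEFAULT_BINDING_RESIDUES
    if not set(binding_residue_ids):
        raise ValueError("binding residue list must be non-empty")
    residues = residues_heavy_selection(trajectory.atom_ids, binding_residue_ids)
    prot_ref = (
        trajectory.coords[0, protein.indices]
        if reference_frame is None
        else np.asarray(reference_frame, dtype=float)
    )
    if prot_ref.shape != (len(protein), 3):
        raise ValueError("reference_frame must match protein heavy-atom count")
    # residue reference taken from the same structure the fit targets
    if reference_frame is None:
        res_ref = trajectory.coords[0, residues.indices]
    else:
        # map residue atoms through their position within the protein selection
        pos_in_protein = {int(i): k for k, i in enumerate(protein.indices)}
        res_ref = prot_ref[[pos_in_protein[int(i)] for i in residues.indices]]
    values = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        transform = superpose.kabsch_fit(trajectory.coords[f, protein.indices], prot_ref)
        values[f] = superpose.rmsd(transform.apply(trajectory.coords[f, residues.indices]), res_ref)
    return RMSDProfile(times=trajectory.times, values=values, key=("binding_residues", "initial"))


def profiles_to_frame(profiles: dict[str, RMSDProfile], stride: int = 1) -> pd.DataFrame:
    """Long-format table of a subsite profile set (time_ns, value_nm, moiety, subsite)."""
    rows = []
    for label, profile in profiles.items():
        moiety, subsite = profile.key
        rows.append(
            pd.DataFrame(
                {
                    "time_ns": profile.times[::stride],
                    "value_nm": profile.values[::stride],
                    "moiety": moiety,
                    "subsite": subsite,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_profiles_csv(profiles: dict[str, RMSDProfile], path: str | Path, stride: int = 1) -> None:
    profiles_to_frame(profiles, stride=stride).to_csv(path, index=False)
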