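import numpy as np
import pytest

from glycotraj import synthetic_data
from glycotraj.system_model import Trajectory


@pytest.fixture(scope="session")
def toy_system():
    """Single-moiety toy complex at the default 4.1 nm (~24 mM) box."""
    return synthetic_data.build_toy_system(n_moieties=1)


@pytest.fixture(scope="session")
def toy_system3():
    """Trisaccharide-like toy complex (reducing/internal/nonreducing)."""
    return synthetic_data.build_toy_system(n_moieties=3)


@pytest.fixture(scope="session")
def short_trajectory(toy_system):
    """A short labelled two-state trajectory (200 ns, 1 ns frames)."""
    trajectory, truth = synthetic_data.simulate_binding_trajectory(
        toy_system, synthetic_data.two_state_scheme(), duration=200.0, seed=42
    )
    return trajectory, truth


def static_trajectory(system, ligand_coords, n_frames=3, box_edge=None):
    """Trajectory with the protein at its reference and a fixed ligand pose."""
    edge = box_edge if box_edge is not None else system.box_edge
    frame = np.vstack([system.protein_coords, ligand_coords])
    coords = np.repeat(frame[None], n_frames, axis=0)
    return Trajectory(
        coords=coords,
        times=np.arange(n_frames, dtype=float),
        box=np.full((n_frames, 3), edge),
        atom_ids=list(system.atom_ids),
    )
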