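#!/usr/bin/env python
"""Generate the synthetic study systems and trajectories used downstream.

Writes, per ligand size (mono/di/trisaccharide), a toy reference PDB plus two
2000 ns replicas of the slow three-state scheme (unbound <-> nonspecific <->
specific, dwells of hundreds of ns — the event scale of a microsecond
simulation) as plain-text .xyzt trajectories with exact ground truth, under
scratch/synthetic/.  Run this first; scripts 02-05 read these files.
"""

from pathlib import Path

from glycotraj import synthetic_data
from glycotraj.system_model import write_xyzt

OUT = Path("scratch/synthetic")
SEED = 2019


def main() -> None:
    scheme = synthetic_data.three_state_scheme()
    for n_moieties, tag in ((1, "glcnac1"), (2, "glcnac2"), (3, "glcnac3")):
        system = synthetic_data.build_toy_system(n_moieties=n_moieties)
        out = OUT / tag
        out.mkdir(parents=True, exist_ok=True)
        synthetic_data.write_toy_pdb(system, out / "reference.pdb")
        for replica in (1, 2):
            trajectory, truth = synthetic_data.simulate_binding_trajectory(
                system, scheme, duration=2000.0, seed=SEED + 10 * n_moieties + replica
            )
            write_xyzt(trajectory, out / f"replica{replica}.xyzt")
            synthetic_data.write_ground_truth(truth, out / f"replica{replica}_truth.json")
            n_bind = sum(1 for s in truth.switch_to if s == "specific")
            print(
                f"{tag} replica {replica}: {len(truth.switch_times)} state switches, "
                f"{n_bind} specific-binding events, "
                f"stationary specific occupancy {truth.occupancy_specific:.3f}"
            )
    print(f"\nwrote fixtures under {OUT}/")


if __name__ == "__main__":
    main()
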