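# glycotraj

Subsite-resolved analysis of protein–carbohydrate binding trajectories.

Unbiased MD simulations can watch a sugar find its binding site ("docking by
dynamics"): a hevein domain (HEV32) with three saccharide subsites and a
GlcNAc mono-, di- or trisaccharide diffusing around it. Deciding *when* the
ligand is specifically bound, nonspecifically adhering or free — and what
that implies thermodynamically — takes a reproducible analysis chain, which
this package provides:

* **RMSD profiling** — Kabsch superposition of every frame onto the
  reference protein heavy atoms (with periodic re-imaging of the ligand),
  then per-moiety RMSD of the seven pyranose atoms C1–C6,O5 against each
  subsite's reference pose, plus binding-residue RMSD versus the initial
  structure;
* **states and events** — three-state classification
  (specific ≤ 0.5 nm, unbound ≥ 4 nm, nonspecific between, with hysteresis
  and dwell filtering) and binding/unbinding event detection;
* **equilibrium** — one protein + one ligand in a box of volume V means
  equal totals C = 1/(N_A V); the bound fraction f then gives the
  dissociation constant Kd = C(1−f)²/f, inverted by
  f = [(2C+Kd) − √((2C+Kd)² − 4C²)]/(2C), with a block-bootstrap interval;
* **interaction fingerprints** — geometric hydrogen-bond and CH/π
  detectors, pyranose stacking-face assignment (C1/C3/C5 vs C2/C4/C6), and
  a per-interval specific/nonspecific signature (nonspecific adhesion is
  backbone-H-bond dominated with no CH/π; the specific pose stacks CH
  bonds on Trp/Tyr ring faces);
* **conformational selection** — the fraction of pre-binding frames in
  which the binding residues already sit in the binding-competent
  conformation;
* **a synthetic generator** — a toy scaffold with three subsites and a
  CTMC-driven ligand whose exact state path, switch times and stationary
  occupancy are known, so every stage is validated against analytic ground
  truth without downloading anything.

## Worked example

```python
from glycotraj import states, synthetic_data, equilibrium
from glycotraj.pipeline import analyze_trajectory

system = synthetic_data.build_toy_system(n_moieties=1)       # 4.1 nm box
scheme = synthetic_data.two_state_scheme()                   # occupancy 0.6
trajectory, truth = synthetic_data.simulate_binding_trajectory(
    system, scheme, duration=2000.0, seed=0)
result = analyze_trajectory(
    trajectory, system.reference, system.moieties,
    states.StateThresholds(min_dwell=0.0), compute_interactions=False)

conc = equilibrium.box_concentration(system.box_edge**3)
print(f"C = {conc*1e3:.2f} mmol/l")
print(f"bound fraction {result.bound_fraction:.3f} (truth {truth.occupancy_specific})")
print(f"Kd = {equilibrium.kd_from_fraction(result.bound_fraction, conc)*1e3:.2f} mM")
```

prints

```
C = 24.09 mmol/l
bound fraction 0.518 (truth 0.6)
Kd = 10.81 mM
```

i.e. a single copy of each species in the 4.1 nm box is ~24 mmol/l, and a
single 2000 ns replica estimates the stationary bound fraction with
noticeable sampling noise (0.52 vs the true 0.6), which the quadratic
Kd = C(1−f)²/f amplifies — exactly why the pipeline pools replicas and
attaches a block-bootstrap interval. Pooling ten such replicas
(`analysis/04_equilibrium.py`) recovers f = 0.609 and
Kd = 6.05 mM [4.85, 7.31] against the analytic 6.42 mM; the same script
prints the desk arithmetic at this concentration: 60% bound ↔ 6.4 mM,
30% ↔ 39 mM, and 94% saturation at an experimental Kd of 100 μM.

The numbered scripts under `analysis/` run the full narrative: simulate
mono/di/trisaccharide replicas (`01`), RMSD profiles per true kinetic state
(`02`), event detection versus exact switch times (`03`), Kd with bootstrap
interval (`04`), interaction fingerprints and stacking faces (`05`), and the
conformational-selection statistic (`06`). Outputs land in
`results/analysis/`; trajectories in `scratch/`.

There is also a CLI:

```
glycotraj simulate --out scratch/demo --scheme three_state --seed 1
glycotraj analyze --config run.yaml
glycotraj report --run-dir results/run
```

`analyze` accepts `mode: synthetic` or `mode: real` configs; real mode reads
a PDB reference (model selectable) and any MDAnalysis-supported trajectory
format, and needs an explicit `subsite_map` from subsite labels to ligand
residue numbers (see `data/real/README.md`).

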