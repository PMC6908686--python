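# Methods

## What the pipeline computes

The package analyses molecular-dynamics trajectories of a small
carbohydrate-binding protein (a hevein domain with three saccharide
subsites, labelled red/green/blue) in the presence of a GlcNAc mono-, di- or
trisaccharide, and decides when and how the ligand is bound. All lengths are
nanometres and all times nanoseconds throughout; PDB Angstroms and
MDAnalysis picoseconds are converted at the boundary.

The chain of observables is:

1. **Superposition.** Every frame is fitted onto the non-hydrogen protein
   atoms of a reference complex by an unweighted SVD Kabsch fit with an
   explicit determinant correction (reflections are never returned;
   singular-value degeneracy tolerance 1e-12). Before fitting, the ligand is
   made whole across periodic boundaries and shifted to the periodic image
   nearest the protein centroid, frame by frame. Without this re-imaging,
   box crossings fabricate RMSD jumps; with it, large RMSD values remain
   meaningful because the RMSD is measured to a subsite, not to the protein
   centroid. Only orthorhombic boxes are supported; triclinic input is
   rejected.

2. **Subsite RMSD profiles.** Per monosaccharide moiety (seven atoms,
   always in the canonical order C1,C2,C3,C4,C5,C6,O5), the per-frame RMSD
   against each subsite's seven reference atoms, with no per-subsite
   re-fitting — the global protein fit is the only superposition. A separate
   profile tracks the pooled heavy atoms of the key binding residues
   (Ser19, Trp21, Trp23, Tyr30 by default) against the initial structure,
   after a per-frame whole-protein fit.

3. **States and events.** The per-frame minimum RMSD over subsites (and
   over moieties, for oligosaccharides) is thresholded into three states:
   `specific` at or below 0.5 nm, `unbound` at or above 4 nm, `nonspecific`
   between. The published narrative places nonspecific adhesion in a stable
   1–2 nm band and complete detachment above 4 nm, but never prints a
   numeric cutoff for specific binding; 0.5 nm was chosen because the
   specific pose sits near 0.1–0.2 nm, an order below the nonspecific band,
   and is configurable. A 0.1 nm hysteresis keeps the current state until
   the minimum crosses its boundary by at least that margin. State runs
   shorter than `min_dwell` (default 10 ns, appropriate for event scales of
   hundreds of ns; set to 0 for flicker-free synthetic data) are absorbed
   into their flanking runs, shortest first, into the shorter neighbour on
   ties. A transition into `specific` is a binding event, out of it an
   unbinding event; the event time is the first frame of the new run.

4. **Equilibrium.** One protein and one ligand copy in a box of volume V
   give equal totals C = 1/(N_A·V) — about 24 mmol/l for the ~69 nm³ boxes
   considered here. For the 1:1 complex with equal totals, Kd = C(1−f)²/f
   and the inverse is the smaller root of the saturation quadratic,
   f = [(2C+Kd) − sqrt((2C+Kd)² − 4C²)]/(2C). Because occupancy estimates
   from a handful of events are crude, a block bootstrap (blocks of 100 ns,
   longer than typical nonspecific dwells, preserving autocorrelation;
   percentile 2.5–97.5 interval) accompanies every Kd estimate. Resamples
   with bound fraction exactly 0 or 1 cannot be converted and are skipped
   with a reported count. The equal-totals model is hard-coded; titration
   with unequal totals is out of scope.

5. **Interaction fingerprints.** Hydrogen bonds use donor–acceptor distance
   ≤ 0.35 nm and D–H···A angle ≥ 120°; CH/π contacts use ring-carbon to
   ring-centroid distance ≤ 0.45 nm, in-plane offset ≤ 0.20 nm and C→H
   versus ring-normal angle ≤ 40°. These are conventional geometric
   criteria — the original analysis identified interactions visually — and
   all are configurable. Tryptophan contributes its five- and six-membered
   rings separately; a contact with either counts. Rings deviating more
   than 0.03 nm from their least-squares plane are flagged and skipped for
   that frame. When a pyranose carbon lacks an explicit hydrogen, candidate
   hydrogens are reconstructed at the two open tetrahedral positions and
   the records flagged. The stacking face of a pyranose on an aromatic ring
   is `odd` when more of C1/C3/C5 than of C2/C4/C6 carry qualifying CH/π
   contacts, `even` in the opposite case, `none` on ties. A bound interval
   is summarised as `nonspecific-like` when its hydrogen bonds are ≥ 80%
   backbone (N–H/C=O main chain) and CH/π contacts average < 0.5 per frame,
   `specific-like` when CH/π averages ≥ 0.5 per frame, otherwise
   `indeterminate`; the 0.8/0.5 cutoffs are this package's
   operationalisation of the two regimes described qualitatively in the
   literature and are printed with every report.

6. **Conformational selection.** For each binding event at time t, the
   fraction of frames in [t−50 ns, t) whose binding-residue RMSD is at or
   below 0.25 nm (the published profiles drop to ~0.2 nm before binding).
   This is a descriptive statistic, not a hypothesis test: values near 1
   mean the binding site already sat in its binding-competent conformation
   before ligand arrival.

## The synthetic generator

The generator exists so that every stage can be validated against exact
ground truth without downloading trajectories. It emulates the statistical
structure the analysis consumes, not the physics:

* a rigid pseudo-protein scaffold of 16 residues (numbers 17–32) with
  backbone N/H/CA/C/O, tryptophan-like indole rings on residues 21 and 23,
  a tyrosine-like ring on residue 30 and a serine-like hydroxyl on residue
  19 — about 90 heavy atoms;
* three subsite reference poses 0.37 nm above the ring plane at 0.52 nm
  spacing (the glycosidic repeat), with successive moieties flipped 180°
  so alternating stacking faces contact the rings, as in a β(1→4) chain;
* an idealised 4C1 pyranose with ring hydrogens whose odd (H1/H3/H5) and
  even (H2/H4/H6) faces are geometrically distinct;
* a continuous-time Markov chain over binding states, sampled exactly
  (Gillespie); emission teleports the ligand between state-conditioned
  poses: the subsite pose (specific), a pose hanging under the backbone on
  the far side of the scaffold where only main-chain partners are in reach
  (nonspecific), or a uniform placement at least 2.2 nm from the scaffold
  centroid (unbound), each with isotropic Gaussian noise of 0.05 nm. Each
  frame finally receives a uniformly random rigid rotation and translation
  (what a raw MD frame looks like before fitting) and, optionally, a random
  integer box shift of the ligand that downstream re-imaging must undo.

Default conditions mirror the study this pipeline targets: box edge 4.1 nm
(24 mmol/l single-copy concentration), 2000 ns at 1 ns frames, ligand
starting unbound.

Two stock schemes are provided. The *narrative* three-state scheme
(unbound↔nonspecific↔specific at 0.01/0.004/0.003/0.0005 per ns) produces a
handful of events per 2 μs at the hundreds-of-ns dwell scale of the real
simulations. The *recovery* two-state scheme (k_on = 0.045, k_off =
0.03 per ns; stationary specific occupancy 0.6) is deliberately faster: the
occupancy correlation time is 1/(k_on+k_off) ≈ 13 ns, so ten pooled 2000 ns
replicas estimate occupancy with a standard error of about
sqrt(2·0.24·13.3/20000) ≈ 0.018 — small enough that occupancy (±0.05) and
the occupancy-implied Kd (±25%, which by error propagation needs
|Δf| ≲ 0.037 at f = 0.6) are statistically identifiable, while dwell means
of 22/33 ns stay well above the 1 ns frame interval so individual switches
remain resolvable. Occupancy and Kd recovery are asserted on the pooled
estimate across replicas (a single 2000 ns replica at these rates has an
occupancy standard deviation near 0.07, so per-replica assertions would
fail for a correct implementation — the published analysis pools replicas
the same way). Recovery runs use `min_dwell = 0` because teleporting
emission with sub-threshold noise produces no flicker, and a positive
filter would only discard genuinely short dwells.

An optional two-state toggle (open/closed at 0.02/0.02 per ns) rigidly
displaces the binding-residue sidechains by ~0.48 nm in the open state;
with `gates_binding` the ligand can enter the specific state only while
closed, which reproduces the conformational-selection signature (mean
pre-binding closed fraction ≈ 0.8 versus ≈ 0.5 for the ungated control).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: diffusive approach paths (binding is
instantaneous between frames, so detected event times are exact to one
frame by construction, whereas real binding events are gradual and their
"time" is partly a matter of definition), intramolecular flexibility of
protein or ligand, partially formed poses at the specific/nonspecific
boundary, and solvent effects. Threshold placement on real data therefore
deserves more care than these tests require; event times recovered from
real trajectories may differ by tens of ns from published "approximately"
values (the published calls rest partly on visual inspection).

In a 4.1 nm box with nearest-image re-imaging, an unbound ligand sits at
most ~3.5 nm from the subsites most of the time, so unbound frames usually
classify as `nonspecific` rather than `unbound` under the 4 nm default.
This is immaterial for occupancy, events and Kd — all are defined by the
specific state alone — and the >4 nm regime is exercised with larger boxes
in the tests.

## Numerical choices

* Kabsch: singular-value tolerance 1e-12; collinear references rejected;
  rotations validated orthogonal within 1e-8 and proper within 1e-8.
* Time weighting of occupancy uses midpoint frame widths, so uniformly
  sampled series reduce exactly to frame counting.
* Event-merging ties: shortest offending run first, earlier on ties;
  absorbed into the shorter neighbour, earlier on ties.
* The stationary distribution of a rate matrix comes from the SVD null
  space of Qᵀ; strict mode requires strong connectivity, while the
  generator accepts any chain with a unique invariant law (e.g. an
  absorbing specific state) and reports NaN occupancy otherwise.
* Bootstrap seeds, simulation seeds and CLI seeds are explicit arguments
  everywhere; there is no global random state.

## Problem sizes

Test and acceptance runs use 2000 ns × 1 ns frames × 10 replicas for
recovery, 50 repeat experiments × 200 bootstrap resamples for interval
coverage, and 100 random frames for the detector-versus-oracle equality
checks. At the ~150-atom toy-system scale the full suite completes in a few
minutes on one core.

## Known limitations

* Real-data subsite assignment requires a user-supplied `subsite_map`
  (subsite label → ligand residue number): deposited topologies number
  ligand residues differently from the reference NMR structure, and the
  package does not guess. Guidance: red is the non-reducing-terminus site
  formed by Trp23/Tyr30/Ser19; green the Trp21/Glu1 site; blue the
  partial-stacking site next to Trp21.
* The published ~30 mg/ml mass concentration for the trisaccharide is not
  consistent with 24 mmol/l × 627.6 g/mol ≈ 15 mg/ml; `mass_concentration`
  reports the computed product.
* Whether the published binding-residue profiles were fitted on all protein
  heavy atoms or on the binding residues alone is not documented; this
  package fits globally (as the ligand protocol does) and documents it.
* Kinetic rate constants (k_on/k_off) are not estimated — only the
  occupancy-based Kd; Markov-state-model estimation is out of scope.
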