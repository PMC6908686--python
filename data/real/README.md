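# Real-mode inputs (not shipped)

The deposited solvent-stripped trajectories of the hevein-domain binding
simulations are published on Materials Cloud under
`10.24435/materialscloud:2019.0042/v2`; the reference NMR complex is PDB
entry 1T0W (model 1), which carries a bound (GlcNAc)3.

To enable the real-data integration test (`tests/test_acceptance.py::
test_real_data_reproduction`):

1. download the trajectories into this directory;
2. fetch `1t0w.pdb` from the PDB;
3. write one pipeline config per system — `glcnac1_replica1.yaml`,
   `glcnac2_replica1.yaml`, `glcnac3_replica2.yaml` — each a `mode: real`
   config (see README at the repository root) pointing at the respective
   trajectory and topology, with an explicit `subsite_map` from the
   red/green/blue subsites to the ligand residue numbers of your topology
   (red = the Trp23/Tyr30/Ser19 terminus site, green = the Trp21/Glu1 site);
4. create a `run.yaml` marker file (its presence switches the test on; it can
   be empty).

The test checks the first specific-binding times (about 720 / 175 / 444 ns),
the monosaccharide replica-1 bound fraction (about 60%) and the box
concentration (about 24 mmol/l).
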