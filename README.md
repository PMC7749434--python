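# kvgate

Hydrophobic-gating analysis for Kv7.4 (KCNQ4) potassium-channel trajectories.

Deletion of the pore residue S269 in Kv7.4 is associated with sensorineural
hearing loss. Structurally, the deletion constricts the ring formed by the
Ile and Phe side chains of adjacent S6 helices at the cavity entrance (I308 /
F311 in wild-type numbering, I307 / F310 in the ΔS269 mutant). Because this
region is apolar, a K⁺ ion must pass it with its hydration shell intact: with
a hydrated-ion radius of 3.5 Å and a Cδ van der Waals radius of 1.7 Å, the
minimal cross-monomer Cδ–Cδ opening for passage is

```
d_min = 2 · (r_hydrated + r_vdW) = 2 · (3.5 + 1.7) = 10.4 Å
```

`kvgate` implements the desk-scale version of this analysis for anyone
studying hydrophobic gating in tetrameric K⁺ channels:

* **Pore geometry** — cross-monomer Cα–Cα / Cδ–Cδ distances, adjacent-monomer
  Ile–Phe distances, Arg–Asp salt-bridge detection (minimum side-chain N–O,
  formed ⇔ mean < 3 Å), side-chain χ₁/χ₂ torsions with circular statistics,
  the S6 kink angle at P314, and water counts within 8 Å of the gate Ile.
* **Gating** — per-frame open/closed calls against the 10.4 Å criterion, and
  selectivity-filter/cavity occupancy states rendered in the standard
  notation (e.g. `S0-W-S2-W-S4-C` for a filter holding K⁺ at S0/S2/S4,
  water at S1/S3 and a trapped cavity ion).
* **Free energies** — umbrella-sampling reconstruction by a self-consistent
  WHAM solver: `G(z) = −kT ln P(z)` from harmonically biased windows
  (0.5 Å spacing, k = 10 kcal/mol/Å² protocol), anchored to the cytoplasmic
  region, with barrier readout in kcal/mol and kT and block-convergence
  diagnostics.
* **Synthetic data** — since no MD trajectories are distributed, a generator
  builds toy four-fold channel trajectories whose targeted observables have
  prescribed means ± SDs, and draws *exact* Boltzmann samples from known
  reference free-energy profiles, so every analysis stage is testable by
  parameter recovery.

## Worked example

The packaged comparison runs the whole pipeline on the WT and ΔS269 fixture
specifications (2000 frames each) plus a synthetic 3 kcal/mol umbrella set
for the mutant:

```python
from kvgate.pipeline import run_compare, format_summary

report = run_compare({
    "seed": 0, "n_frames": 2000,
    "pmf": {"mutant": {"synthetic": {"kind": "barrier", "height": 3.0,
                                     "center": -8.0, "width": 1.5,
                                     "n_per_window": 10000}}},
}, output_dir="out")
print(format_summary(report))
```

prints

```
Kv7.4 WT vs dS269 comparison
========================================
gate passage threshold: 10.4 A (Cd-Cd)
WT fraction open:      0.707
mutant fraction open:  0.000

cross Cd-Cd differences WT - mutant (A):
  A-C: 1.5
  B-D: 2.2
cross Ca-Ca differences WT - mutant (A):
  A-C: 2.8
  B-D: 3.1
adjacent I-F Ca-Ca mean difference: 0.5 A

salt bridges (mean N-O, formed = mean < cutoff):
  C-D: WT 3.2 A (open), mutant 2.6 A (formed)
  D-A: WT 5.6 A (open), mutant 2.7 A (formed)
  A-B: WT 6.3 A (open), mutant 2.9 A (formed)
  B-C: WT 5.5 A (open), mutant 2.6 A (formed)

cavity waters within 8 A of Ile: WT 50.0, mutant 30.0
occupancy census (top states):
  WT: S0-W-S2-W-S4: 1.00
  mutant: S0-W-S2-W-S4-C: 1.00

PMF barrier: 3.01 kcal/mol at z = -7.9 A (~5.1 kT)
```

Reading the output: both cross Cδ–Cδ means of the WT (10.8, 10.9 Å) sit above
the 10.4 Å passage threshold, so the WT gate is open in ~70 % of frames; the
mutant means (9.3, 8.7 Å) sit well below it and the gate is effectively never
open. The mutant's reconstructed free-energy profile shows the corresponding
~3 kcal/mol (~5 kT) barrier near z = −8 Å, and the mutant traps a fourth ion
in the cavity (`S0-W-S2-W-S4-C`) while holding ~30 rather than ~50 waters
within 8 Å of the gate Ile. `out/` additionally receives the four TSV
comparison tables, per-variant gate/census tables, the PMF profile and the
fully resolved configuration.

The same pipeline is scriptable from the shell:

```bash
kvgate make-fixtures --out-dir fixtures --seed 1 --n-frames 200
kvgate gating --pdb fixtures/mutant.pdb --variant dS269
kvgate pmf --meta fixtures/windows_barrier/metadata.txt --out-dir pmf_out
kvgate compare --out-dir out --seed 0
```

## Layout

```
src/kvgate/
  io.py         multi-model PDB, umbrella window sets, configs, TSV reports
  geometry.py   distances, torsions, kink angle, salt bridges, water counts
  gating.py     passage criterion, site definitions, occupancy states
  pmf.py        WHAM solver, anchoring, barrier readout, convergence blocks
  synthetic.py  toy-channel generator and exact Boltzmann umbrella sampling
  pipeline.py   WT-vs-mutant comparison and PMF runner
  cli.py        `kvgate` command-line interface
docs/methods.md the methods note (model, assumptions, numerical choices)
```
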