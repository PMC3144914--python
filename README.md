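# dfgflip

Tools for predicting and exploiting the inactive **DFG-out** conformation of
protein kinases starting from their abundant **DFG-in** crystal structures.

Type-II kinase inhibitors (imatinib being the canonical example) bind the
DFG-out state, spanning the adenine pocket, hydrophobic pocket II and the
DFG-out pocket of the widened active-site cleft. Because solved DFG-out
structures are rare, structure-based design of type-II inhibitors usually has
to start from a DFG-in structure. `dfgflip` implements the decision layer of
an activation-loop remodeling workflow around external modeling (Rosetta loop
rebuilding) and docking (AutoDock) engines:

1. **Cleft geometry** — the cleft width statistic
   *D = d(K,D) + d(K,F) + d(E,D) + d(E,F)*, the sum of the four pairwise
   distances from the catalytic Lys (β3) and the αC Glu to the DFG Asp and
   Phe. A three-tier rule maps D to an outward N-lobe rotation:
   D > 32 Å → 0°, 30 ≤ D ≤ 32 Å → 5°, D < 30 Å → 15°. The rigid rotation is
   applied about the normal of the plane through the domain centroid and the
   αC ends, passing through the middle hinge residue.
2. **DFG classification** — after superposing a model onto its DFG-in
   reference over non-loop Cα atoms, each DFG side chain gets a normal
   **n** = (Cα_Asp→Cα_Phe) × (Cα→Cγ). Negative dot products of model vs
   reference normals for *both* Asp and Phe mean both side chains crossed the
   activation-loop axis: DFG-out. Both positive: DFG-in. Anything else:
   intermediate.
3. **Pocket analysis** — a LIGSITE-style 1 Å grid scan (protein–solvent–
   protein enclosure along 7 directions) plus PASS-style buried-site
   clustering finds the cleft sites B1/B2/B3; pocket volume is reported as
   occupied waters at 1 g/ml. Models qualify for ensemble docking with ≥ 3
   cleft sites and strictly more than 20 occupied waters.
4. **Loop clustering** — nearest-neighbour clustering (4 Å Cα RMSD, in the
   fixed non-loop frame) of a 16-residue segment starting two residues
   before the DFG motif; plus DFG-motif heavy-atom RMSD and a
   fixed-correspondence TM-score for model-vs-crystal comparison.
5. **Conformational selection of docking results** — poses outside the cleft
   (no heavy atom within 3 Å of B2 or B3) are discarded; the lowest-energy
   surviving pose is the ligand's representative and picks the representative
   DFG-out model; ligands re-ranked by representative energy form the hit
   list scored by ROC AUC against active/decoy labels.

External engines are *not* run by this package: it emits their inputs
(Rosetta `LOOP start end cut 0 1` lines with the cut at the most hydrophilic
middle-third residue; AutoDock grid/docking parameter stubs centered on B2
with the 60 Å box, 20 runs, population 150, 27 000 generations, 1.5 M
evaluations) and ingests their outputs.

## Worked example

Everything is testable offline through the synthetic fixtures: a toy
two-lobe kinase whose cleft width and DFG state are set by construction.

```python
from dfgflip import (make_toy_kinase, ToyKinaseSpec, cleft_distance_sum,
                     rotation_category, rotation_axis, rotate_nlobe,
                     classify_dfg, make_screening_set, build_hitlist, roc_auc)
from dfgflip.cleft_geometry import replace_spec

ref, ann = make_toy_kinase(ToyKinaseSpec(target_distance_sum=28.5,
                                         dfg_state="in", seed=1))
m = cleft_distance_sum(ref, "CA")
print(f"distance sum D = {m.distance_sum:.1f} A")
angle = rotation_category(m.distance_sum)
print(f"rotation tier: {angle} degrees")
spec = replace_spec(rotation_axis(ref, "CA"), angle_deg=float(angle))
widened = rotate_nlobe(ref, spec)
print(f"D after rotation = {cleft_distance_sum(widened, 'CA').distance_sum:.1f} A")

model, _ = make_toy_kinase(ToyKinaseSpec(target_distance_sum=28.5,
                                         dfg_state="out", seed=1))
r = classify_dfg(model, ref)
print(f"classification: {r.label}")

reps, labels = make_screening_set(50, 500, -10.0, -7.0, 1.0, seed=7)
res = roc_auc(build_hitlist(reps, labels))
print(f"screening AUC = {res.auc:.3f}")
```

prints

```
distance sum D = 28.5 A
rotation tier: 15 degrees
D after rotation = 35.8 A
classification: DFG_OUT
screening AUC = 0.992
```

A cleft of D = 28.5 Å is too narrow for a type-II scaffold, so the 15° tier
applies; the rigid outward rotation widens it to 35.8 Å. The constructed
DFG-out twin is recovered as `DFG_OUT` by the sidedness test. On the
synthetic screen (active energies N(−10, 1), decoys N(−7, 1)) the measured
AUC of 0.992 sits near the closed-form expectation Φ(3/√2) ≈ 0.983.

The same operations are available from the shell, e.g.

```sh
dfgflip fixtures --kind toy-kinase --out demo/
dfgflip cleftsum --pdb demo/toy_in.pdb --ann demo/toy.ann --convention CA
dfgflip classify --model demo/toy_out.pdb --ref demo/toy_in.pdb --ann demo/toy.ann
```

For crystal structures, the distance sum depends on which representative
point stands for each residue; `cleft_distance_sum` supports `"CA"`,
`"sidechain_centroid"` (default) and `"functional"` (Lys NZ, Glu CD, Asp CG,
Phe CZ) conventions — see `docs/methods.md` for how to calibrate the choice
against structures with known tier assignments.

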