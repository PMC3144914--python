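# Methods

This note documents the models, parameters and numerical choices behind
`dfgflip`, and what the synthetic fixtures do and do not establish about
behavior on real kinase structures.

## Scope and assumptions

The package is the decision layer of a DFG-out prediction workflow. It
assumes single-chain kinase catalytic domains with author residue numbering
preserved from the input file, and a user-supplied annotation naming the
functional residues (DFG triad, catalytic Lys, αC Glu, αC start/end, hinge
range, activation-loop end, last N-lobe residue). Annotations are inputs, not
inferences: assigning them needs structural judgment (or a kinase numbering
service) that is outside this package's scope. All heavy-atom geometry
ignores hydrogens; structures are used as-is after preparation (waters, ions
and ligands stripped; SEP/TPO/PTR renamed to SER/THR/TYR with phosphate atoms
dropped). Missing side-chain atoms are *not* rebuilt — preparation never
moves or invents coordinates; users who need completed side chains should run
a modeling tool first.

## Cleft width and the tiered N-lobe rotation

The cleft statistic D is the sum of the four pairwise distances from the
catalytic Lys and αC Glu to the DFG Asp and Phe. The tier rule (D > 32 Å →
0°, 30–32 Å → 5°, D < 30 Å → 15°, boundaries inclusive in the 5° tier) is a
total, piecewise-constant function of D ≥ 0.

**Representative-point conventions.** A residue-level distance needs an atom
choice. Three conventions are provided:

* `CA` — backbone Cα; the most robust, and exact on the CA-trace fixtures;
* `sidechain_centroid` (default) — mean of side-chain heavy atoms, falling
  back to Cα for glycine; tracks where the side chain actually is without
  depending on a single atom;
* `functional` — the interaction tip (Lys NZ, Glu CD, Asp CG, Phe CZ);
  closest to salt-bridge chemistry but most sensitive to side-chain modeling.

The tier thresholds for this statistic were derived on *relaxed* structures,
so on raw crystal coordinates a ±1 Å tolerance on D near tier boundaries is
realistic. When tier assignments for reference structures are known,
calibrate once: compute D under each convention for a structure with a
known value, keep the convention minimizing the discrepancy, and
validate on the remaining structures. The package ships with
`sidechain_centroid` as the a-priori default; it is a parameter, not a fitted
constant.

**Rotation axis.** The axis is the unit normal of the plane through (i) the
Cα centroid of the whole catalytic domain, (ii) Cα of the αC start residue,
(iii) Cα of the αC end residue, positioned at the Cα of the middle hinge
residue (integer midpoint of the hinge range, floored). The domain "center"
is a Cα centroid rather than a mass-weighted one — at the precision the tier
rule needs, the difference is immaterial, and Cα centroids are insensitive to
missing side chains. The rotation sense is resolved per structure by ±1°
trial rotations, keeping the sense that increases D (the outward direction);
a structure where neither sense widens the cleft is an error, not a silent
choice. The rotation itself is a Rodrigues rigid rotation applied to residues
with `res_seq <= nlobe_last`; the C-lobe is returned bit-identical.

## DFG-state classification

After rigid superposition of the model onto its DFG-in reference over the
common Cα atoms *outside* the remodeled segment (DFG−2 … activation-loop
end, so loop motion cannot bias the frame), each of Asp and Phe contributes a
normal vector n = (Cα_Asp→Cα_Phe) × (Cα→Cγ). The sign of
n_model · n_reference says whether that side chain stayed on its side of the
activation-loop axis (+) or crossed it (−). Both negative → DFG-out, both
positive → DFG-in, mixed or an exact zero (|dot| ≤ 1e−12) → intermediate.
Superposition is least-squares (Kabsch sense) with a proper rotation; the
test suite checks it against an independent quaternion eigen-decomposition
oracle at 1e−9.

The classifier is deliberately frame-based rather than torsion-based: it
reproduces the sidedness semantics of the DFG flip using only four atoms per
structure, and is invariant to any global rigid motion of the model. It does
not attempt the finer spatial sub-states that torsion-based kinase
classifiers distinguish.

## Pocket detection and water-occupancy volume

`build_grid` rasterizes the structure on a 1 Å grid over the bounding box
plus a 5 Å margin; a grid point is protein iff within vdW + 1.4 Å probe of a
heavy atom (vdW: C 1.70, N 1.55, O 1.52, S/P 1.80 Å; unknown elements as
carbon). `psp_scan` counts protein–solvent–protein enclosure along the 3 axes
and 4 cube diagonals; solvent points enclosed along ≥ 4 of 7 directions form
the pocket mask. The 4-of-7 threshold, 1.4 Å probe and 5 Å margin are the
common grid-scan conventions for this family of detectors. Sites are
single-linkage clusters of pocket points at 2× grid spacing, each reduced to
a buriedness-weighted centroid (weight = PSP count); B1 is the site nearest
the middle hinge Cα (adenine pocket), B3 nearest the DFG-Asp Cα (DFG-out
pocket), and B2 the remaining site nearest the Lys–Glu midpoint (hydrophobic
pocket II), with near-ties (within 0.5 Å) resolved toward the heavier site.
The "active-site cleft" is the pocket mask within 8 Å of a labeled site, so
distal surface pockets never inflate the volume.

**Occupied waters.** Pocket volume is reported as the number of waters of a
cubic 1 g/ml lattice (lattice constant (18.015 / (6.02214×10²³ ×
10⁻²⁴))^⅓ ≈ 3.105 Å, registered to the grid origin) that belong to the
pocket: the water's nearest masked grid point lies within 1.6 Å *and* the
grid voxel containing the water is masked. The proximity criterion alone
would add a ~1.6 Å surface rind to every pocket — a systematic (1 + 3.2/L)³
overcount that contradicts the 1 g/ml density semantics (a 1000 Å³ cavity
should hold ≈ 33 waters, not ≈ 77); the voxel condition removes the rind
while keeping the stated 1.6 Å rule operative for coarse or ragged masks.
Registration to the grid origin makes counts invariant under whole-grid-step
co-translations; sub-grid registration sensitivity is of order ±1 water per
pocket axis, which is why volume checks on small cavities carry a ±30% band —
and why a cube of side 8 Å (2.58 lattice constants per axis) cannot be
counted to ±30% by any integer lattice: its admissible counts are 8 or 27
against an expectation of 17.1. Realistic kinase clefts (600–1500 Å³) sit
well above this regime.

A model qualifies for the docking ensemble with ≥ 3 sites in the cleft and
strictly more than 20 occupied waters — 20 being the occupied-water volume of
a minimal type-II scaffold, so the criterion reads "the cleft holds at least
one minimal type-II molecule and then some".

## Loop clustering and comparison metrics

The clustering segment is 16 residues from DFG−2. Pairwise loop RMSD is
computed in the fixed non-loop frame: superpose the two models over Cα atoms
outside the segment, then take Cα RMSD over the segment. This makes clusters
reflect where the loop sits in the cleft, not merely its internal shape; it
is symmetric to numerical precision but, like any superposed RMSD, not a true
metric. Nearest-neighbour clustering at a 4 Å threshold is realized as
connected components of the ≤ 4 Å graph (exactly a single-linkage cut);
cluster order is by descending population with ties to the lowest member
index, and each cluster's representative minimizes the summed RMSD to its
cluster mates. The population multiset is invariant to input order.

The DFG-motif RMSD is a heavy-atom RMSD over the three motif residues after
the same non-loop Cα superposition, pairing atoms by name. The TM-score uses
the standard normalization d0 = 1.24(L−15)^⅓ − 1.8 (floored at 0.5 Å) with a
*fixed* residue correspondence — the structures are the same protein, so no
alignment search is needed — and approximates the maximization over
superpositions by seeding on sliding windows (full length, half length, 7
residues) and iterating between scoring and re-superposing on the residues
within max(d0, 4.5 Å). Degenerate (collinear) seed windows are skipped. On
the displaced-loop fixtures this agrees with an exhaustive-seed oracle to
0.01.

## Remodeling and docking job specifications

The remodeling segment runs from DFG−2 to the activation-loop end. The chain
cut point is the most hydrophilic residue (minimum Kyte–Doolittle hydropathy)
in the middle third of the segment (rounded outward; never empty for length
≥ 3), ties resolved toward the segment midpoint and then N-terminally —
Kyte–Doolittle because it is the field's default hydropathy scale; the cut
always satisfies start < cut < end. Docking specs default to the
ensemble-docking protocol: 60 Å cubic box centered on B2, 20 runs, GA
population 150, 27 000 generations, 1.5 M energy evaluations.

## Docking pose selection and screening

A pose is in-cleft iff any heavy atom is strictly within 3 Å of B2 *or* B3
(the union reading of the two anchors — the looser and more literal
interpretation; requiring both would mostly filter by ligand length, which
the 20-water volume criterion already handles upstream). The representative
pose of a ligand is its lowest-energy in-cleft pose across the ensemble,
ties to the lexicographically smallest (model, run). Ligands with no
in-cleft pose are kept in the hit list at the worst rank rather than dropped,
so screening denominators are stable. Ligand RMSD pairs atoms 1:1 by name
after applying the receptor superposition transform and applies no
graph-automorphism symmetry correction, so RMSDs of symmetric ligands are
pessimistic upper bounds. AUC is the Mann–Whitney statistic (ties ½), which
equals the trapezoidal area under the rank-threshold ROC; both are computed
and agree to 1e−9.

## What the fixtures do and do not show

The toy kinase is a CA-trace scaffold with DFG side-chain stubs: its cleft
rectangle makes D exact under the `CA` convention, its DFG twins realize the
three states by construction, and its lobes/anchors give a well-defined
rotation axis. It has no packing, secondary structure or sterics, so passing
tests demonstrate the *geometry and logic* of the pipeline — not that the
tier thresholds or pocket parameters are optimal for real kinases, which is
what the calibration-against-known-structures step is for. Cavity fixtures
are idealized shells with analytic volumes; the three-chamber cavity shares
walls between chambers specifically so that no partially-enclosed exterior
gaps create spurious sites. The screening set draws per-ligand representative
energies directly from two normal distributions — it validates the
rank/AUC machinery against the closed form Φ(Δμ/σ√2), not docking energetics.

Problem sizes used by the default test run and the acceptance script (toy
ensembles of 30–75 models, cavities of 6–12 Å, screens of 550–2000 ligands)
were chosen as the smallest sizes at which every contract is exercised with
comfortable statistical margins.

## Known limitations

* Annotations must be supplied; nothing infers αC limits or loop ends.
* Phospho-residue demotion renames and deletes; it does not rebuild the
  unmodified side chain's hydrogens or optimize geometry.
* The PASS-style site finder is a buriedness-weighted clustering of the grid
  mask, not the original probe-sphere layering; only the contract (ranked
  buried site centers) matches.
* TM-score assumes identical sequences (fixed correspondence); it is not a
  structure-alignment tool.
* Ligand RMSD has no symmetry correction.
* Water counts on cavities smaller than ~3 lattice constants per axis are
  dominated by integer discretization (see above).
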