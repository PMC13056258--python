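# Methods

This note documents the models, defaults, and numerical choices behind
`oligostate`, and what the synthetic-data validation does and does not
establish about real simulation data.

## System and conventions

All coordinates are stored in nanometres; PDB I/O converts from
Ångström, and the package's multi-frame XYZ dialect stores nm directly
with the frame time (ps) on the comment line. Frame cadence must be
uniform (times are `frame_index × Δt`, default Δt = 10 ps); irregular
cadence is rejected because first-passage times and transition counts
assume a fixed step. A run of duration T saved every Δt yields
`round(T/Δt)` snapshots with times 0 … (n−1)Δt, so 500 ns at 10 ps is
50,000 frames. Capping groups (ACE/NME) are retained as atoms — they
participate in distances and energies — but excluded from residue-level
indexing, so a capped heptapeptide has 7 residues. Four peptides in a
409 nm³ box correspond to 16.2 mM.

## Oligomer detection and the 10-state classifier

Peptide contact: minimum atom–atom distance ≤ 0.3 nm over all atoms
present in the topology (hydrogens included when present; the reduced
synthetic model has none). Oligomers are connected components of the
contact graph, which reproduces the chained dimer→trimer→tetramer
definitions exactly and is verified against a brute-force
reachability-matrix oracle on random geometries.

State labels combine the largest component size with the number of
sheet-participating peptides inside it. Two readings were open:

* A lone β-conformation peptide does **not** advance the state: a sheet
  requires paired strands, so states II, IV and VII absorb sheet counts
  of 0 *or* 1. Under this reading the admissible (size, count) pairs
  are exactly ten: (1,0), (2,0), (2,2), (3,0), (3,2), (3,3), (4,0),
  (4,2), (4,3), (4,4).
* With several same-size largest components (e.g. two dimers), the most
  sheet-rich one defines the state, since the taxonomy describes the
  oligomer achieved.

## β-sheet detection and the 8-class taxonomy

Strands are maximal runs of ≥ 2 consecutive β-labelled residues. Two
strands on different peptides pair when the mean of their residue-wise
Cα distances, minimized over register shifts of −2…+2 and over both
alignment senses, is ≤ 0.55 nm with ≥ 2 aligned positions. Orientation
is the sign of the dot product of the strand direction vectors
(first→last Cα); near-perpendicular pairs (|cos| < 0.1) are rejected and
logged, as no registry is defined for them. Sheets are connected
components of the pairing graph; the class combines the number of
distinct peptides (2–4) with the orientation mix (a two-strand sheet
cannot be mixed), giving 2 + 3 + 3 = 8 classes.

## Secondary structure

A deterministic φ/ψ-region assigner replaces hydrogen-bond-based
algorithms (which need all-atom geometry the reduced model does not
have):

* β: φ ∈ [−180°, −90°] and ψ ∈ [90°, 180°] ∪ [−180°, −170°];
* helix: φ ∈ [−100°, −30°] and ψ ∈ [−80°, −5°];
* turn: neither box, Cα(i−2)→Cα(i+2) distance < 1.0 nm, and both
  sequence neighbours not β;
* coil otherwise; chain-terminal residues (undefined φ or ψ) are coil.

Torsions follow the IUPAC sign convention and were cross-checked against
an independent implementation (biotite) during development; the test
suite carries its own vector-algebra oracle. Because the turn criterion
is a geometric stand-in, absolute turn/coil percentages from
hydrogen-bond-based assigners are not comparable and are not targets.
Transition counting is undirected for reporting (a directed matrix is
kept internally); per-residue counts between consecutive frames are
normalized by the observation span in ns.

## Energetics

Gas-phase Coulomb + Lennard-Jones with Lorentz–Berthelot combining;
Coulomb constant 332.0637 kcal·Å·mol⁻¹·e⁻²; no cutoff by default
(analysis-time sums are exact; a 1.0 nm cutoff is available to mimic
simulation conventions). Distances below 0.01 nm raise an error —
closer approach indicates broken geometry, not physics. The IIE is
computed as the sum over peptide pairs of group–group energies; the test
suite proves it equal (to < 1e−9 kcal/mol) to the difference form
E_complex − Σᵢ Eᵢ evaluated by a brute-force all-pair total-energy
routine, since bonded and intra-peptide terms cancel.

The built-in parameter table for synthetic pseudo-atoms is a
reduced-model calibration, not a force field: backbone N/C carry ∓0.3 e
(residues stay neutral, electrostatics is non-trivial), pseudo-ring
carbons are neutral (the aromatic-H partial charge folded in, as the
model has no hydrogens), and σ values (0.15–0.19 nm) are sized to the
model's own contact scale so that rigid-docked geometries (closest
approach ≈ 0.2–0.25 nm) sit near the attractive well rather than deep in
the r⁻¹² core. Consequently IIE *magnitudes* on synthetic data are not
physical; only their mechanics (decomposition, additivity, sign
behaviour) are meaningful. π–π energies are ring-atom pair sums over
the six-site pseudo-rings; for pair types with several instances per
frame (intermolecular types), the most favourable instance represents
the type in the population count, matching a contact-style statistic.

## Free-energy landscape

ΔG(bin) = −k_B·T·[ln P(bin) − ln P_max] with k_B =
0.0019872 kcal·mol⁻¹·K⁻¹ and T = 310 K by default; bin width 0.1 nm on
both axes (no published value; 0.1 nm resolves basin separations of a
few tenths of nm and is configurable). Empty bins carry +∞, never 0,
and are excluded from minima search; the minimum occupied bin is exactly
0 by construction. Basin characterization runs k-means (k-means++, 20
restarts, fixed seed) on the raw per-frame points rather than bin
centers; k is user-supplied. Centroid distances (the cd coordinate) use
the unweighted geometric center by default because synthetic pseudo-atom
masses are nominal; mass weighting is available by configuration.

## SASA and other geometry

SASA uses the Shrake–Rupley construction with a deterministic
golden-spiral point set (default 960 points, probe 0.14 nm, error below
32 points), validated against closed forms (isolated sphere to < 1%,
two-sphere cap geometry to < 2%). Radii default to a small element
table (C 0.17, N 0.155, O 0.152, H 0.12 nm). Rg is mass-weighted with
unit masses when masses are unknown. The intramolecular residue-contact
count excludes |i−j| < 2 pairs, which are trivially within the 0.45 nm
residue cutoff.

## The synthetic-data generator

The generator is the package's substitute for molecular dynamics: it
tests analysis code, not physics. Peptides are reduced models — N, CA,
C per residue placed by internal-coordinate (NeRF) chain extension from
target dihedrals (standard bond lengths 0.1458/0.1525/0.1329 nm, ω =
180°), one pseudo side-chain site along the idealized CA→Cβ direction at
the residue's side-chain centroid distance, and a planar six-site ring
(edge 0.139 nm, center 0.35 nm from CA, face-on to the side-chain axis)
for phenylalanine. Construction is exact: measured φ/ψ reproduce the
targets to ≪ 1e−3°, and the analyzer recovers them identically on
noiseless frames.

Scripted conformers are β (−139°, 135°), helix (−57°, −47°), and a
PPII-like coil (−75°, 145°) chosen so the region assigner labels it
coil (outside both boxes and too extended for the bend test — a
*compact* random coil would trigger the turn test, so "coil" here means
extended-disordered). The script vocabulary is
associate/dissociate/set_conformation/set_registry; validation rejects
dissociation of never-associated pairs, registry events on non-β
peptides, and events outside the run duration.

Geometry is rigid placement, not dynamics: clusters lay members along a
stacking axis in association order; β–β neighbours stack at the
registry Cα spacing (default 0.48 nm, a typical sheet spacing) by
aligning Cα centroids, with a 0.06 nm pleat offset and a 94° strand
azimuth — calibrated once so that the minimum atom distance of a paired
strand falls in [0.15, 0.25] nm for both registries and both study
sequences (inside the 0.3 nm contact cutoff, outside steric overlap);
non-β neighbours are docked by bisection to a 0.22 nm minimum atom
distance. Antiparallel strands are 180°-rotated about the stacking
axis, which preserves chirality and dihedrals. Separate clusters sit at
the mean of their members' tetrahedron vertices and are pushed apart if
rigid blocks approach within 1 nm. Noise has two parts, both from one
seeded generator: a tethered per-cluster random walk (step σ, relaxation
0.9 — stationary spread ≈ 2.3σ, so clusters wander without colliding)
and i.i.d. Gaussian noise σ on every coordinate. Identical seeds give
bit-identical output; different seeds change noise but not labels.

## What the validation shows — and does not

On noiseless scripted trajectories every stage is exact: partitions,
I–X state sequences, OT2/OT3/OT4, sheet classes, and per-residue labels
match the script frame for frame. At the study noise level (σ =
0.02 nm) partition recovery and state recovery on the canonical
stepwise-assembly ensemble (10 × 5,000 frames) remain ≥ 99%. Recovery
degrades monotonically with σ (the validation driver tabulates this up
to σ = 0.4 nm).

Known limitation: in sheet-rich phases, state recovery is slightly lower
(≈ 96–98% of sheet-phase frames) because 0.02 nm coordinate noise moves
backbone torsions by ~10–15°, occasionally breaking a strand's run of
consecutive β residues and demoting X to IX for single frames; partition
recovery is unaffected. This is faithful detector behaviour under the
stated noise, not an error to be tuned away.

The generator emulates geometry and kinetics, not thermodynamics: no
solvent, no forces, no Boltzmann-weighted conformational ensembles, and
docked geometries are not energy-minimized. Passing tests therefore
demonstrate the correctness of the *analysis* definitions and their
implementations, and say nothing about force-field accuracy or sampling
convergence on real trajectories.

## Problem sizes

Default study sizes were chosen so the full validation stack runs
comfortably on one CPU: scripted ensembles of 4–10 trajectories of
3,000–5,000 frames (30–50 ns at 10 ps cadence), heavy per-frame
observables (SASA, contact maps, energies) on a 10–25-frame stride
within the analysis window, and oracle suites of 200–1,000 random
frames. All sizes are parameters of the drivers and tests.
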