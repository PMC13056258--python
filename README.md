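# oligostate

Oligomerization-state and β-sheet-topology analysis for small amyloid
peptide assemblies, with a scripted synthetic-trajectory generator that
provides exact ground truth for every analysis stage.

## The scientific problem

Short amyloid fragments such as Aβ16–22 (KLVFFAE) are standard minimal
models of early amyloid aggregation: four peptides in a box at
millimolar concentration assemble within tens of nanoseconds through
dimer → trimer → tetramer intermediates, and the resulting oligomers
reorganize into parallel, antiparallel, or mixed β-sheets.
Characterizing that process from a coordinate trajectory requires a
stack of analyses that are usually scattered across ad-hoc scripts:

* **Oligomer detection.** Two peptides are in contact when their minimum
  atom–atom distance is ≤ 0.3 nm; oligomers are the connected components
  of the contact graph (a trimer is a dimer plus a third peptide in
  contact with either member, and so on).
* **Ten oligomerization states.** Each frame of a four-peptide system is
  labelled I–X by (largest oligomer size, number of sheet-forming
  peptides inside it): I = four monomers; II/III = dimer without/with a
  β-sheet; IV/V/VI = trimer with 0–1/2/3 sheet peptides; VII–X = tetramer
  with 0–1/2/3/4 sheet peptides. Enumerating the admissible
  combinations yields exactly ten states.
* **Eight β-sheet classes.** Sheets of 2–4 strands are classified by
  size and registry — pBS2, apBS2, pBS3, apBS3, mBS3, pBS4, apBS4, mBS4
  (p = parallel, ap = antiparallel, m = mixed). Strands are maximal runs
  of ≥ 2 consecutive β residues; two strands pair when their optimally
  aligned Cα distances average ≤ 0.55 nm, with orientation from the sign
  of the strand-direction dot product.
* **Kinetics.** Oligomerization times OT2/OT3/OT4 (first passage to
  dimer/trimer/tetramer), peptide-weighted species populations over
  time, and the undirected state-transition network split into
  *growth* (size-changing) and *rearranging* (same-size) transitions.
* **Energetics.** The intermolecular interaction energy
  IIE = E_complex − Σᵢ Eᵢ reduces to the sum of inter-peptide nonbonded
  pair energies and splits exactly into van der Waals and Coulombic
  parts (Lorentz–Berthelot combining, Coulomb constant
  332.0637 kcal·Å·mol⁻¹·e⁻²). π–π interactions between phenylalanine
  rings are scored per ring pair; a pair's *population* is the
  percentage of frames with energy below −1.0 kcal/mol. For k Phe per
  peptide there are C(k,2) intramolecular and C(k+1,2) intermolecular
  pair types (KLVFFAE: 1 and 3; the K16F/E22F analogue FLVFFAF: 6
  and 10).
* **Free-energy landscapes.** ΔG(V) = −k_B·T·[ln P(V) − ln P_max] over a
  2D histogram of (e2e, cd) — the summed peptide end-to-end distances
  and the summed pairwise centroid distances — with basins characterized
  by k-means centers and populations.
* **Secondary structure.** A deterministic φ/ψ-region assigner with a
  chain-bend turn test labels each residue β/helix/turn/coil, feeding
  per-residue profiles and residue-level transition statistics.

Because no public trajectories exist for this kind of study, the package
includes a first-class synthetic-data module: peptides built from target
backbone dihedrals (internal-coordinate chain construction), placed on a
3.5 nm regular tetrahedron (≈ 16 mM for four peptides in a 409 nm³ box),
and driven by a script of timed association/dissociation, conformation,
and registry events. The generator emits the matching ground-truth
labels, so detector and classifier outputs can be checked exactly.

## Worked example

```python
from oligostate import detect_oligomers
from oligostate.synthetic import canonical_script, generate
from oligostate.kinetics import oligomerization_times, transition_network
from oligostate.oligomers import classify_state, detect_sheets
from oligostate.secondary import assign_ss_frame
import numpy as np

# stepwise assembly at 2/7/18 ns, antiparallel sheet after tetramer
script = canonical_script(noise_sigma_nm=0.02, seed=42,
                          registries=("antiparallel",) * 3)
topology, frames, truth = generate(script)

states, sizes = [], []
for frame in frames:
    part = detect_oligomers(topology, frame, cutoff_nm=0.3)
    ss = assign_ss_frame(topology, frame)
    states.append(classify_state(part, detect_sheets(topology, frame, ss)).label)
    sizes.append(part.largest_size)

ot = oligomerization_times(np.array(sizes), script.save_interval_ps)
print("OT2/OT3/OT4 (ns):", [t / 1000 for t in ot.as_tuple()])
net = transition_network([states])
print("dominant state:", max(set(states), key=states.count))
print("growth vs rearranging transitions:", net.n_growth(), net.n_rearranging())
recovery = np.mean([s == t for s, t in zip(states, truth.state_labels)])
print("scripted-state recovery:", f"{100 * recovery:.1f}%")
```

prints

```
OT2/OT3/OT4 (ns): [2.0, 7.0, 18.0]
dominant state: IV
growth vs rearranging transitions: 13 202
scripted-state recovery: 96.1%
```

The detected first-passage times reproduce the scripted association
times exactly; the dominant state is the β-free trimer (IV) because the
sheet only forms in the final 12 ns; transitions are overwhelmingly
*rearranging* (sheet flicker within the tetramer) rather than *growth*;
and 96% of the noisy frames receive exactly the scripted I–X label (the
missing 4% are sheet-phase frames where coordinate noise briefly breaks
one strand's β run — see `docs/methods.md`).

## Command line

```bash
oligostate generate --seed 7 --out demo              # demo.pdb/.xyz/.labels.tsv
oligostate analyze --topology demo.pdb --traj demo.xyz --fel-k 2 --out outdir
oligostate report --summary demo outdir/summary.json
```

## Analysis drivers

`analysis/01…05_*.py` run the full study over two scripted four-peptide
systems — wild-type-like (KLVFFAE, antiparallel registry, slower
assembly) and mutant-like (FLVFFAF, mixed registry, faster assembly) —
and write their tables under `results/`: ensemble structural summaries
and the side-by-side report, species-population time courses, transition
networks, free-energy landscapes with k-means minima, π–π population
tables, and detector-recovery-vs-noise validation curves.

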