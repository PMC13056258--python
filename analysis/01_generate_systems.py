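#!/usr/bin/env python
"""Build the two four-peptide study systems and record their design numbers.

Writes results/systems/: the initial-frame PDB of each system, the box
design table (peptide concentration, snapshot counts), and a preview of
the scripted ground-truth labels.
"""

import os
import sys

sys.path.insert(0, os.path.dirname(__file__))

import numpy as np
from common import SYSTEMS, make_scripts

from oligostate.io import n_frames_for, write_labels, write_topology
from oligostate.metrics import min_distance
from oligostate.synthetic import generate, molar_concentration_mM

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "systems")


def main() -> None:
    os.makedirs(OUT, exist_ok=True)

    with open(os.path.join(OUT, "design.tsv"), "w") as fh:
        fh.write("quantity\tvalue\n")
        fh.write(f"peptide_concentration_mM_4_in_409nm3\t"
                 f"{molar_concentration_mM(4, 409.0):.1f}\n")
        fh.write(f"snapshots_500ns_10ps\t{n_frames_for(500_000.0, 10.0)}\n")
        fh.write("tetrahedron_edge_nm\t3.5\n")

    for name in SYSTEMS:
        script = make_scripts(name, n_traj=1)[0]
        top, frames, labels = generate(script)
        write_topology(top, frames[0].coordinates,
                       os.path.join(OUT, f"{name}_initial.pdb"))
        # label preview: every 100th frame
        sub_idx = np.arange(0, labels.n_frames, 100)
        import dataclasses

        preview = dataclasses.replace(
            labels,
            components=labels.components[sub_idx],
            conformations=[labels.conformations[i] for i in sub_idx],
            state_labels=[labels.state_labels[i] for i in sub_idx],
            sheet_classes=[labels.sheet_classes[i] for i in sub_idx],
            orientations=labels.orientations[sub_idx],
            time_ps=labels.time_ps[sub_idx],
        )
        write_labels(preview, os.path.join(OUT, f"{name}_labels_preview.tsv"))

        d0 = min(
            min_distance(frames[0].coordinates[top.peptide_atom_indices(i)],
                         frames[0].coordinates[top.peptide_atom_indices(j)])
            for i in range(4) for j in range(i + 1, 4)
        )
        print(f"{name}: {top.n_peptides} x {top.peptides[0].sequence}, "
              f"{len(frames)} frames, initial min inter-peptide distance "
              f"{d0:.2f} nm")
    print(f"concentration of 4 peptides in 409 nm^3: "
          f"{molar_concentration_mM(4, 409.0):.1f} mM")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
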