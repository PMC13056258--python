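#!/usr/bin/env python
"""Two-dimensional free-energy landscapes over (e2e, cd) with k-means minima.

Pools all frames of each scripted ensemble (so the landscape spans the
whole assembly funnel, from distant extended monomers to the compact
tetramer), bins the coordinates (0.1 nm), converts to ΔG at 310 K,
clusters the raw points, and writes results/fel/: grids, minima JSON,
and a rendered heat map.
"""

import json
import os
import sys

sys.path.insert(0, os.path.dirname(__file__))

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from common import SYSTEMS, make_scripts

from oligostate.fel import ReactionCoordinates, find_minima, free_energy_surface, reaction_coordinates
from oligostate.synthetic import generate

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "fel")


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    fig, axes = plt.subplots(1, len(SYSTEMS), figsize=(11, 4.5), squeeze=False)
    for ax, name in zip(axes[0], SYSTEMS):
        e2e, cd = [], []
        top = None
        for script in make_scripts(name):
            t, frames, _ = generate(script)
            top = t
            rc = reaction_coordinates(top, frames)
            e2e.append(rc.e2e_nm)
            cd.append(rc.cd_nm)
        pooled = ReactionCoordinates(np.concatenate(e2e), np.concatenate(cd))
        fes = free_energy_surface(pooled, bin_width_nm=0.1, temperature_K=310.0)
        minima = find_minima(pooled, k=2, seed=0)

        with open(os.path.join(OUT, f"{name}_minima.json"), "w") as fh:
            json.dump({"k": minima.k,
                       "centers_nm": minima.centers.tolist(),
                       "populations_pct": minima.populations_pct.tolist()},
                      fh, indent=2)
        print(f"{name}: minima at "
              + ", ".join(f"({c[0]:.2f}, {c[1]:.2f}) nm [{p:.1f}%]"
                          for c, p in zip(minima.centers, minima.populations_pct)))

        grid = np.where(np.isinf(fes.delta_g_kcal), np.nan, fes.delta_g_kcal)
        im = ax.pcolormesh(fes.e2e_edges, fes.cd_edges, grid.T, cmap="viridis")
        ax.scatter(minima.centers[:, 0], minima.centers[:, 1], marker="x",
                   c="red", s=60)
        ax.set_xlabel("e2e (nm)")
        ax.set_ylabel("cd (nm)")
        ax.set_title(name)
        fig.colorbar(im, ax=ax, label=r"$\Delta G$ (kcal/mol)")
    fig.tight_layout()
    fig.savefig(os.path.join(OUT, "fel_landscapes.png"), dpi=120)
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
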