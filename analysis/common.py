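"""Shared study definitions for the analysis drivers.

Two scripted four-peptide systems emulate the wild-type (KLVFFAE) and
K16F/E22F double-mutant (FLVFFAF) study conditions: stepwise association
with per-trajectory oligomerization times drawn from the reported mean ±
sd (wild type 2±1, 10±3, 32±7 ns; mutant 2±1, 7±2, 18±4 ns), followed by
β-sheet formation — all-antiparallel registry for the wild type, a mixed
parallel/antiparallel registry for the mutant, matching each system's
reported registry preference.  Coordinate noise sigma is 0.02 nm.
"""

from __future__ import annotations

import numpy as np

from oligostate.synthetic import canonical_script

SYSTEMS = {
    "wt": {
        "sequence": "KLVFFAE",
        "ot_mean_sd_ns": [(2.0, 1.0), (10.0, 3.0), (32.0, 7.0)],
        "registries": ("antiparallel", "antiparallel", "antiparallel"),
        "duration_ns": 45.0,
    },
    "mutant": {
        "sequence": "FLVFFAF",
        "ot_mean_sd_ns": [(2.0, 1.0), (7.0, 2.0), (18.0, 4.0)],
        "registries": ("parallel", "antiparallel", "parallel"),
        "duration_ns": 30.0,
    },
}

N_TRAJECTORIES = 4
NOISE_SIGMA_NM = 0.02
BASE_SEED = 2026


def make_scripts(system: str, n_traj: int = N_TRAJECTORIES, seed: int = BASE_SEED):
    """Scripted ensemble for one system, OTs drawn from the stated mean±sd."""
    cfg = SYSTEMS[system]
    rng = np.random.default_rng(seed + (0 if system == "wt" else 1))
    scripts = []
    for _ in range(n_traj):
        times = []
        lo = 0.5
        for mean, sd in cfg["ot_mean_sd_ns"]:
            t = float(np.clip(rng.normal(mean, sd), lo, cfg["duration_ns"] - 5.0))
            times.append(t)
            lo = t + 0.5  # preserve OT2 < OT3 < OT4 ordering
        scripts.append(
            canonical_script(
                ot2_ps=times[0] * 1000.0,
                ot3_ps=times[1] * 1000.0,
                ot4_ps=times[2] * 1000.0,
                duration_ps=cfg["duration_ns"] * 1000.0,
                noise_sigma_nm=NOISE_SIGMA_NM,
                seed=int(rng.integers(2**31)),
                sequence=cfg["sequence"],
                registries=cfg["registries"],
            )
        )
    return scripts


def analysis_window(system: str, save_interval_ps: float = 10.0):
    """Post-assembly window: the portion after the latest possible OT4."""
    from oligostate.topology import AnalysisWindow

    cfg = SYSTEMS[system]
    n_frames = int(round(cfg["duration_ns"] * 1000.0 / save_interval_ps))
    first = int(round((cfg["duration_ns"] - 4.0) * 1000.0 / save_interval_ps))
    return AnalysisWindow(first, n_frames - 1, description="post-assembly")
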