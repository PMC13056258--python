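"""End-to-end per-trajectory and ensemble analysis orchestration.

``run_pipeline`` drives every stage over one or more trajectories of the
same system: per-frame oligomer partitions, secondary structure, sheet
assemblies and I–X states; windowed structural averages (Rg, SASA,
contact counts); interaction energies; π–π statistics; species
populations; the state-transition network; oligomerization times; and
the (e2e, cd) free-energy landscape.  Ensemble means ± sd are taken
across trajectories, matching how multi-run simulation studies report
their table values.  All artifacts are tidy TSV/JSON files accompanied
by a manifest (config, versions, seed).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .energetics import default_parameters, iie, pipi_interactions
from .fel import find_minima, free_energy_surface, reaction_coordinates
from .io import RunConfig
from .kinetics import (
    ensemble_oligomerization_times,
    helicity_by_oligomer_size,
    oligomerization_times,
    species_populations,
    transition_network,
)
from .metrics import contact_map, frame_metrics
from .oligomers import (
    SHEET_CLASSES,
    STATE_LABELS,
    classify_state,
    detect_oligomers,
    detect_sheets,
)
from .secondary import assign_ss_frame, ss_contents
from .topology import AnalysisWindow, SystemTopology, TrajectoryFrame

__all__ = ["EnsembleSummary", "run_pipeline", "report", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, annotated with stage name (and frame where known)."""


@dataclass
class EnsembleSummary:
    """Per-system ensemble statistics (mean ± sd across trajectories)."""

    n_trajectories: int
    window: AnalysisWindow
    ss_pct: dict[str, tuple[float, float]]
    sasa_nm2: tuple[float, float]
    rg_nm: tuple[float, float]
    n_inter: tuple[float, float]
    n_intra: tuple[float, float]
    iie_vdw_kcal: tuple[float, float]
    iie_ele_kcal: tuple[float, float]
    sheet_class_pct: dict[str, float]
    state_pct: dict[str, float]
    ot_stats: dict
    helicity_by_size: dict[int, float | None]
    fel_minima: dict | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_trajectories": self.n_trajectories,
            "window": [self.window.first_frame, self.window.last_frame],
            "ss_pct": {k: list(v) for k, v in self.ss_pct.items()},
            "sasa_nm2": list(self.sasa_nm2),
            "rg_nm": list(self.rg_nm),
            "n_inter": list(self.n_inter),
            "n_intra": list(self.n_intra),
            "iie_vdw_kcal": list(self.iie_vdw_kcal),
            "iie_ele_kcal": list(self.iie_ele_kcal),
            "sheet_class_pct": self.sheet_class_pct,
            "state_pct": self.state_pct,
            "ot_stats": self.ot_stats,
            "helicity_by_size": {str(k): v for k, v in self.helicity_by_size.items()},
            "fel_minima": self.fel_minima,
            "extras": self.extras,
        }


def _mean_sd(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def run_pipeline(
    config: RunConfig,
    topology: SystemTopology,
    trajectories: list[list[TrajectoryFrame]],
    window: AnalysisWindow | None = None,
    out_dir: str | None = None,
    fel_k: int | None = None,
    seed: int = 0,
    sasa_stride: int = 10,
    contact_stride: int = 10,
    tsv_stride: int = 1,
) -> EnsembleSummary:
    """Run every analysis stage over an ensemble of trajectories.

    Heavy per-frame observables (SASA, residue-contact maps, energies)
    are evaluated on a frame stride within the window; everything
    state-related runs on every frame.  Deterministic given inputs,
    config and seed.
    """
    if not trajectories:
        raise PipelineError("stage=input: empty trajectory list")
    n_frames = len(trajectories[0])
    for k, traj in enumerate(trajectories):
        if len(traj) != n_frames:
            raise PipelineError(
                f"stage=input: trajectory {k} length {len(traj)} != {n_frames}"
            )
    if window is None:
        window = AnalysisWindow(0, n_frames - 1)
    try:
        window.validate(n_frames)
    except ValueError as exc:
        raise PipelineError(f"stage=window: {exc}") from exc

    params = default_parameters(topology)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)

    all_partitions = []
    all_states: list[list[str]] = []
    per_traj_ot = []
    ss_pct_per_traj: list[dict[str, float]] = []
    rg_per_traj, sasa_per_traj = [], []
    ninter_per_traj, nintra_per_traj = [], []
    vdw_per_traj, ele_per_traj = [], []
    sheet_counts = {c: 0 for c in SHEET_CLASSES}
    sheet_frames_total = 0
    helicity_accum: list[dict[int, float | None]] = []
    coords_window_pts = []

    for t_idx, frames in enumerate(trajectories):
        try:
            partitions = [detect_oligomers(topology, fr,
                                           config.peptide_contact_cutoff_nm)
                          for fr in frames]
            assignments = [assign_ss_frame(topology, fr) for fr in frames]
            states = []
            for f, fr in enumerate(frames):
                sheets = detect_sheets(topology, fr, assignments[f],
                                       config.sheet_pair_cutoff_nm)
                states.append(classify_state(partitions[f], sheets).label)
                if f >= window.first_frame and f <= window.last_frame:
                    sheet_frames_total += 1
                    # population = % of window frames in which the class occurs
                    for cls in set(sheets.sheet_classes):
                        sheet_counts[cls] += 1
        except Exception as exc:
            raise PipelineError(f"stage=states trajectory={t_idx}: {exc}") from exc

        all_partitions.append(partitions)
        all_states.append(states)
        per_traj_ot.append(
            oligomerization_times(
                np.array([p.largest_size for p in partitions]),
                config.save_interval_ps,
            )
        )

        win_idx = range(window.first_frame, window.last_frame + 1)
        ss_pct_per_traj.append(
            ss_contents([assignments[f] for f in win_idx])
        )
        helicity_accum.append(
            helicity_by_oligomer_size(assignments, partitions, window)
        )

        try:
            rg_vals, sasa_vals, vdw_vals, ele_vals = [], [], [], []
            for f in range(window.first_frame, window.last_frame + 1, sasa_stride):
                m = frame_metrics(topology, frames[f],
                                  probe_nm=config.sasa_probe_nm,
                                  sasa_points=config.sasa_n_points,
                                  mass_weighted=config.mass_weighted_centroids)
                rg_vals.append(m.rg_nm)
                sasa_vals.append(m.sasa_nm2)
                e = iie(topology, frames[f], params, config.energy_cutoff_nm)
                vdw_vals.append(e.vdw)
                ele_vals.append(e.ele)
            rg_per_traj.append(float(np.mean(rg_vals)))
            sasa_per_traj.append(float(np.mean(sasa_vals)))
            vdw_per_traj.append(float(np.mean(vdw_vals)))
            ele_per_traj.append(float(np.mean(ele_vals)))
        except Exception as exc:
            raise PipelineError(f"stage=metrics trajectory={t_idx}: {exc}") from exc

        try:
            cm_frames = [frames[f] for f in
                         range(window.first_frame, window.last_frame + 1,
                               contact_stride)]
            cm = contact_map(topology, cm_frames, None,
                             config.residue_contact_cutoff_nm)
            ninter_per_traj.append(cm.n_inter)
            nintra_per_traj.append(cm.n_intra)
        except Exception as exc:
            raise PipelineError(f"stage=contacts trajectory={t_idx}: {exc}") from exc

        coords = reaction_coordinates(
            topology, [frames[f] for f in win_idx],
            config.mass_weighted_centroids,
        )
        coords_window_pts.append(coords)

        if out_dir is not None:
            _write_state_tsv(
                os.path.join(out_dir, f"states_traj{t_idx}.tsv"),
                partitions, states, config.save_interval_ps, tsv_stride,
            )

    # ensemble aggregates
    spec_pop = species_populations(all_partitions, config.save_interval_ps,
                                   topology.n_peptides)
    network = transition_network(all_states, config.save_interval_ps)
    ot_stats = ensemble_oligomerization_times(per_traj_ot)

    from .fel import ReactionCoordinates

    pooled = ReactionCoordinates(
        e2e_nm=np.concatenate([c.e2e_nm for c in coords_window_pts]),
        cd_nm=np.concatenate([c.cd_nm for c in coords_window_pts]),
    )
    fel = free_energy_surface(pooled, config.fel_bin_width_nm,
                              config.temperature_K)
    minima_dict = None
    if fel_k is not None:
        minima = find_minima(pooled, fel_k, seed=seed)
        minima_dict = {
            "k": minima.k,
            "centers": minima.centers.tolist(),
            "populations_pct": minima.populations_pct.tolist(),
        }

    # pi-pi statistics on the window (strided like energies)
    pipi_frames = []
    for frames in trajectories:
        pipi_frames.extend(
            frames[f] for f in range(window.first_frame, window.last_frame + 1,
                                     sasa_stride)
        )
    pipi = pipi_interactions(topology, pipi_frames, params,
                             config.pipi_threshold_kcal)

    helicity_by_size: dict[int, float | None] = {}
    for s in (1, 2, 3, 4):
        vals = [h[s] for h in helicity_accum if h[s] is not None]
        helicity_by_size[s] = float(np.mean(vals)) if vals else None

    ss_keys = ("beta", "helix", "turn", "coil")
    summary = EnsembleSummary(
        n_trajectories=len(trajectories),
        window=window,
        ss_pct={k: _mean_sd([d[k] for d in ss_pct_per_traj]) for k in ss_keys},
        sasa_nm2=_mean_sd(sasa_per_traj),
        rg_nm=_mean_sd(rg_per_traj),
        n_inter=_mean_sd(ninter_per_traj),
        n_intra=_mean_sd(nintra_per_traj),
        iie_vdw_kcal=_mean_sd(vdw_per_traj),
        iie_ele_kcal=_mean_sd(ele_per_traj),
        sheet_class_pct={
            c: 100.0 * sheet_counts[c] / sheet_frames_total
            if sheet_frames_total else 0.0
            for c in SHEET_CLASSES
        },
        state_pct={
            lab: float(network.populations_pct[i])
            for i, lab in enumerate(STATE_LABELS)
        },
        ot_stats=ot_stats,
        helicity_by_size=helicity_by_size,
        fel_minima=minima_dict,
        extras={
            "pipi": [
                {
                    "pair_type": p.pair_type,
                    "intra": p.intra,
                    "mean_energy_kcal": p.mean_energy,
                    "population_pct": p.population_pct(config.pipi_threshold_kcal),
                }
                for p in pipi
            ],
            "n_growth_transitions": network.n_growth(),
            "n_rearranging_transitions": network.n_rearranging(),
        },
    )

    if out_dir is not None:
        _write_species_tsv(os.path.join(out_dir, "species_populations.tsv"),
                           spec_pop, tsv_stride)
        _write_network_tsv(os.path.join(out_dir, "transition_network.tsv"), network)
        _write_fel_tsv(os.path.join(out_dir, "fel_grid.tsv"), fel)
        with open(os.path.join(out_dir, "summary.json"), "w") as fh:
            json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
        _write_manifest(os.path.join(out_dir, "manifest.json"), config, seed,
                        len(trajectories), n_frames)
    return summary


def _write_state_tsv(path, partitions, states, dt, stride=1):
    with open(path, "w") as fh:
        fh.write("frame\ttime_ps\tlargest_size\tstate_label\n")
        for f, (p, s) in enumerate(zip(partitions, states)):
            if f % stride == 0:
                fh.write(f"{f}\t{f * dt:.1f}\t{p.largest_size}\t{s}\n")


def _write_species_tsv(path, spec, stride=1):
    with open(path, "w") as fh:
        fh.write("time_ps\tfrac_monomer\tfrac_dimer\tfrac_trimer\tfrac_tetramer\n")
        for k, (t, row) in enumerate(zip(spec.time_ps, spec.fractions)):
            if k % stride == 0:
                fh.write(f"{t:.1f}\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def _write_network_tsv(path, network):
    with open(path, "w") as fh:
        fh.write("state_a\tstate_b\tcount\tfrequency_per_ns\tkind\n")
        for a, b, c, freq, kind in network.edge_list():
            fh.write(f"{a}\t{b}\t{c}\t{freq:.4f}\t{kind}\n")


def _write_fel_tsv(path, fel):
    ec = 0.5 * (fel.e2e_edges[:-1] + fel.e2e_edges[1:])
    cc = 0.5 * (fel.cd_edges[:-1] + fel.cd_edges[1:])
    with open(path, "w") as fh:
        fh.write("e2e_bin_center_nm\tcd_bin_center_nm\tP\tdG_kcal\n")
        for i, e in enumerate(ec):
            for j, c in enumerate(cc):
                dg = fel.delta_g_kcal[i, j]
                dg_s = "inf" if np.isinf(dg) else f"{dg:.6f}"
                fh.write(f"{e:.3f}\t{c:.3f}\t{fel.probability[i, j]:.8f}\t{dg_s}\n")


def _write_manifest(path, config: RunConfig, seed: int, n_traj: int, n_frames: int):
    cfg = config.to_dict()
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]
    manifest = {
        "oligostate_version": __version__,
        "numpy_version": np.__version__,
        "config": cfg,
        "config_sha256_16": cfg_hash,
        "seed": seed,
        "n_trajectories": n_traj,
        "n_frames": n_frames,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def report(summaries: dict[str, EnsembleSummary], out_path: str | None = None) -> str:
    """Render a human-readable multi-system comparison report.

    ``summaries`` maps a system name (e.g. "WT", "mutant") to its
    ensemble summary; with one system the comparison columns collapse.
    """
    if not summaries:
        raise ValueError("report requires at least one system summary")
    names = list(summaries)
    lines = []
    lines.append("Overall structural parameters (mean ± sd across trajectories)")
    header = f"{'quantity':<22}" + "".join(f"{n:>22}" for n in names)
    lines.append(header)
    lines.append("-" * len(header))

    def fmt(ms):
        return f"{ms[0]:.2f} ± {ms[1]:.2f}"

    rows = [
        ("beta %", lambda s: fmt(s.ss_pct["beta"])),
        ("helix %", lambda s: fmt(s.ss_pct["helix"])),
        ("turn %", lambda s: fmt(s.ss_pct["turn"])),
        ("coil %", lambda s: fmt(s.ss_pct["coil"])),
        ("SASA (nm^2)", lambda s: fmt(s.sasa_nm2)),
        ("Rg (nm)", lambda s: fmt(s.rg_nm)),
        ("N_inter", lambda s: fmt(s.n_inter)),
        ("N_intra", lambda s: fmt(s.n_intra)),
        ("IIEvdw (kcal/mol)", lambda s: fmt(s.iie_vdw_kcal)),
        ("IIEele (kcal/mol)", lambda s: fmt(s.iie_ele_kcal)),
    ]
    for label, f in rows:
        lines.append(f"{label:<22}" + "".join(f"{f(s):>22}" for s in summaries.values()))

    lines.append("")
    lines.append("Sheet-class populations (% of window frames)")
    for c in SHEET_CLASSES:
        lines.append(
            f"{c:<22}"
            + "".join(f"{s.sheet_class_pct[c]:>22.2f}" for s in summaries.values())
        )
    lines.append("")
    lines.append("State populations (%)")
    for lab in STATE_LABELS:
        lines.append(
            f"{lab:<22}"
            + "".join(f"{s.state_pct[lab]:>22.2f}" for s in summaries.values())
        )
    lines.append("")
    lines.append("Oligomerization times (ns, mean ± sd; n defined)")
    for key in ("OT2", "OT3", "OT4"):
        cells = []
        for s in summaries.values():
            st = s.ot_stats[key]
            if st["mean_ps"] is None:
                cells.append("undefined")
            else:
                sd = st["sd_ps"] or 0.0
                cells.append(
                    f"{st['mean_ps'] / 1000:.2f} ± {sd / 1000:.2f} (n={st['n_defined']})"
                )
        lines.append(f"{key:<22}" + "".join(f"{c:>22}" for c in cells))
    text = "\n".join(lines) + "\n"
    if out_path is not None:
        with open(out_path, "w") as fh:
            fh.write(text)
    return text
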