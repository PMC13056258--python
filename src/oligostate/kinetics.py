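"""Oligomerization times, species populations, state-transition networks,
and helicity-by-oligomer-size cross-tabulation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .oligomers import STATE_LABELS, OligomerPartition
from .topology import AnalysisWindow

__all__ = [
    "OligomerizationTimes",
    "oligomerization_times",
    "ensemble_oligomerization_times",
    "SpeciesPopulations",
    "species_populations",
    "StateTransitionNetwork",
    "transition_network",
    "helicity_by_oligomer_size",
]

_STATE_SIZE = {"I": 1, "II": 2, "III": 2, "IV": 3, "V": 3, "VI": 3,
               "VII": 4, "VIII": 4, "IX": 4, "X": 4}


@dataclass(frozen=True)
class OligomerizationTimes:
    """First-passage times (ps) to dimer/trimer/tetramer; None if never."""

    ot2_ps: float | None
    ot3_ps: float | None
    ot4_ps: float | None

    def as_tuple(self):
        return (self.ot2_ps, self.ot3_ps, self.ot4_ps)


def oligomerization_times(
    largest_sizes: np.ndarray, save_interval_ps: float
) -> OligomerizationTimes:
    """OT2/OT3/OT4 from a per-frame largest-oligomer-size sequence.

    OTn is the time of the first frame whose largest component reaches
    size ≥ n (a dimer present at frame 0 gives OT2 = 0); a size never
    reached is reported as None, never as 0.
    """
    sizes = np.asarray(largest_sizes, dtype=int)
    out = []
    for n in (2, 3, 4):
        hits = np.nonzero(sizes >= n)[0]
        out.append(float(hits[0] * save_interval_ps) if hits.size else None)
    return OligomerizationTimes(*out)


def ensemble_oligomerization_times(
    per_trajectory: list[OligomerizationTimes],
) -> dict[str, dict[str, float | int | None]]:
    """Mean ± sd (across trajectories) of each OT; undefined values excluded."""
    summary: dict[str, dict[str, float | int | None]] = {}
    for key, pick in (("OT2", 0), ("OT3", 1), ("OT4", 2)):
        vals = [ot.as_tuple()[pick] for ot in per_trajectory]
        defined = np.array([v for v in vals if v is not None], dtype=float)
        summary[key] = {
            "mean_ps": float(defined.mean()) if defined.size else None,
            "sd_ps": float(defined.std(ddof=1)) if defined.size > 1 else 0.0
            if defined.size else None,
            "n_defined": int(defined.size),
            "n_undefined": len(vals) - int(defined.size),
        }
    return summary


@dataclass
class SpeciesPopulations:
    """Peptide-weighted fractions of monomer/dimer/trimer/tetramer vs time.

    ``fractions[f, s-1]`` is the fraction of peptides residing in
    components of size s at frame f (rows sum to 1); for an ensemble the
    mean over trajectories is stored with the per-trajectory count.
    """

    time_ps: np.ndarray
    fractions: np.ndarray  # (n_frames, 4)
    n_trajectories: int = 1


def species_populations(
    partitions_per_traj: list[list[OligomerPartition]],
    save_interval_ps: float,
    n_peptides: int = 4,
) -> SpeciesPopulations:
    """Ensemble-mean species fractions per time point.

    A peptide inside a size-s component contributes to the size-s
    fraction, so each frame's fractions sum to exactly 1.  All
    trajectories must share cadence and length.
    """
    if not partitions_per_traj:
        raise ValueError("no trajectories")
    n_frames = len(partitions_per_traj[0])
    for k, traj in enumerate(partitions_per_traj):
        if len(traj) != n_frames:
            raise ValueError(
                f"trajectory {k} has {len(traj)} frames, expected {n_frames}"
            )
    acc = np.zeros((n_frames, 4))
    for traj in partitions_per_traj:
        for f, part in enumerate(traj):
            for comp in part.components:
                s = len(comp)
                acc[f, s - 1] += s / n_peptides
    acc /= len(partitions_per_traj)
    return SpeciesPopulations(
        time_ps=np.arange(n_frames) * save_interval_ps,
        fractions=acc,
        n_trajectories=len(partitions_per_traj),
    )


@dataclass
class StateTransitionNetwork:
    """Pooled state populations and consecutive-frame transition counts.

    ``counts`` is the symmetric (undirected) 10×10 matrix excluding
    self-transitions; ``directed`` keeps from→to counts including the
    diagonal.  Growth transitions connect states of different oligomer
    size, rearranging transitions states of equal size.
    """

    counts: np.ndarray     # (10, 10) symmetric, zero diagonal
    directed: np.ndarray   # (10, 10)
    populations_pct: np.ndarray  # (10,)
    span_ns: float

    def edge_list(self):
        edges = []
        for a in range(len(STATE_LABELS)):
            for b in range(a + 1, len(STATE_LABELS)):
                c = self.counts[a, b]
                if c > 0:
                    la, lb = STATE_LABELS[a], STATE_LABELS[b]
                    kind = ("rearranging" if _STATE_SIZE[la] == _STATE_SIZE[lb]
                            else "growth")
                    freq = c / self.span_ns if self.span_ns > 0 else 0.0
                    edges.append((la, lb, int(c), freq, kind))
        return edges

    def n_growth(self) -> int:
        return sum(c for _, _, c, _, k in self.edge_list() if k == "growth")

    def n_rearranging(self) -> int:
        return sum(c for _, _, c, _, k in self.edge_list() if k == "rearranging")

    def count(self, a: str, b: str) -> int:
        return int(self.counts[STATE_LABELS.index(a), STATE_LABELS.index(b)])


def transition_network(
    state_sequences: list[list[str]], save_interval_ps: float = 10.0
) -> StateTransitionNetwork:
    """Pool consecutive-frame state transitions over an ensemble."""
    k = len(STATE_LABELS)
    counts = np.zeros((k, k))
    directed = np.zeros((k, k))
    pop = np.zeros(k)
    n_frames_total = 0
    n_steps_total = 0
    for seq in state_sequences:
        if len(seq) < 1:
            raise ValueError("empty state sequence")
        idx = [STATE_LABELS.index(s) for s in seq]
        for s in idx:
            pop[s] += 1
        n_frames_total += len(idx)
        n_steps_total += max(len(idx) - 1, 0)
        for a, b in zip(idx[:-1], idx[1:]):
            directed[a, b] += 1
            if a != b:
                counts[a, b] += 1
                counts[b, a] += 1
    if n_frames_total == 0:
        raise ValueError("no frames")
    span_ns = n_steps_total * save_interval_ps / 1000.0
    return StateTransitionNetwork(
        counts=counts,
        directed=directed,
        populations_pct=100.0 * pop / n_frames_total,
        span_ns=span_ns,
    )


def helicity_by_oligomer_size(
    assignments: list[list[list[str]]],
    partitions: list[OligomerPartition],
    window: AnalysisWindow | None = None,
) -> dict[int, float | None]:
    """Mean helical residue percentage of peptides in size-s components.

    Returns {1: %, 2: %, 3: %, 4: %}, with None for sizes never populated
    inside the window.
    """
    if len(assignments) != len(partitions):
        raise ValueError("assignments and partitions must align frame-wise")
    if window is None:
        window = AnalysisWindow(0, len(partitions) - 1)
    window.validate(len(partitions))
    frac_sum = {s: 0.0 for s in (1, 2, 3, 4)}
    n_obs = {s: 0 for s in (1, 2, 3, 4)}
    for f in range(window.first_frame, window.last_frame + 1):
        sizes = partitions[f].sizes_by_peptide()
        for p, labels in enumerate(assignments[f]):
            s = int(sizes[p])
            helical = sum(1 for lab in labels if lab == "helix") / len(labels)
            frac_sum[s] += helical
            n_obs[s] += 1
    return {
        s: (100.0 * frac_sum[s] / n_obs[s]) if n_obs[s] else None
        for s in (1, 2, 3, 4)
    }
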