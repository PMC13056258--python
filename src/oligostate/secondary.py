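"""Dihedral measurement and four-class secondary-structure assignment.

The assigner is a deterministic φ/ψ-region labeler with a chain-bend test
for turns, covering the four classes used throughout the analysis (β,
helix, turn, coil).  Region boundaries (degrees):

* β:     φ ∈ [−180, −90] and ψ ∈ [90, 180] ∪ [−180, −170]
* helix: φ ∈ [−100, −30] and ψ ∈ [−80, −5]
* turn:  neither of the above, Cα(i−2)→Cα(i+2) distance < 1.0 nm, and
  both sequence neighbours not labelled β
* coil:  everything else; chain-terminal residues (undefined φ or ψ) are
  always coil.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .topology import SystemTopology, TrajectoryFrame

__all__ = [
    "dihedral",
    "measure_dihedrals",
    "DihedralProfile",
    "assign_ss",
    "assign_ss_frame",
    "ss_contents",
    "ss_transitions",
    "SSTransitionMatrix",
    "SS_CLASSES",
]

SS_CLASSES = ("beta", "helix", "turn", "coil")


def _cross_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    out[..., 0] = a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1]
    out[..., 1] = a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2]
    out[..., 2] = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    return out


def torsions(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
             ) -> np.ndarray:
    """IUPAC-signed torsion angles (degrees) for batched 4-point chains.

    Inputs are (n, 3) arrays; returns (n,).  Degenerate (collinear)
    geometries yield NaN rather than raising.
    """
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.sqrt((b1**2).sum(axis=-1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        b1u = b1 / nb1
        v = b0 - (b0 * b1u).sum(axis=-1, keepdims=True) * b1u
        w = b2 - (b2 * b1u).sum(axis=-1, keepdims=True) * b1u
        x = (v * w).sum(axis=-1)
        y = (_cross_rows(b1u, v) * w).sum(axis=-1)
        ang = np.degrees(np.arctan2(y, x))
    bad = (
        (nb1[..., 0] < 1e-12)
        | (np.sqrt((v**2).sum(axis=-1)) < 1e-10)
        | (np.sqrt((w**2).sum(axis=-1)) < 1e-10)
    )
    ang = np.where(bad, np.nan, ang)
    return ang


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """IUPAC-signed torsion angle p0-p1-p2-p3 in degrees; NaN if collinear."""
    return float(
        torsions(np.asarray(p0, float)[None], np.asarray(p1, float)[None],
                 np.asarray(p2, float)[None], np.asarray(p3, float)[None])[0]
    )


@dataclass
class DihedralProfile:
    """Per-residue (φ, ψ) in degrees; NaN where undefined (termini)."""

    phi: np.ndarray
    psi: np.ndarray

    def defined(self, i: int) -> bool:
        return not (np.isnan(self.phi[i]) or np.isnan(self.psi[i]))


def measure_dihedrals(
    topology: SystemTopology, frame: TrajectoryFrame, peptide: int
) -> DihedralProfile:
    """Backbone φᵢ = C(i−1)-N(i)-CA(i)-C(i), ψᵢ = N(i)-CA(i)-C(i)-N(i+1)."""
    pep = topology.peptides[peptide]
    if not pep.backbone_index_map:
        raise ValueError(f"peptide {peptide} has no backbone index map")
    n = pep.n_residues
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    X = frame.coordinates
    bb = np.array([pep.backbone_index_map[i] for i in range(n)])  # (n, 3): N, CA, C
    if n > 1:
        phi[1:] = torsions(X[bb[:-1, 2]], X[bb[1:, 0]], X[bb[1:, 1]], X[bb[1:, 2]])
        psi[:-1] = torsions(X[bb[:-1, 0]], X[bb[:-1, 1]], X[bb[:-1, 2]], X[bb[1:, 0]])
    return DihedralProfile(phi=phi, psi=psi)


def _region_label(phi: float, psi: float) -> str | None:
    if -180.0 <= phi <= -90.0 and (90.0 <= psi <= 180.0 or -180.0 <= psi <= -170.0):
        return "beta"
    if -100.0 <= phi <= -30.0 and -80.0 <= psi <= -5.0:
        return "helix"
    return None


def assign_ss(
    profile: DihedralProfile,
    ca_coords: np.ndarray,
    bend_cutoff_nm: float = 1.0,
) -> list[str]:
    """Label each residue of one peptide for one frame.

    ``ca_coords`` is the (n_res, 3) Cα coordinate array used by the bend
    test.  Assignment is pure: identical (φ, ψ, geometry) gives identical
    labels.
    """
    n = len(profile.phi)
    labels: list[str | None] = [None] * n
    for i in range(n):
        if not profile.defined(i):
            labels[i] = "coil"
        else:
            labels[i] = _region_label(float(profile.phi[i]), float(profile.psi[i]))
    # second pass: bend-geometry turns among unlabelled residues
    for i in range(n):
        if labels[i] is not None:
            continue
        is_turn = False
        if 2 <= i <= n - 3:
            span = float(np.linalg.norm(ca_coords[i + 2] - ca_coords[i - 2]))
            neighbours_non_beta = (labels[i - 1] != "beta") and (labels[i + 1] != "beta")
            is_turn = span < bend_cutoff_nm and neighbours_non_beta
        labels[i] = "turn" if is_turn else "coil"
    return labels  # type: ignore[return-value]


def assign_ss_frame(
    topology: SystemTopology, frame: TrajectoryFrame, bend_cutoff_nm: float = 1.0
) -> list[list[str]]:
    """Per-peptide, per-residue labels for one frame."""
    out = []
    for p, pep in enumerate(topology.peptides):
        prof = measure_dihedrals(topology, frame, p)
        ca = frame.coordinates[pep.ca_indices()]
        out.append(assign_ss(prof, ca, bend_cutoff_nm))
    return out


def ss_contents(assignments: list[list[list[str]]]) -> dict[str, float]:
    """Percent of residues per class over frames × peptides × residues."""
    counts = {c: 0 for c in SS_CLASSES}
    total = 0
    for frame_labels in assignments:
        for pep_labels in frame_labels:
            for lab in pep_labels:
                counts[lab] += 1
                total += 1
    if total == 0:
        raise ValueError("no residues to summarize")
    return {c: 100.0 * counts[c] / total for c in SS_CLASSES}


def per_residue_contents(assignments: list[list[list[str]]]) -> np.ndarray:
    """(n_res, 4) percent per residue position, classes in SS_CLASSES order."""
    n_res = len(assignments[0][0])
    counts = np.zeros((n_res, len(SS_CLASSES)))
    n_obs = 0
    for frame_labels in assignments:
        for pep_labels in frame_labels:
            n_obs += 1
            for i, lab in enumerate(pep_labels):
                counts[i, SS_CLASSES.index(lab)] += 1
    return 100.0 * counts / max(n_obs, 1)


@dataclass
class SSTransitionMatrix:
    """Residue-level secondary-structure transition statistics.

    ``undirected[r]`` is the per-residue symmetric 4×4 count matrix of
    label changes between consecutive frames; ``directed`` keeps the
    from→to asymmetry.  ``frequency_per_ns`` normalizes the pooled
    undirected counts by the observation span.
    """

    undirected: np.ndarray  # (n_res, 4, 4)
    directed: np.ndarray    # (n_res, 4, 4)
    n_steps: int
    span_ns: float

    def pooled(self) -> np.ndarray:
        return self.undirected.sum(axis=0)

    def pair_count(self, a: str, b: str) -> float:
        ia, ib = SS_CLASSES.index(a), SS_CLASSES.index(b)
        return float(self.pooled()[ia, ib])

    def frequency_per_ns(self) -> np.ndarray:
        if self.span_ns <= 0:
            return np.zeros_like(self.undirected)
        return self.undirected / self.span_ns

    def total_transitions(self) -> float:
        """Off-diagonal label changes, pooled over residues."""
        pool = self.pooled()
        return float(pool.sum() - np.trace(pool))


def ss_transitions(
    assignments: list[list[list[str]]],
    save_interval_ps: float = 10.0,
) -> SSTransitionMatrix:
    """Count label changes between consecutive frames, per residue.

    ``assignments[f][p][i]`` indexes frame, peptide, residue.  Counts are
    pooled over peptides; the undirected matrix bins by unordered label
    pair (stored symmetrically, each change counted once per (a, b) cell
    and mirrored), with self-pairs on the diagonal.
    """
    n_frames = len(assignments)
    if n_frames == 0:
        raise ValueError("no frames")
    n_res = len(assignments[0][0])
    k = len(SS_CLASSES)
    undirected = np.zeros((n_res, k, k))
    directed = np.zeros((n_res, k, k))
    for f in range(1, n_frames):
        for prev_pep, cur_pep in zip(assignments[f - 1], assignments[f]):
            for i, (a, b) in enumerate(zip(prev_pep, cur_pep)):
                ia, ib = SS_CLASSES.index(a), SS_CLASSES.index(b)
                directed[i, ia, ib] += 1
                if ia == ib:
                    undirected[i, ia, ib] += 1
                else:
                    undirected[i, min(ia, ib), max(ia, ib)] += 1
                    undirected[i, max(ia, ib), min(ia, ib)] += 1
    span_ns = (n_frames - 1) * save_interval_ps / 1000.0
    return SSTransitionMatrix(
        undirected=undirected,
        directed=directed,
        n_steps=n_frames - 1,
        span_ns=span_ns,
    )
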