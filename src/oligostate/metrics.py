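"""Geometric observables: distances, gyration radius, SASA, contacts."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .topology import AnalysisWindow, SystemTopology, TrajectoryFrame

__all__ = [
    "min_distance",
    "radius_of_gyration",
    "sasa",
    "end_to_end",
    "centroid_distances",
    "residue_contacts",
    "contact_map",
    "ContactSummary",
    "StructureMetrics",
    "DEFAULT_RADII_NM",
    "frame_metrics",
]

#: default van der Waals radii by element (nm)
DEFAULT_RADII_NM = {"C": 0.17, "N": 0.155, "O": 0.152, "H": 0.12, "S": 0.18}


def min_distance(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Exact minimum atom–atom distance (nm) between two coordinate sets."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("min_distance requires two non-empty atom groups")
    return float(cdist(a.reshape(-1, 3), b.reshape(-1, 3)).min())


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Mass-weighted radius of gyration, sqrt(Σ mᵢ‖rᵢ−r̄‖²/Σ mᵢ), in nm.

    With ``masses=None`` all atoms get unit mass (appropriate for the
    synthetic pseudo-atom systems, whose elements are nominal).
    """
    c = np.asarray(coords, dtype=float).reshape(-1, 3)
    if c.shape[0] == 0:
        raise ValueError("radius_of_gyration requires at least one atom")
    if masses is None:
        m = np.ones(c.shape[0])
    else:
        m = np.asarray(masses, dtype=float)
        if (m <= 0).any():
            raise ValueError("masses must be positive")
    com = (c * m[:, None]).sum(axis=0) / m.sum()
    return float(np.sqrt((m * ((c - com) ** 2).sum(axis=1)).sum() / m.sum()))


_SPHERE_CACHE: dict[int, np.ndarray] = {}


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-spiral lattice)."""
    if n in _SPHERE_CACHE:
        return _SPHERE_CACHE[n]
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    pts = np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)],
        axis=1,
    )
    _SPHERE_CACHE[n] = pts
    return pts


def sasa(
    coords: np.ndarray,
    radii_nm: np.ndarray,
    probe_nm: float = 0.14,
    n_points: int = 960,
) -> tuple[float, np.ndarray]:
    """Shrake–Rupley solvent-accessible surface area (nm²).

    Each atom's extended sphere (radius rᵢ + probe) is sampled with
    ``n_points`` quasi-uniform test points; a point is buried if it falls
    inside any neighbour's extended sphere.  Returns (total, per-atom).
    """
    if n_points < 32:
        raise ValueError("n_points < 32 is below the accuracy floor")
    c = np.asarray(coords, dtype=float).reshape(-1, 3)
    r = np.asarray(radii_nm, dtype=float)
    if (r <= 0).any():
        raise ValueError("radii must be positive")
    if r.shape[0] != c.shape[0]:
        raise ValueError("one radius per atom required")
    ext = r + probe_nm
    sphere = _fibonacci_sphere(n_points)
    n = c.shape[0]
    per_atom = np.zeros(n)
    # neighbour lists via full distance matrix (systems here are small)
    dmat = cdist(c, c)
    for i in range(n):
        neigh = np.where((dmat[i] < ext[i] + ext) & (np.arange(n) != i))[0]
        pts = c[i] + ext[i] * sphere
        if neigh.size:
            d2 = ((pts[:, None, :] - c[neigh][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (ext[neigh] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[i] = frac * 4.0 * np.pi * ext[i] ** 2
    return float(per_atom.sum()), per_atom


def system_radii(topology: SystemTopology) -> np.ndarray:
    """Per-atom radii from the element default table (nm)."""
    return np.array(
        [DEFAULT_RADII_NM.get(el.upper(), 0.17) for el in topology.elements()]
    )


def end_to_end(topology: SystemTopology, frame: TrajectoryFrame, peptide: int) -> float:
    """Cα(first)–Cα(last) distance (nm) over the non-cap residues."""
    pep = topology.peptides[peptide]
    if pep.n_residues < 2:
        raise ValueError("end_to_end requires a peptide of >= 2 residues")
    ca = pep.ca_indices()
    a = frame.coordinates[ca[0]]
    b = frame.coordinates[ca[-1]]
    return float(np.linalg.norm(a - b))


def centroid_distances(
    topology: SystemTopology, frame: TrajectoryFrame, mass_weighted: bool = False
) -> np.ndarray:
    """All C(N,2) pairwise centroid distances (nm), lexicographic pair order.

    Centroids are unweighted geometric centers by default (synthetic
    pseudo-atoms have uniform nominal masses); set ``mass_weighted`` to
    use simple element masses instead.
    """
    centers = []
    masses = _element_masses(topology) if mass_weighted else None
    for p in range(topology.n_peptides):
        idx = topology.peptide_atom_indices(p)
        c = frame.coordinates[idx]
        if masses is None:
            centers.append(c.mean(axis=0))
        else:
            m = masses[idx]
            centers.append((c * m[:, None]).sum(axis=0) / m.sum())
    centers = np.array(centers)
    out = []
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            out.append(np.linalg.norm(centers[i] - centers[j]))
    return np.array(out)


_ELEMENT_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}


def _element_masses(topology: SystemTopology) -> np.ndarray:
    return np.array([_ELEMENT_MASS.get(el.upper(), 12.011) for el in topology.elements()])


@dataclass
class ContactSummary:
    """Residue–residue contact counts and the inter-peptide frequency map."""

    n_inter: float
    n_intra: float
    inter_map: np.ndarray  # (n_res, n_res) frequencies in [0, 1]


@dataclass
class StructureMetrics:
    """Whole-system geometric observables for one frame."""

    rg_nm: float
    sasa_nm2: float
    e2e_nm: np.ndarray       # per-peptide
    pair_distances_nm: np.ndarray  # C(N,2) centroid distances


def _residue_coords(topology: SystemTopology, frame: TrajectoryFrame
                    ) -> list[list[np.ndarray]]:
    out = []
    for pep in topology.peptides:
        out.append([frame.coordinates[r.atom_indices] for r in pep.noncap_residues])
    return out


def residue_contacts(
    topology: SystemTopology, frame: TrajectoryFrame, cutoff_nm: float = 0.45
) -> tuple[int, int, np.ndarray]:
    """Per-frame contact counts.

    Returns (N_inter, N_intra, inter_indicator) where the indicator is the
    symmetric (n_res, n_res) 0/1 sum over ordered peptide pairs.  A residue
    pair is in contact when its minimum atom distance is ≤ cutoff; the
    intramolecular count excludes sequence neighbours (|i−j| < 2), which
    are trivially within the cutoff.
    """
    res_coords = _residue_coords(topology, frame)
    n_pep = topology.n_peptides
    n_res = max(len(rc) for rc in res_coords)

    n_intra = 0
    for rc in res_coords:
        for i in range(len(rc)):
            for j in range(i + 2, len(rc)):
                if min_distance(rc[i], rc[j]) <= cutoff_nm:
                    n_intra += 1

    n_inter = 0
    indicator = np.zeros((n_res, n_res))
    for a in range(n_pep):
        for b in range(a + 1, n_pep):
            for i in range(len(res_coords[a])):
                for j in range(len(res_coords[b])):
                    if min_distance(res_coords[a][i], res_coords[b][j]) <= cutoff_nm:
                        n_inter += 1
                        indicator[i, j] += 1
                        if i != j:
                            indicator[j, i] += 1
    return n_inter, n_intra, indicator


def contact_map(
    topology: SystemTopology,
    frames: list[TrajectoryFrame],
    window: AnalysisWindow | None = None,
    cutoff_nm: float = 0.45,
) -> ContactSummary:
    """Window-averaged contact statistics and inter-residue frequency map.

    Map frequencies are normalized per frame and ordered peptide pair, so
    a residue pair that is in contact across every peptide pair of every
    frame scores 1.0.
    """
    if window is None:
        window = AnalysisWindow(0, len(frames) - 1)
    window.validate(len(frames))
    sel = frames[window.slice()]
    n_pep = topology.n_peptides
    n_ordered = n_pep * (n_pep - 1)

    tot_inter = tot_intra = 0.0
    acc = None
    for fr in sel:
        ni, na, ind = residue_contacts(topology, fr, cutoff_nm)
        tot_inter += ni
        tot_intra += na
        acc = ind if acc is None else acc + ind
    n_frames = len(sel)
    n_unordered = n_ordered // 2
    # a contact adds 1 to cell (i, j) (mirrored to (j, i)); the maximum per
    # cell is one contact per unordered peptide pair per frame
    freq = acc / (n_frames * n_unordered) if acc is not None else None
    return ContactSummary(
        n_inter=tot_inter / n_frames,
        n_intra=tot_intra / n_frames,
        inter_map=freq,
    )


def frame_metrics(
    topology: SystemTopology,
    frame: TrajectoryFrame,
    probe_nm: float = 0.14,
    sasa_points: int = 960,
    mass_weighted: bool = False,
) -> StructureMetrics:
    """Rg, SASA, per-peptide end-to-end, and centroid pair distances."""
    masses = _element_masses(topology) if mass_weighted else None
    rg = radius_of_gyration(frame.coordinates, masses)
    total_sasa, _ = sasa(frame.coordinates, system_radii(topology), probe_nm, sasa_points)
    e2e = np.array(
        [end_to_end(topology, frame, p) for p in range(topology.n_peptides)]
    )
    cd = centroid_distances(topology, frame, mass_weighted)
    return StructureMetrics(rg_nm=rg, sasa_nm2=total_sasa, e2e_nm=e2e,
                            pair_distances_nm=cd)
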