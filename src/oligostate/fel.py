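"""Two-dimensional free-energy landscape over (e2e, cd) coordinates.

ΔG(V) = −kB·T·[ln P(V) − ln P_max] over a 2D histogram of the per-frame
reaction coordinates: e2e, the sum of the four peptides' end-to-end
distances, and cd, the sum of the six pairwise centroid distances (nm).
Minima are characterized by k-means clustering of the raw frame points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .io import BOLTZMANN_KCAL
from .metrics import centroid_distances, end_to_end
from .topology import SystemTopology, TrajectoryFrame

__all__ = [
    "ReactionCoordinates",
    "reaction_coordinates",
    "FreeEnergySurface",
    "free_energy_surface",
    "FELMinima",
    "find_minima",
]


@dataclass
class ReactionCoordinates:
    """Per-frame (e2e, cd) series in nm."""

    e2e_nm: np.ndarray
    cd_nm: np.ndarray

    def points(self) -> np.ndarray:
        return np.stack([self.e2e_nm, self.cd_nm], axis=1)


def reaction_coordinates(
    topology: SystemTopology,
    frames: list[TrajectoryFrame],
    mass_weighted: bool = False,
) -> ReactionCoordinates:
    e2e = np.empty(len(frames))
    cd = np.empty(len(frames))
    for f, fr in enumerate(frames):
        e2e[f] = sum(
            end_to_end(topology, fr, p) for p in range(topology.n_peptides)
        )
        cd[f] = centroid_distances(topology, fr, mass_weighted).sum()
    return ReactionCoordinates(e2e_nm=e2e, cd_nm=cd)


@dataclass
class FreeEnergySurface:
    """Binned ΔG grid; empty bins carry +inf (never 0)."""

    e2e_edges: np.ndarray
    cd_edges: np.ndarray
    probability: np.ndarray  # (n_e2e_bins, n_cd_bins), sums to 1
    delta_g_kcal: np.ndarray  # same shape; min over occupied bins == 0
    temperature_K: float

    @property
    def kBT(self) -> float:
        return BOLTZMANN_KCAL * self.temperature_K

    def occupied(self) -> np.ndarray:
        return self.probability > 0


def free_energy_surface(
    coords: ReactionCoordinates,
    bin_width_nm: float = 0.1,
    temperature_K: float = 310.0,
) -> FreeEnergySurface:
    """ΔG(bin) = −kB·T·[ln P(bin) − ln P_max] over a uniform 2D histogram."""
    pts = coords.points()
    if pts.shape[0] == 0:
        raise ValueError("free_energy_surface requires at least one frame")
    if bin_width_nm <= 0:
        raise ValueError("bin width must be positive")

    def edges(v: np.ndarray) -> np.ndarray:
        lo = np.floor(v.min() / bin_width_nm) * bin_width_nm
        hi = np.ceil(v.max() / bin_width_nm) * bin_width_nm
        if hi <= lo:
            hi = lo + bin_width_nm
        n = int(round((hi - lo) / bin_width_nm))
        return lo + bin_width_nm * np.arange(n + 1)

    e_edges = edges(coords.e2e_nm)
    c_edges = edges(coords.cd_nm)
    H, _, _ = np.histogram2d(coords.e2e_nm, coords.cd_nm, bins=[e_edges, c_edges])
    P = H / H.sum()
    pmax = P.max()
    with np.errstate(divide="ignore"):
        dg = np.where(P > 0, -BOLTZMANN_KCAL * temperature_K * (np.log(P) - np.log(pmax)),
                      np.inf)
    return FreeEnergySurface(
        e2e_edges=e_edges, cd_edges=c_edges, probability=P,
        delta_g_kcal=dg, temperature_K=temperature_K,
    )


@dataclass
class FELMinima:
    """k-means characterization of FEL basins.

    ``centers`` are (e2e, cd) in nm; ``populations_pct`` the percentage of
    frames per cluster, ordered by population descending.
    """

    k: int
    centers: np.ndarray          # (k, 2)
    populations_pct: np.ndarray  # (k,)


def find_minima(coords: ReactionCoordinates, k: int, seed: int = 0) -> FELMinima:
    """k-means (k-means++ init, 20 restarts, fixed seed) on raw frame points."""
    pts = coords.points()
    n_distinct = np.unique(pts, axis=0).shape[0]
    if k < 1 or k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct points")
    km = KMeans(n_clusters=k, init="k-means++", n_init=20, random_state=seed)
    labels = km.fit_predict(pts)
    pops = np.array([100.0 * (labels == c).mean() for c in range(k)])
    order = np.argsort(-pops, kind="stable")
    return FELMinima(k=k, centers=km.cluster_centers_[order],
                     populations_pct=pops[order])
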