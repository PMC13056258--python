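"""Synthetic four-peptide trajectories with scripted aggregation.

The generator stands in for molecular dynamics: it produces coordinate
series with *known* oligomerization, conformation, and β-sheet-registry
ground truth, so that every analysis stage can be validated exactly.

Peptides are reduced models: backbone N, CA, C per residue built from
target (φ, ψ, ω) dihedrals by internal-coordinate (NeRF) chain extension,
one pseudo side-chain site per residue along the CA→Cβ direction at the
residue's side-chain centroid distance, and a planar six-site aromatic
ring for phenylalanine.  Four peptides start at the vertices of a regular
tetrahedron (default edge 3.5 nm, minimum inter-peptide distance > 2 nm,
matching a ~16 mM four-peptide box).  A script of timed events then
drives association/dissociation, coil/β/helix conformational switching,
and parallel/antiparallel β-registry; docked geometries are constructed
by rigid placement, with a tethered random-walk drift of each cluster and
i.i.d. Gaussian coordinate noise on top.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .topology import (
    GroundTruthLabels,
    ONE_TO_THREE,
    PeptideTopology,
    Residue,
    SystemTopology,
    TrajectoryFrame,
)

__all__ = [
    "BackboneSpec",
    "AssemblyScript",
    "Event",
    "build_backbone",
    "build_peptide",
    "place_initial",
    "generate",
    "molar_concentration_mM",
    "CONFORMER_DIHEDRALS",
    "canonical_script",
    "SIDECHAIN_CENTROID_NM",
]

# idealized (phi, psi) per scripted conformer, degrees.  "coil" is a
# PPII-like conformer so the dihedral-region assigner labels it coil
# (outside both the beta and helix boxes, too extended for the bend test).
CONFORMER_DIHEDRALS = {
    "beta": (-139.0, 135.0),
    "helix": (-57.0, -47.0),
    "coil": (-75.0, 145.0),
}

#: side-chain centroid distance from CA (nm), a coarse united-residue size
SIDECHAIN_CENTROID_NM = {
    "ALA": 0.152, "ARG": 0.40, "ASN": 0.25, "ASP": 0.25, "CYS": 0.21,
    "GLN": 0.31, "GLU": 0.31, "GLY": 0.10, "HIS": 0.31, "ILE": 0.23,
    "LEU": 0.26, "LYS": 0.35, "MET": 0.31, "PHE": 0.34, "PRO": 0.19,
    "SER": 0.19, "THR": 0.19, "TRP": 0.38, "TYR": 0.39, "VAL": 0.20,
}

_RING_NAMES = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
_RING_EDGE_NM = 0.139
_RING_CENTER_FROM_CA_NM = 0.35


@dataclass(frozen=True)
class BackboneSpec:
    """Per-chain target dihedrals and standard backbone geometry."""

    phi_deg: tuple[float, ...]
    psi_deg: tuple[float, ...]
    omega_deg: tuple[float, ...] | None = None
    bond_n_ca_nm: float = 0.1458
    bond_ca_c_nm: float = 0.1525
    bond_c_n_nm: float = 0.1329
    angle_n_ca_c_deg: float = 111.0
    angle_ca_c_n_deg: float = 116.6
    angle_c_n_ca_deg: float = 121.9

    @classmethod
    def uniform(cls, n_residues: int, phi: float, psi: float) -> "BackboneSpec":
        return cls(phi_deg=(phi,) * n_residues, psi_deg=(psi,) * n_residues)

    @classmethod
    def for_conformer(cls, n_residues: int, conformer: str) -> "BackboneSpec":
        phi, psi = CONFORMER_DIHEDRALS[conformer]
        return cls.uniform(n_residues, phi, psi)

    @classmethod
    def hairpin(cls, n_residues: int = 7) -> "BackboneSpec":
        """β-hairpin-like compact conformer: β flanks, 3-residue apex.

        The apex dihedrals fall outside both the β and helix regions, so
        the region assigner labels the mid-apex residue turn (bend test)
        and the flanking strand residues β.
        """
        if n_residues < 5:
            raise ValueError("hairpin needs >= 5 residues")
        beta_phi, beta_psi = CONFORMER_DIHEDRALS["beta"]
        apex = [(-110.0, -30.0), (-110.0, 30.0), (-110.0, -30.0)]
        n_flank = n_residues - 3
        left = n_flank // 2 + n_flank % 2
        right = n_flank // 2
        phi = [beta_phi] * left + [a[0] for a in apex] + [beta_phi] * right
        psi = [beta_psi] * left + [a[1] for a in apex] + [beta_psi] * right
        return cls(phi_deg=tuple(phi), psi_deg=tuple(psi))

    def omega(self, i: int) -> float:
        if self.omega_deg is None:
            return 180.0
        return self.omega_deg[i]


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF: place atom d given chain a-b-c, |cd|=bond, angle(b,c,d), torsion(a,b,c,d)."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValueError("collinear reference atoms in chain construction")
    n /= norm
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(sequence: str, spec: BackboneSpec) -> tuple[PeptideTopology, np.ndarray]:
    """Construct a peptide from a one-letter sequence and target dihedrals.

    Returns a :class:`PeptideTopology` (atom indices local, starting at 0)
    plus coordinates in nm.  φ of the first residue and ψ of the last are
    geometric free parameters and are realized with the requested values
    where defined; measured interior φ/ψ reproduce the spec to better than
    1e-3 degrees (the construction is exact up to floating point).
    """
    sequence = sequence.strip().upper()
    if not sequence:
        raise ValueError("empty sequence")
    n = len(sequence)
    if len(spec.phi_deg) != n or len(spec.psi_deg) != n:
        raise ValueError("dihedral list lengths must match sequence length")
    for vals in (spec.phi_deg, spec.psi_deg):
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("non-finite dihedral angle")

    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))

    # first residue: N at origin, CA on +x, C in the xy-plane
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (spec.bond_n_ca_nm, 0.0, 0.0)
    ang = math.radians(spec.angle_n_ca_c_deg)
    C[0] = CA[0] + spec.bond_ca_c_nm * np.array([-math.cos(ang), math.sin(ang), 0.0])

    for i in range(1, n):
        N[i] = _place_atom(N[i - 1], CA[i - 1], C[i - 1],
                           spec.bond_c_n_nm, spec.angle_ca_c_n_deg,
                           spec.psi_deg[i - 1])
        CA[i] = _place_atom(CA[i - 1], C[i - 1], N[i],
                            spec.bond_n_ca_nm, spec.angle_c_n_ca_deg,
                            spec.omega(i - 1))
        C[i] = _place_atom(C[i - 1], N[i], CA[i],
                           spec.bond_ca_c_nm, spec.angle_n_ca_c_deg,
                           spec.phi_deg[i])

    coords: list[np.ndarray] = []
    residues: list[Residue] = []
    backbone_map: dict[int, tuple[int, int, int]] = {}
    idx = 0
    for i, code in enumerate(sequence):
        res3 = ONE_TO_THREE.get(code)
        if res3 is None:
            raise ValueError(f"unknown residue code {code!r}")
        names = ["N", "CA", "C"]
        elements = ["N", "C", "C"]
        res_coords = [N[i], CA[i], C[i]]

        cb_dir = _cb_direction(N[i], CA[i], C[i])
        cb_len = SIDECHAIN_CENTROID_NM.get(res3, 0.25)
        if res3 != "GLY":
            names.append("CB")
            elements.append("C")
            res_coords.append(CA[i] + cb_len * cb_dir)
        if res3 == "PHE":
            center = CA[i] + _RING_CENTER_FROM_CA_NM * cb_dir
            for name, pos in zip(_RING_NAMES, _ring_sites(center, cb_dir, N[i], CA[i], C[i])):
                names.append(name)
                elements.append("C")
                res_coords.append(pos)

        atom_idx = np.arange(idx, idx + len(names))
        idx += len(names)
        residues.append(
            Residue(name=res3, atom_names=tuple(names), elements=tuple(elements),
                    atom_indices=atom_idx)
        )
        backbone_map[i] = (int(atom_idx[0]), int(atom_idx[1]), int(atom_idx[2]))
        coords.extend(res_coords)

    pep = PeptideTopology(residues=residues, backbone_index_map=backbone_map)
    xyz = np.array(coords, dtype=float)
    if not np.isfinite(xyz).all():
        raise ValueError("non-finite geometry produced")
    return pep, xyz


def _cb_direction(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Idealized CA→Cβ unit vector from sp3 geometry (L-chirality)."""
    u1 = n - ca
    u1 /= np.linalg.norm(u1)
    u2 = c - ca
    u2 /= np.linalg.norm(u2)
    bisector = -(u1 + u2)
    bisector /= np.linalg.norm(bisector)
    normal = np.cross(u2, u1)
    normal /= np.linalg.norm(normal)
    d = math.cos(math.radians(54.0)) * bisector + math.sin(math.radians(54.0)) * normal
    return d / np.linalg.norm(d)


def _ring_sites(center: np.ndarray, cb_dir: np.ndarray,
                n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> list[np.ndarray]:
    """Planar hexagon (edge = circumradius = 0.139 nm) about ``center``.

    The ring normal lies along the CA→Cβ axis (a face-on disc), so ring
    atoms spread perpendicular to the side-chain direction; side chains of
    neighbouring sheet strands then meet face-to-face instead of
    interpenetrating edge-on.
    """
    ref = np.cross(n - ca, c - ca)
    nrm = np.linalg.norm(ref)
    if nrm < 1e-9 or abs(np.dot(ref / nrm, cb_dir)) > 0.99:
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, cb_dir)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        nrm = np.linalg.norm(ref)
    ref = ref / nrm
    e1 = np.cross(ref, cb_dir)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(cb_dir, e1)
    e2 /= np.linalg.norm(e2)
    sites = []
    for k in range(6):
        theta = math.pi / 3.0 * k
        sites.append(center + _RING_EDGE_NM * (math.cos(theta) * e1 + math.sin(theta) * e2))
    return sites


def build_peptide(sequence: str, conformer: str = "coil") -> tuple[PeptideTopology, np.ndarray]:
    """Convenience: build one peptide in a named conformer, canonically oriented."""
    spec = BackboneSpec.for_conformer(len(sequence), conformer)
    pep, xyz = build_backbone(sequence, spec)
    return pep, canonical_orientation(pep, xyz)


def canonical_orientation(pep: PeptideTopology, xyz: np.ndarray) -> np.ndarray:
    """Center at origin; strand axis (first→last CA) along +z; side-chain
    spread along ±x.  Used so sheet stacking along x is well defined."""
    xyz = xyz - xyz.mean(axis=0)
    ca = np.array([xyz[pep.backbone_index_map[i][1]] for i in range(pep.n_residues)])
    if len(ca) < 2:
        return xyz
    axis = ca[-1] - ca[0]
    axis /= np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    xyz = _rotate_a_to_b(xyz, axis, z)
    # align alternating side-chain directions with ±x
    ca = np.array([xyz[pep.backbone_index_map[i][1]] for i in range(pep.n_residues)])
    spread = np.zeros(3)
    sign = 1.0
    for i, res in enumerate(pep.noncap_residues):
        cb = [j for nm, j in zip(res.atom_names, res.atom_indices) if nm == "CB"]
        if cb:
            v = xyz[cb[0]] - ca[i]
            v[2] = 0.0
            spread += sign * v
            sign = -sign
    nrm = np.linalg.norm(spread)
    if nrm > 1e-9:
        spread /= nrm
        xyz = _rotate_about_z(xyz, spread, np.array([1.0, 0.0, 0.0]))
    return xyz - xyz.mean(axis=0)


def _rotate_a_to_b(xyz: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    v = np.cross(a, b)
    s = np.linalg.norm(v)
    c = float(np.dot(a, b))
    if s < 1e-12:
        if c > 0:
            return xyz
        # 180° flip about any axis perpendicular to a
        perp = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(perp, a)) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        perp -= np.dot(perp, a) * a
        perp /= np.linalg.norm(perp)
        R = 2.0 * np.outer(perp, perp) - np.eye(3)
        return xyz @ R.T
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    R = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    return xyz @ R.T


def _rotate_about_z(xyz: np.ndarray, frm: np.ndarray, to: np.ndarray) -> np.ndarray:
    a1 = math.atan2(frm[1], frm[0])
    a2 = math.atan2(to[1], to[0])
    th = a2 - a1
    R = np.array(
        [[math.cos(th), -math.sin(th), 0.0],
         [math.sin(th), math.cos(th), 0.0],
         [0.0, 0.0, 1.0]]
    )
    return xyz @ R.T


# ---------------------------------------------------------------------------
# initial placement
# ---------------------------------------------------------------------------

AVOGADRO = 6.02214076e23


def molar_concentration_mM(n_molecules: int, volume_nm3: float) -> float:
    """Concentration (mM) of n molecules in a box of the given volume.

    The canonical four-peptide truncated-octahedron box of 409 nm³ holds
    the peptides at ≈ 16.2 mM.
    """
    if volume_nm3 <= 0:
        raise ValueError("volume must be positive")
    litres = volume_nm3 * 1e-24
    return n_molecules / (AVOGADRO * litres) * 1e3


def tetrahedron_vertices(edge_nm: float) -> np.ndarray:
    """Vertices of a regular tetrahedron of the given edge, centered at 0."""
    v = np.array(
        [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
    )
    return v * (edge_nm / (2.0 * math.sqrt(2.0)))


def place_initial(peptide_coords: list[np.ndarray], edge_nm: float = 3.5
                  ) -> tuple[np.ndarray, float]:
    """Place four peptides with centroids at regular-tetrahedron vertices.

    Returns the stacked coordinate array and the minimum inter-peptide
    atom–atom distance.  Raises if the edge is non-positive or so small
    that peptide extents overlap.
    """
    if len(peptide_coords) != 4:
        raise ValueError("place_initial requires exactly 4 peptides")
    if edge_nm <= 0:
        raise ValueError("tetrahedron edge must be positive")
    verts = tetrahedron_vertices(edge_nm)
    placed = [xyz - xyz.mean(axis=0) + verts[i] for i, xyz in enumerate(peptide_coords)]
    min_d = math.inf
    for i in range(4):
        for j in range(i + 1, 4):
            diff = placed[i][:, None, :] - placed[j][None, :, :]
            d = np.sqrt((diff**2).sum(axis=2)).min()
            min_d = min(min_d, d)
    if min_d <= 0.05:
        raise ValueError(
            f"edge {edge_nm} nm too small for peptide extents "
            f"(min inter-peptide distance {min_d:.3f} nm)"
        )
    return np.concatenate(placed, axis=0), float(min_d)


# ---------------------------------------------------------------------------
# assembly scripts
# ---------------------------------------------------------------------------

_EVENT_KINDS = {"associate", "dissociate", "set_conformation", "set_registry"}
_CONFORMATIONS = set(CONFORMER_DIHEDRALS)


@dataclass(frozen=True)
class Event:
    """A timed scripted event.

    kinds: ``associate(i, j)``, ``dissociate(i, j)``,
    ``set_conformation(i, coil|beta|helix)``,
    ``set_registry(i, j, parallel|antiparallel)``.
    """

    time_ps: float
    kind: str
    i: int
    j: int | None = None
    value: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in _EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind in ("associate", "dissociate", "set_registry"):
            if self.j is None or self.j == self.i:
                raise ValueError(f"{self.kind} requires two distinct peptides")
        if self.kind == "set_conformation" and self.value not in _CONFORMATIONS:
            raise ValueError(f"conformation must be one of {sorted(_CONFORMATIONS)}")
        if self.kind == "set_registry" and self.value not in ("parallel", "antiparallel"):
            raise ValueError("registry must be 'parallel' or 'antiparallel'")


@dataclass
class AssemblyScript:
    """Ordered scripted events plus run geometry/noise parameters."""

    events: list[Event]
    duration_ps: float
    save_interval_ps: float = 10.0
    noise_sigma_nm: float = 0.0
    seed: int = 0
    sequence: str = "KLVFFAE"
    edge_nm: float = 3.5
    n_peptides: int = 4

    def validate(self) -> None:
        if self.duration_ps <= 0 or self.save_interval_ps <= 0:
            raise ValueError("duration and save interval must be positive")
        if self.noise_sigma_nm < 0:
            raise ValueError("noise_sigma_nm must be >= 0")
        bonds: set[frozenset[int]] = set()
        conf = {p: "coil" for p in range(self.n_peptides)}
        last_t = -math.inf
        for ev in sorted(self.events, key=lambda e: e.time_ps):
            if not (0.0 <= ev.time_ps <= self.duration_ps):
                raise ValueError(f"event at {ev.time_ps} ps outside [0, duration]")
            for p in (ev.i, ev.j):
                if p is not None and not (0 <= p < self.n_peptides):
                    raise ValueError(f"event refers to peptide {p} (out of range)")
            last_t = ev.time_ps
            if ev.kind == "associate":
                bonds.add(frozenset((ev.i, ev.j)))
            elif ev.kind == "dissociate":
                key = frozenset((ev.i, ev.j))
                if key not in bonds:
                    raise ValueError(
                        f"dissociate({ev.i},{ev.j}) at {ev.time_ps} ps: "
                        "pair was never associated"
                    )
                bonds.discard(key)
            elif ev.kind == "set_conformation":
                conf[ev.i] = ev.value  # type: ignore[assignment]
            elif ev.kind == "set_registry":
                if conf[ev.i] != "beta" or conf[ev.j] != "beta":
                    raise ValueError(
                        f"set_registry({ev.i},{ev.j}) at {ev.time_ps} ps: both "
                        "peptides must be in beta conformation"
                    )

    def sorted_events(self) -> list[Event]:
        return sorted(self.events, key=lambda e: (e.time_ps,
                                                  list(_EVENT_KINDS).index(e.kind)))


def canonical_script(
    ot2_ps: float = 2000.0,
    ot3_ps: float = 7000.0,
    ot4_ps: float = 18000.0,
    duration_ps: float = 30000.0,
    noise_sigma_nm: float = 0.0,
    seed: int = 0,
    sequence: str = "KLVFFAE",
    registries: tuple[str, ...] = (),
    beta_from_ps: float | None = None,
) -> AssemblyScript:
    """Stepwise monomer→dimer→trimer→tetramer assembly script.

    The default association times (2, 7, 18 ns) follow the mean dimeric,
    trimeric and tetrameric first-passage times reported for the
    double-mutant four-peptide system; the wild-type means (2, 10, 32 ns)
    can be scripted by passing those times instead.  Optional ``registries``
    strings ('parallel'/'antiparallel') pair peptides (0,1), (1,2), (2,3)
    into sheets once all are β; ``beta_from_ps`` switches all peptides to
    β at that time (required if registries are given).
    """
    events = [
        Event(ot2_ps, "associate", 0, 1),
        Event(ot3_ps, "associate", 1, 2),
        Event(ot4_ps, "associate", 2, 3),
    ]
    if registries:
        if beta_from_ps is None:
            beta_from_ps = ot4_ps
        for p in range(4):
            events.append(Event(beta_from_ps, "set_conformation", p, value="beta"))
        pairs = [(0, 1), (1, 2), (2, 3)]
        t_reg = max(beta_from_ps, ot4_ps)
        for (i, j), reg in zip(pairs, registries):
            events.append(Event(t_reg, "set_registry", i, j, value=reg))
    return AssemblyScript(
        events=events,
        duration_ps=duration_ps,
        noise_sigma_nm=noise_sigma_nm,
        seed=seed,
        sequence=sequence,
    )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

_BETA_CA_RISE_NM = 0.335  # approximate rise/residue of the built β conformer

# sheet stacking geometry: strands are rotated about their axis by the
# azimuth and successive strands offset by the pleat perpendicular to the
# stacking direction; chosen so that at 0.48 nm Cα spacing the minimum
# atom distance of a paired strand lies in [0.15, 0.25] nm (inside the
# 0.3 nm contact cutoff, outside steric overlap) for both registries
_SHEET_AZIMUTH_DEG = 94.0
_SHEET_PLEAT_NM = 0.06


class _AssemblyState:
    """Mutable scripted state: bonds, conformations, registries, layout."""

    def __init__(self, script: AssemblyScript):
        self.n = script.n_peptides
        self.bonds: set[frozenset[int]] = set()
        self.conformation = {p: "coil" for p in range(self.n)}
        self.registry: dict[frozenset[int], str] = {}
        self.order: list[int] = []  # association order, defines sheet slots

    def apply(self, ev: Event) -> None:
        if ev.kind == "associate":
            self.bonds.add(frozenset((ev.i, ev.j)))
            for p in (ev.i, ev.j):
                if p not in self.order:
                    self.order.append(p)
        elif ev.kind == "dissociate":
            self.bonds.discard(frozenset((ev.i, ev.j)))
            self.registry.pop(frozenset((ev.i, ev.j)), None)
        elif ev.kind == "set_conformation":
            self.conformation[ev.i] = ev.value  # type: ignore[assignment]
        elif ev.kind == "set_registry":
            self.registry[frozenset((ev.i, ev.j))] = ev.value  # type: ignore[assignment]

    def components(self) -> list[list[int]]:
        parent = list(range(self.n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for bond in self.bonds:
            a, b = tuple(bond)
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
        comps: dict[int, list[int]] = {}
        for p in range(self.n):
            comps.setdefault(find(p), []).append(p)
        return [sorted(v) for v in sorted(comps.values(), key=lambda c: c[0])]

    def slot_order(self, comp: list[int]) -> list[int]:
        """Stacking order inside a cluster: association order, then index."""
        ordered = [p for p in self.order if p in comp]
        ordered += [p for p in sorted(comp) if p not in ordered]
        return ordered

    def orientations(self, comp_sorted: list[int]) -> dict[int, int]:
        """Strand signs (+1/-1) satisfying the registry constraints.

        Propagated across the cluster's registry edges from the
        lowest-index β peptide; unconstrained strands default +1.
        """
        signs: dict[int, int] = {}
        members = set(comp_sorted)
        edges = {e: r for e, r in self.registry.items() if e <= members}
        for start in comp_sorted:
            if start in signs:
                continue
            signs[start] = 1
            stack = [start]
            while stack:
                u = stack.pop()
                for e, reg in edges.items():
                    if u in e:
                        (v,) = e - {u}
                        want = signs[u] * (1 if reg == "parallel" else -1)
                        if v not in signs:
                            signs[v] = want
                            stack.append(v)
        return signs


def _dock_offset(xyz_a: np.ndarray, xyz_b: np.ndarray, target_nm: float,
                 lo: float = 0.05, hi: float = 8.0) -> float:
    """x-offset of body B relative to A so min atom distance == target."""

    def min_d(off: float) -> float:
        diff = xyz_a[:, None, :] - (xyz_b + np.array([off, 0.0, 0.0]))[None, :, :]
        return float(np.sqrt((diff**2).sum(axis=2)).min())

    # min distance is nondecreasing in offset over [lo, hi]; bisect
    f_lo, f_hi = min_d(lo), min_d(hi)
    if f_hi < target_nm:
        return hi
    if f_lo > target_nm:
        return lo
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if min_d(mid) < target_nm:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate(
    script: AssemblyScript,
    registry_ca_spacing_nm: float = 0.48,
    dock_distance_nm: float = 0.22,
) -> tuple[SystemTopology, list[TrajectoryFrame], GroundTruthLabels]:
    """Realize an assembly script as a trajectory plus ground-truth labels.

    Frames are emitted at the script's save cadence (times 0, Δt, …,
    (n-1)Δt with n = duration/Δt).  Events take effect on the first frame
    whose time is ≥ the event time.  Associated peptides are rigidly
    docked (min atom distance ≈ ``dock_distance_nm`` ≤ 0.25 nm); β-paired
    strands are stacked side by side at ``registry_ca_spacing_nm`` Cα
    spacing with parallel or antiparallel direction per registry.  A
    tethered random walk (σ = noise σ per frame, relaxation 0.9) moves
    each cluster about its anchor, and i.i.d. Gaussian noise of the same
    σ is added to every coordinate.  Identical seeds give identical
    output.
    """
    script.validate()
    n_res = len(script.sequence)

    # one conformer library per peptide (shared geometry; copies placed)
    conformer_xyz: dict[str, np.ndarray] = {}
    pep0, _ = build_peptide(script.sequence, "coil")
    for conf in CONFORMER_DIHEDRALS:
        _, xyz = build_peptide(script.sequence, conf)
        conformer_xyz[conf] = xyz
    n_atoms_pp = conformer_xyz["coil"].shape[0]
    ca_idx_local = pep0.ca_indices()

    # system topology: four copies with shifted global indices
    peptides = []
    for p in range(script.n_peptides):
        shift = p * n_atoms_pp
        residues = [
            Residue(name=r.name, atom_names=r.atom_names, elements=r.elements,
                    atom_indices=r.atom_indices + shift, is_cap=r.is_cap)
            for r in pep0.residues
        ]
        bmap = {k: (a + shift, b + shift, c + shift)
                for k, (a, b, c) in pep0.backbone_index_map.items()}
        peptides.append(PeptideTopology(residues=residues, backbone_index_map=bmap))
    topology = SystemTopology(peptides=peptides,
                              atom_count=script.n_peptides * n_atoms_pp)

    n_frames = int(round(script.duration_ps / script.save_interval_ps))
    rng = np.random.default_rng(script.seed)
    verts = tetrahedron_vertices(script.edge_nm)

    state = _AssemblyState(script)
    events = script.sorted_events()
    ev_ptr = 0

    frames: list[TrajectoryFrame] = []
    components_out = np.zeros((n_frames, script.n_peptides), dtype=int)
    orientations_out = np.zeros((n_frames, script.n_peptides), dtype=int)
    conformations_out: list[list[str]] = []
    state_labels: list[str] = []
    sheet_classes: list[str] = []
    times = np.arange(n_frames) * script.save_interval_ps

    drift = np.zeros((script.n_peptides, 3))  # per-cluster, keyed by anchor peptide
    layout_cache: dict = {"key": None, "coords": None, "meta": None}

    for f in range(n_frames):
        t = times[f]
        changed = False
        while ev_ptr < len(events) and events[ev_ptr].time_ps <= t:
            state.apply(events[ev_ptr])
            ev_ptr += 1
            changed = True

        key = (
            frozenset(state.bonds),
            tuple(sorted(state.conformation.items())),
            tuple(sorted((tuple(sorted(e)), r) for e, r in state.registry.items())),
        )
        if changed or layout_cache["key"] != key:
            coords0, meta = _layout(state, conformer_xyz, verts,
                                    registry_ca_spacing_nm, dock_distance_nm,
                                    script.edge_nm, ca_idx_local)
            layout_cache = {"key": key, "coords": coords0, "meta": meta}
        coords0, meta = layout_cache["coords"], layout_cache["meta"]

        # tethered random walk per cluster + i.i.d. coordinate noise
        coords = coords0.copy()
        if script.noise_sigma_nm > 0:
            comp_of = meta["comp_of"]
            anchors = sorted(set(comp_of.values()))
            step = rng.normal(0.0, script.noise_sigma_nm, size=(len(anchors), 3))
            for a_i, anchor in enumerate(anchors):
                drift[anchor] = 0.9 * drift[anchor] + step[a_i]
            for p in range(script.n_peptides):
                sl = slice(p * n_atoms_pp, (p + 1) * n_atoms_pp)
                coords[sl] += drift[comp_of[p]]
            coords += rng.normal(0.0, script.noise_sigma_nm, size=coords.shape)
        else:
            rng.normal(size=3)  # keep stream advancing uniformly per frame

        frames.append(TrajectoryFrame(frame_index=f, time_ps=float(t),
                                      coordinates=coords))
        components_out[f] = meta["component_ids"]
        orientations_out[f] = meta["orientations"]
        conformations_out.append([state.conformation[p]
                                  for p in range(script.n_peptides)])
        state_labels.append(meta["state_label"])
        sheet_classes.append(meta["sheet_class"])

    labels = GroundTruthLabels(
        components=components_out,
        conformations=conformations_out,
        state_labels=state_labels,
        sheet_classes=sheet_classes,
        orientations=orientations_out,
        time_ps=times.astype(float),
    )
    return topology, frames, labels


def _beta_runs(order: list[int], conformation: dict[int, str]) -> list[list[int]]:
    """Maximal runs of >= 2 consecutive β members along the stacking order."""
    runs: list[list[int]] = []
    run: list[int] = []
    for p in order:
        if conformation[p] == "beta":
            run.append(p)
        else:
            if len(run) >= 2:
                runs.append(run)
            run = []
    if len(run) >= 2:
        runs.append(run)
    return runs


def _run_class(run: list[int], signs: dict[int, int]) -> str:
    kinds = {
        "parallel" if signs.get(a, 1) == signs.get(b, 1) else "antiparallel"
        for a, b in zip(run, run[1:])
    }
    prefix = "m" if len(kinds) > 1 else ("p" if "parallel" in kinds else "ap")
    return f"{prefix}BS{len(run)}"


def _layout(state: _AssemblyState, conformer_xyz: dict[str, np.ndarray],
            verts: np.ndarray, ca_spacing: float, dock_distance: float,
            edge_nm: float, ca_idx: np.ndarray):
    """Deterministic rigid placement for the current scripted state."""
    n = state.n
    n_atoms_pp = conformer_xyz["coil"].shape[0]
    comps = state.components()

    placed = np.zeros((n * n_atoms_pp, 3))
    component_ids = np.zeros(n, dtype=int)
    orientations = np.zeros(n, dtype=int)
    comp_of: dict[int, int] = {}
    cluster_blocks: list[tuple[list[int], np.ndarray]] = []

    th = math.radians(_SHEET_AZIMUTH_DEG)
    rz = np.array(
        [[math.cos(th), -math.sin(th), 0.0],
         [math.sin(th), math.cos(th), 0.0],
         [0.0, 0.0, 1.0]]
    )
    for cid, comp in enumerate(comps):
        order = state.slot_order(comp)
        signs = state.orientations(order)
        local: dict[int, np.ndarray] = {}
        prev: int | None = None
        for p in order:
            conf = state.conformation[p]
            xyz = conformer_xyz[conf].copy()
            if conf == "beta":
                xyz = xyz @ rz.T  # sheet azimuth about the strand axis
                orientations[p] = signs.get(p, 1)
                if orientations[p] < 0:
                    # antiparallel: 180° rotation about x flips the strand
                    # direction while preserving chirality and dihedrals
                    xyz = xyz @ np.diag([1.0, -1.0, -1.0])
            xyz = xyz - xyz.mean(axis=0)
            if prev is None:
                local[p] = xyz
            else:
                both_beta = (state.conformation[prev] == "beta" and conf == "beta")
                prev_x = float(local[prev][:, 0].mean())
                prev_y = float(local[prev][:, 1].mean())
                if both_beta:
                    # stack by Cα centroids: the registry-aligned residue-wise
                    # Cα distance then equals ~ the requested spacing for both
                    # orientations regardless of side-chain mass distribution
                    shift = (local[prev][ca_idx].mean(axis=0)
                             - xyz[ca_idx].mean(axis=0)
                             + np.array([ca_spacing, _SHEET_PLEAT_NM, 0.0]))
                    local[p] = xyz + shift
                else:
                    x_new = _dock_offset(local[prev], xyz + np.array([0.0, prev_y, 0.0]),
                                         dock_distance,
                                         lo=prev_x, hi=prev_x + 8.0)
                    local[p] = xyz + np.array([x_new, prev_y, 0.0])
            prev = p

        block = np.concatenate([local[p] for p in order], axis=0)
        block -= block.mean(axis=0)
        anchor_pep = min(comp)
        anchor = verts[list(comp)].mean(axis=0) if len(comp) < n else np.zeros(3)
        for p in order:
            comp_of[p] = anchor_pep
            component_ids[p] = cid
        cluster_blocks.append((order, block + anchor))

    # push clusters apart if rigid blocks approach within 1 nm
    blocks = [blk for _, blk in cluster_blocks]
    if len(blocks) > 1:
        scale = 1.0
        for _ in range(40):
            ok = True
            for i in range(len(blocks)):
                for j in range(i + 1, len(blocks)):
                    bi = _scaled(blocks[i], scale)
                    bj = _scaled(blocks[j], scale)
                    diff = bi[:, None, :] - bj[None, :, :]
                    if np.sqrt((diff**2).sum(axis=2)).min() < 1.0:
                        ok = False
            if ok:
                break
            scale *= 1.15
        blocks = [_scaled(b, scale) for b in blocks]

    for (order, _), blk in zip(cluster_blocks, blocks):
        for slot, p in enumerate(order):
            placed[p * n_atoms_pp:(p + 1) * n_atoms_pp] = \
                blk[slot * n_atoms_pp:(slot + 1) * n_atoms_pp]

    # ground-truth state: sheet peptides within the most sheet-rich largest
    # component; sheet class reported for its largest run
    largest = max(len(c) for c in comps)
    n_sheet = 0
    sheet_class = "-"
    for comp in (c for c in comps if len(c) == largest):
        order = state.slot_order(comp)
        signs = state.orientations(order)
        runs = _beta_runs(order, state.conformation)
        total = sum(len(r) for r in runs)
        if total > n_sheet or (total == n_sheet and total > 0 and sheet_class == "-"):
            n_sheet = total
            big = max(runs, key=len)
            sheet_class = _run_class(big, signs)

    from .oligomers import state_label_for  # local import avoids a cycle

    label = state_label_for(largest, n_sheet)
    meta = {
        "component_ids": component_ids,
        "orientations": orientations,
        "comp_of": comp_of,
        "state_label": label,
        "sheet_class": sheet_class,
    }
    return placed, meta


def _scaled(block: np.ndarray, scale: float) -> np.ndarray:
    center = block.mean(axis=0)
    return center * scale + (block - center)
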